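from itertools import permutations

import numpy as np
import pytest

from d2d.evaluation import (hungarian_match, loglik_matrix, matching_curve,
                            metrics_report, mi_estimate, perplexity, accuracy,
                            sequence_loglik, batch_logliks)
from d2d.models import UniformBaseline
from d2d.pmsa import PairedMSA

from conftest import perfect_model_for


@pytest.fixture()
def uniform_model(tok):
    return UniformBaseline(tok)


class TestPerplexityAccuracy:
    def test_uniform_model_pp_is_21(self, tok, uniform_model, tiny_pmsa):
        assert perplexity(uniform_model, tiny_pmsa, tok=tok) == pytest.approx(21.0)

    def test_perfect_model(self, tok, tiny_pmsa):
        m = perfect_model_for(tok, tiny_pmsa)
        rep = metrics_report(m, tiny_pmsa, range(3), tok)
        assert rep.perplexity == pytest.approx(1.0, abs=1e-9)
        assert rep.accuracy == 1.0
        assert rep.cross_entropy == pytest.approx(0.0, abs=1e-9)

    def test_hand_perplexity(self, tok, table_model_factory):
        # probabilities (0.5, 0.125) -> PP = (1/16)^(-1/2) = 4
        rows = np.zeros((2, 21))
        rows[0, :] = np.log(0.5)
        rows[1, :] = np.log(0.125)
        m = table_model_factory(rows)
        pmsa = PairedMSA(["AAA"], ["CD"], ["x"])
        assert perplexity(m, pmsa, tok=tok) == pytest.approx(4.0)

    def test_accuracy_constant_argmax(self, tok, table_model_factory):
        # model always prefers 'A' (token 0); target has 1 of 4 positions == A
        rows = np.full((4, 21), np.log(0.01))
        rows[:, 0] = np.log(0.79)
        m = table_model_factory(rows)
        pmsa = PairedMSA(["AAA"], ["ACDE"], ["x"])
        assert accuracy(m, pmsa, tok=tok) == pytest.approx(0.25)

    def test_uniform_loglik_value(self, tok, uniform_model):
        ll = sequence_loglik(uniform_model, "AAA", "ACD")
        assert ll == pytest.approx(3 * np.log(1 / 21))

    def test_loglik_equals_negative_ce_times_nout(self, tok, uniform_model, tiny_pmsa):
        rep = metrics_report(uniform_model, tiny_pmsa, range(3), tok)
        ll = sequence_loglik(uniform_model, tiny_pmsa.source_seqs[0],
                             tiny_pmsa.target_seqs[0])
        assert ll == pytest.approx(-rep.cross_entropy * tiny_pmsa.Nout)

    def test_manual_accumulation_agrees(self, tok, tiny_model, tiny_pmsa):
        src = np.array([tok.encode(tiny_pmsa.source_seqs[0])])
        tgt = np.array([tok.encode(tiny_pmsa.target_seqs[0])])
        lp = tiny_model.conditional_logprobs(src, tgt)
        manual = sum(lp[0, i, tgt[0, i]] for i in range(tgt.shape[1]))
        assert batch_logliks(tiny_model, src, tgt)[0] == pytest.approx(manual, abs=1e-10)

    def test_jensen_gap(self, tok, tiny_model, tiny_pmsa):
        rep = metrics_report(tiny_model, tiny_pmsa, range(3), tok)
        assert rep.perplexity >= rep.perplexity_geom - 1e-9

    def test_empty_subset_error(self, tok, uniform_model, tiny_pmsa):
        with pytest.raises(ValueError, match="empty"):
            metrics_report(uniform_model, tiny_pmsa, [], tok)


class TestHungarian:
    def test_diagonally_dominant_identity(self):
        m = np.full((5, 5), -10.0)
        np.fill_diagonal(m, 0.0)
        r = hungarian_match(m)
        np.testing.assert_array_equal(r.assignment, np.arange(5))
        assert r.matched_fraction == 1.0

    def test_bruteforce_total_small(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            M = rng.integers(2, 7)
            mat = rng.normal(size=(M, M))
            r = hungarian_match(mat)
            best = max(sum(mat[i, p[i]] for i in range(M))
                       for p in permutations(range(M)))
            assert r.total_loglik == pytest.approx(best, abs=1e-9)

    def test_single_pair(self):
        r = hungarian_match(np.array([[3.0]]))
        assert r.matched_fraction == 1.0
        assert r.random_baseline == 1.0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            hungarian_match(np.zeros((2, 3)))

    def test_non_finite_rejected(self):
        m = np.zeros((2, 2))
        m[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            hungarian_match(m)


class TestLoglikMatrix:
    def test_single_entry(self, tok, tiny_model, tiny_pmsa):
        src = np.array([tok.encode(tiny_pmsa.source_seqs[0])])
        tgt = np.array([tok.encode(tiny_pmsa.target_seqs[0])])
        mat = loglik_matrix(tiny_model, src, tgt)
        assert mat.shape == (1, 1)
        assert mat[0, 0] == pytest.approx(
            sequence_loglik(tiny_model, src[0], tgt[0]), abs=1e-5)

    def test_diagonal_consistency_and_column_equivariance(self, tok, tiny_model,
                                                          tiny_pmsa):
        src = np.array([tok.encode(s) for s in tiny_pmsa.source_seqs])
        tgt = np.array([tok.encode(s) for s in tiny_pmsa.target_seqs])
        mat = loglik_matrix(tiny_model, src, tgt)
        for i in range(3):
            assert mat[i, i] == pytest.approx(
                batch_logliks(tiny_model, src[i:i + 1], tgt[i:i + 1])[0], abs=1e-5)
        perm = [2, 0, 1]
        mat_p = loglik_matrix(tiny_model, src, tgt[perm])
        np.testing.assert_allclose(mat_p, mat[:, perm], atol=1e-5)

    def test_memory_cap(self, tok, uniform_model):
        src = np.zeros((3, 2), dtype=np.int64)
        tgt = np.zeros((3, 2), dtype=np.int64)
        with pytest.raises(ValueError, match="cap"):
            loglik_matrix(uniform_model, src, tgt, cap=2)
        loglik_matrix(uniform_model, src, tgt, cap=2, force=True)


class TestMatchingCurve:
    def test_size_one_always_matched(self, tok, uniform_model, tiny_pmsa):
        df = matching_curve(uniform_model, tiny_pmsa, [0, 1, 2], [1],
                            n_repeats=4, seed=0, tok=tok)
        assert df["matched_fraction"][0] == 1.0

    def test_deterministic_given_seed(self, tok, tiny_model, tiny_pmsa):
        a = matching_curve(tiny_model, tiny_pmsa, [0, 1, 2], [2], 3, seed=7, tok=tok)
        b = matching_curve(tiny_model, tiny_pmsa, [0, 1, 2], [2], 3, seed=7, tok=tok)
        assert a.equals(b)

    def test_oversized_subsample_rejected(self, tok, uniform_model, tiny_pmsa):
        with pytest.raises(ValueError, match="exceeds"):
            matching_curve(uniform_model, tiny_pmsa, [0, 1], [3], 2, 0, tok)


class TestMiEstimate:
    def test_identical_models_zero(self, tok, tiny_model, tiny_pmsa):
        src = np.array([tok.encode(s) for s in tiny_pmsa.source_seqs])
        tgt = np.array([tok.encode(s) for s in tiny_pmsa.target_seqs])
        assert mi_estimate(tiny_model, tiny_model, src, tgt) == 0.0

    def test_per_position_flag(self, tok, uniform_model, tiny_pmsa):
        src = np.array([tok.encode(s) for s in tiny_pmsa.source_seqs])
        tgt = np.array([tok.encode(s) for s in tiny_pmsa.target_seqs])
        m = perfect_model_for(tok, tiny_pmsa)
        g_seq = mi_estimate(m, uniform_model, src, tgt)
        g_pos = mi_estimate(m, uniform_model, src, tgt, per_position=True)
        assert g_seq == pytest.approx(g_pos * tiny_pmsa.Nout)
        assert g_seq == pytest.approx(tiny_pmsa.Nout * np.log(21), rel=1e-6)
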