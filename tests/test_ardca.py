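from itertools import product

import numpy as np
import pytest

from d2d.ardca import (ArdcaParams, ardca_conditional, ardca_fit,
                       ardca_loglik, ardca_sample, Q)
from d2d.pmsa import PairedMSA


def random_params(Nin, Nout, scale, seed):
    rng = np.random.default_rng(seed)
    p = ArdcaParams.zeros(Nin, Nout)
    p.h[:] = rng.normal(0, scale, p.h.shape)
    for i in range(Nout):
        p.J[i, : Nin + i] = rng.normal(0, scale, (Nin + i, Q, Q))
    return p


class TestConditional:
    def test_zero_params_uniform(self):
        p = ArdcaParams.zeros(3, 2)
        c = ardca_conditional(p, [0, 1, 2], [], 0)
        np.testing.assert_allclose(c, 1.0 / 21, atol=1e-12)

    def test_first_position_ignores_target(self):
        p = random_params(3, 2, 0.5, 0)
        c = ardca_conditional(p, [4, 5, 6], [], 0)
        assert c.shape == (21,)
        np.testing.assert_allclose(c.sum(), 1.0, atol=1e-8)

    def test_bruteforce_softmax_oracle(self):
        """Direct exponential-sum evaluation on Nin=Nout=2 random params."""
        p = random_params(2, 2, 0.7, 1)
        rng = np.random.default_rng(2)
        for _ in range(20):
            src = rng.integers(0, Q, 2)
            pre = rng.integers(0, Q, 1)
            i = 1
            ctx = list(src) + list(pre)
            logits = np.array([
                p.h[i, a] + sum(p.J[i, j, a, ctx[j]] for j in range(len(ctx)))
                for a in range(Q)])
            expect = np.exp(logits) / np.exp(logits).sum()
            got = ardca_conditional(p, src, pre, i)
            np.testing.assert_allclose(got, expect, atol=1e-10)

    def test_prefix_length_mismatch(self):
        p = ArdcaParams.zeros(2, 2)
        with pytest.raises(ValueError, match="prefix"):
            ardca_conditional(p, [0, 1], [0], 0)


class TestLoglik:
    def test_zero_params_value(self):
        p = ArdcaParams.zeros(2, 4)
        ll = ardca_loglik(p, [0, 1], [2, 3, 4, 5])
        np.testing.assert_allclose(ll, 4 * np.log(1 / 21), atol=1e-12)

    def test_consistent_with_conditionals(self):
        p = random_params(2, 3, 0.4, 3)
        rng = np.random.default_rng(4)
        src = rng.integers(0, Q, 2)
        tgt = rng.integers(0, Q, 3)
        manual = sum(np.log(ardca_conditional(p, src, tgt[:i], i)[tgt[i]])
                     for i in range(3))
        np.testing.assert_allclose(ardca_loglik(p, src, tgt), manual, atol=1e-10)

    def test_exhaustive_normalization(self):
        """Sum of P(A|B) over all 21^2 targets equals 1 (exact softmax chain)."""
        p = random_params(2, 2, 0.6, 5)
        src = [7, 13]
        total = sum(np.exp(ardca_loglik(p, src, list(t)))
                    for t in product(range(Q), repeat=2))
        np.testing.assert_allclose(total, 1.0, atol=1e-6)


class TestFit:
    def _pmsa_from(self, src, tgt, tok):
        return PairedMSA([tok.decode(r) for r in src], [tok.decode(r) for r in tgt],
                         [f"r{i}" for i in range(len(src))])

    def test_objective_monotone(self, tok):
        rng = np.random.default_rng(0)
        true = random_params(3, 3, 0.3, 0)
        src = rng.integers(0, Q, (500, 3))
        tgt = ardca_sample(true, src, rng)
        fit = ardca_fit(self._pmsa_from(src, tgt, tok), l2_lambda=0.1, tokenizer=tok)
        h = fit.objective_history
        assert len(h) > 2
        assert all(b <= a + 1e-7 for a, b in zip(h, h[1:]))

    def test_strong_regularization_limit(self, tok):
        rng = np.random.default_rng(1)
        src = rng.integers(0, Q, (50, 2))
        tgt = rng.integers(0, Q, (50, 2))
        fit = ardca_fit(self._pmsa_from(src, tgt, tok), l2_lambda=1e7, tokenizer=tok)
        assert np.abs(fit.params.J).max() < 1e-3
        c = ardca_conditional(fit.params, src[0], [], 0)
        np.testing.assert_allclose(c, 1.0 / 21, atol=1e-3)

    def test_degenerate_mle_single_pair(self, tok):
        src = np.tile([3, 4], (30, 1))
        tgt = np.tile([5, 6], (30, 1))
        fit = ardca_fit(self._pmsa_from(src, tgt, tok), l2_lambda=0.0, tokenizer=tok)
        p = np.exp(ardca_loglik(fit.params, [3, 4], [5, 6]))
        assert p > 0.99

    def test_evaluation_contract(self, tok):
        """arDCA plugs into the shared metric stack unchanged."""
        from d2d.evaluation import metrics_report, match_subset
        rng = np.random.default_rng(2)
        true = random_params(3, 3, 0.3, 7)
        src = rng.integers(0, Q, (200, 3))
        tgt = ardca_sample(true, src, rng)
        pmsa = self._pmsa_from(src, tgt, tok)
        fit = ardca_fit(pmsa, l2_lambda=1.0, tokenizer=tok)
        rep = metrics_report(fit, pmsa, range(50), tok)
        assert 1.0 <= rep.perplexity <= 21.5
        mr = match_subset(fit, pmsa, range(6), tok)
        assert mr.loglik_matrix.shape == (6, 6)

    def test_site_order_permutation_hook(self, tok):
        """A permuted autoregressive order still defines a valid model: the
        total probability over target space sums to 1 and evaluation rows come
        back in alignment order."""
        rng = np.random.default_rng(5)
        true = random_params(2, 2, 0.4, 11)
        src = rng.integers(0, Q, (300, 2))
        tgt = ardca_sample(true, src, rng)
        pmsa = self._pmsa_from(src, tgt, tok)
        fit = ardca_fit(pmsa, l2_lambda=1.0, tokenizer=tok, site_order=[1, 0])
        assert fit.params.site_order == [1, 0]
        lp = fit.conditional_logprobs(src[:5], tgt[:5])
        assert lp.shape == (5, 2, Q)
        # chain rule under the permuted order still normalizes exactly
        total = 0.0
        for a in range(Q):
            for b in range(Q):
                rows = fit.conditional_logprobs(src[:1], np.array([[a, b]]))
                total += np.exp(rows[0, 0, a] + rows[0, 1, b])
        np.testing.assert_allclose(total, 1.0, atol=1e-6)

    def test_quadratic_parameter_scaling(self):
        def expected(Nin, Nout):
            # fields + one QxQ coupling block per (target pos, context pos)
            return Nout * Q + sum((Nin + i) * Q * Q for i in range(Nout))

        assert ArdcaParams.zeros(3, 3).n_parameters == expected(3, 3)
        assert ArdcaParams.zeros(6, 6).n_parameters == expected(6, 6)
        # doubling both lengths scales the count ~quadratically
        ratio = expected(6, 6) / expected(3, 3)
        assert 3.5 < ratio < 4.5
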