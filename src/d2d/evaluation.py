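"""Quality metrics for conditional sequence models of interacting domains.

All metrics work on any model exposing ``conditional_logprobs(src, tgt)`` —
teacher-forced log P(a_i | B, a_<i) over the 21 residue symbols — so the
Transformer and the arDCA baseline are evaluated identically:

* per-sequence conditional log-likelihood and perplexity
  PP(A,B) = exp(-log P(A|B) / Nout),
* per-position accuracy (argmax over the residue alphabet),
* matching specificity: re-pair a shuffled validation set by maximizing the
  total log-likelihood over an optimal assignment (Hungarian algorithm); a
  random matching scores 1/M in expectation,
* a rough per-sequence mutual-information estimate between partner domains,
  obtained by contrasting a model trained on true pairs with one trained on
  shuffled pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .alphabet import Tokenizer
from .pmsa import PairedMSA


@dataclass
class MetricsReport:
    perplexity: float          # arithmetic mean of per-sequence PP
    perplexity_geom: float     # exp(mean cross-entropy); <= perplexity (Jensen)
    accuracy: float
    cross_entropy: float       # mean over positions and sequences, nats
    n_sequences: int
    subset_label: str = ""


def encode_rows(pmsa: PairedMSA, indices, tok: Tokenizer):
    """Tokenize selected pMSA rows into (source, target) integer matrices."""
    idx = list(indices)
    src = np.array([tok.encode(pmsa.source_seqs[i]) for i in idx], dtype=np.int64)
    tgt = np.array([tok.encode(pmsa.target_seqs[i]) for i in idx], dtype=np.int64)
    return src, tgt


_encode_rows = encode_rows


def batch_logliks(model, src_tokens: np.ndarray, tgt_tokens: np.ndarray) -> np.ndarray:
    """Per-row log P(A|B) summed over the Nout residue positions."""
    lp = model.conditional_logprobs(src_tokens, tgt_tokens)  # (B, Nout, 21)
    picked = np.take_along_axis(lp, tgt_tokens[..., None], axis=-1)[..., 0]
    return picked.sum(axis=1)


def sequence_loglik(model, source, target) -> float:
    """log P(A|B) for one pair; accepts strings or token arrays."""
    tok = model.tokenizer
    src = np.asarray(tok.encode(source) if isinstance(source, str) else source)
    tgt = np.asarray(tok.encode(target) if isinstance(target, str) else target)
    return float(batch_logliks(model, src[None, :], tgt[None, :])[0])


def metrics_report(model, pmsa: PairedMSA, indices, tok: Tokenizer | None = None,
                   subset_label: str = "") -> MetricsReport:
    """Perplexity, accuracy and cross-entropy on a subset of pMSA rows."""
    idx = list(indices)
    if not idx:
        raise ValueError("cannot evaluate metrics on an empty subset")
    tok = tok or model.tokenizer
    src, tgt = _encode_rows(pmsa, idx, tok)
    lp = model.conditional_logprobs(src, tgt)               # (B, Nout, 21)
    picked = np.take_along_axis(lp, tgt[..., None], axis=-1)[..., 0]
    Nout = tgt.shape[1]
    per_seq_ll = picked.sum(axis=1)
    pp = float(np.exp(-per_seq_ll / Nout).mean())
    ce = float(-picked.mean())
    pp_geom = float(np.exp(ce))
    # Jensen: arithmetic mean of per-sequence PP dominates exp(mean CE)
    assert pp >= pp_geom - 1e-6 * max(1.0, pp_geom)
    acc = float((lp.argmax(axis=-1) == tgt).mean())
    return MetricsReport(perplexity=pp, perplexity_geom=pp_geom, accuracy=acc,
                         cross_entropy=ce, n_sequences=len(idx),
                         subset_label=subset_label)


def perplexity(model, pmsa: PairedMSA, indices=None, tok: Tokenizer | None = None) -> float:
    indices = list(indices) if indices is not None else list(range(pmsa.M))
    return metrics_report(model, pmsa, indices, tok).perplexity


def accuracy(model, pmsa: PairedMSA, indices=None, tok: Tokenizer | None = None) -> float:
    indices = list(indices) if indices is not None else list(range(pmsa.M))
    return metrics_report(model, pmsa, indices, tok).accuracy


# --------------------------------------------------------------------------
# matching specificity
# --------------------------------------------------------------------------

@dataclass
class MatchingResult:
    loglik_matrix: np.ndarray   # (M, M); entry (i, j) = log P(A_j | B_i)
    assignment: np.ndarray      # sigma: source i matched to target sigma[i]
    matched_fraction: float     # fixed points of sigma / M
    random_baseline: float      # 1 / M
    total_loglik: float


def loglik_matrix(model, src_tokens: np.ndarray, tgt_tokens: np.ndarray,
                  cap: int = 2000, force: bool = False) -> np.ndarray:
    """All-pairs conditional log-likelihoods: entry (i, j) = log P(A_j | B_i).

    Costs O(M^2) sequence evaluations, batched one target against all sources.
    """
    M = src_tokens.shape[0]
    if tgt_tokens.shape[0] != M:
        raise ValueError("source and target lists must have equal length")
    if M > cap and not force:
        raise ValueError(f"M={M} exceeds the matrix cap {cap}; pass force=True")
    out = np.empty((M, M))
    for j in range(M):
        tiled = np.repeat(tgt_tokens[j][None, :], M, axis=0)
        out[:, j] = batch_logliks(model, src_tokens, tiled)
    return out


def hungarian_match(matrix: np.ndarray) -> MatchingResult:
    """Optimal assignment maximizing the total log-likelihood."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matching needs a square matrix, got {matrix.shape}")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matching matrix contains non-finite entries")
    rows, cols = linear_sum_assignment(matrix, maximize=True)
    sigma = np.empty(matrix.shape[0], dtype=np.int64)
    sigma[rows] = cols
    M = matrix.shape[0]
    frac = float((sigma == np.arange(M)).mean())
    return MatchingResult(loglik_matrix=matrix, assignment=sigma,
                          matched_fraction=frac, random_baseline=1.0 / M,
                          total_loglik=float(matrix[rows, cols].sum()))


def match_subset(model, pmsa: PairedMSA, indices, tok: Tokenizer | None = None,
                 **kwargs) -> MatchingResult:
    tok = tok or model.tokenizer
    src, tgt = _encode_rows(pmsa, indices, tok)
    return hungarian_match(loglik_matrix(model, src, tgt, **kwargs))


def matching_curve(model, pmsa: PairedMSA, indices, subsample_sizes,
                   n_repeats: int = 5, seed: int = 0,
                   tok: Tokenizer | None = None) -> pd.DataFrame:
    """Matched fraction versus subsample size M, with the 1/M baseline.

    The matching task hardens as M grows, so the curve (mean ± standard error
    over random subsamples) is the informative view of specificity.
    """
    tok = tok or model.tokenizer
    idx = list(indices)
    rng = np.random.default_rng(seed)
    rows = []
    for size in subsample_sizes:
        if size > len(idx):
            raise ValueError(f"subsample size {size} exceeds subset size {len(idx)}")
        fracs = []
        for _ in range(n_repeats):
            sub = rng.choice(idx, size=size, replace=False)
            fracs.append(match_subset(model, pmsa, sub, tok).matched_fraction)
        fracs = np.array(fracs)
        rows.append({
            "size": size,
            "matched_fraction": float(fracs.mean()),
            "stderr": float(fracs.std(ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 else 0.0,
            "random_baseline": 1.0 / size,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# mutual information estimate
# --------------------------------------------------------------------------

def mi_estimate(paired_model, shuffled_model, src_tokens: np.ndarray,
                tgt_tokens: np.ndarray, per_position: bool = False) -> float:
    """Mean validation log-likelihood gap between a model trained on true
    pairs and one trained on shuffled pairs, in nats per sequence.

    The shuffled model sees no source/target correlation, so its conditional
    approximates the target marginal and the gap estimates MI(A; B).  With
    ``per_position=True`` the gap is normalized by Nout.
    """
    if src_tokens.shape[0] != tgt_tokens.shape[0]:
        raise ValueError("source/target row mismatch")
    ll_p = batch_logliks(paired_model, src_tokens, tgt_tokens)
    ll_s = batch_logliks(shuffled_model, src_tokens, tgt_tokens)
    gap = float((ll_p - ll_s).mean())
    return gap / tgt_tokens.shape[1] if per_position else gap
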