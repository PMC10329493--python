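"""Shallow autoregressive coupling model (arDCA-style baseline).

The concatenated pair (B, A) is modeled left to right with the source fully
preceding the target, so each target position i has an exact softmax
conditional over the 21 residue symbols,

    P(a_i | B, a_<i) = softmax( h_i(a) + sum_{j < Nin + i} J_{i,j}(a, s_j) ),

where s is the concatenated sequence.  Fields h and couplings J are fit by
L2-regularized maximum conditional likelihood with a quasi-Newton optimizer;
the parameter count grows quadratically with Nin + Nout, in contrast to the
length-independent Transformer.

Only the target conditionals are modeled (the source is always observed), and
positions keep their natural alignment order.  ``site_order`` permutes the
target positions for experiments with entropy-style orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_softmax as sp_log_softmax

from .alphabet import Tokenizer
from .pmsa import PairedMSA

Q = 21  # residue alphabet size


@dataclass
class ArdcaParams:
    """Fields ``h[i, a]`` and couplings ``J[i, j, a, b]`` for target position i,
    context position j (0 <= j < Nin + i over the concatenated sequence).

    ``site_order`` permutes the autoregressive order of the *target* positions
    (index i runs over ``site_order``); None means natural alignment order.
    """

    Nin: int
    Nout: int
    h: np.ndarray          # (Nout, Q)
    J: np.ndarray          # (Nout, Nin + Nout - 1, Q, Q); entries with j >= Nin+i unused
    l2_lambda: float = 0.01
    site_order: list[int] | None = None

    @classmethod
    def zeros(cls, Nin: int, Nout: int, l2_lambda: float = 0.01) -> "ArdcaParams":
        return cls(Nin, Nout, np.zeros((Nout, Q)),
                   np.zeros((Nout, Nin + Nout - 1, Q, Q)), l2_lambda)

    @property
    def n_parameters(self) -> int:
        return self.h.size + sum((self.Nin + i) * Q * Q for i in range(self.Nout))


def _context_logits(params: ArdcaParams, ctx_onehot: np.ndarray, i: int) -> np.ndarray:
    """Logits for target position i given one-hot context (M, Nin+i, Q)."""
    nctx = params.Nin + i
    return params.h[i] + np.einsum("jab,mjb->ma", params.J[i, :nctx], ctx_onehot,
                                   optimize=True)


def _onehot(tokens: np.ndarray) -> np.ndarray:
    return np.eye(Q)[tokens]


def ardca_conditional(params: ArdcaParams, source_tokens, target_prefix_tokens,
                      i: int) -> np.ndarray:
    """Distribution over the 21 symbols at target position i; sums to 1 exactly."""
    src = np.asarray(source_tokens)
    pre = np.asarray(target_prefix_tokens)
    if i >= params.Nout:
        raise ValueError(f"position {i} out of range for Nout={params.Nout}")
    if len(pre) != i:
        raise ValueError(f"prefix length {len(pre)} != position {i}")
    if len(src) != params.Nin:
        raise ValueError(f"source length {len(src)} != Nin={params.Nin}")
    ctx = _onehot(np.concatenate([src, pre]).astype(np.int64))[None]
    logits = _context_logits(params, ctx, i)[0]
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def _nll_and_grad(x: np.ndarray, X: np.ndarray, tgt: np.ndarray,
                  Nin: int, Nout: int, lam: float):
    """Mean NLL + (lam/M) * (||J||^2 + ||h||^2), with analytic gradient.

    ``X`` is the one-hot concatenated data (M, Nin+Nout, Q); the L2 penalty is
    applied to the summed log-likelihood objective, i.e. lam * ||.||^2 against
    sum_l log P, which per-sample is lam/M.
    """
    M = X.shape[0]
    h = x[: Nout * Q].reshape(Nout, Q)
    J = x[Nout * Q:].reshape(Nout, Nin + Nout - 1, Q, Q)
    gh = np.zeros_like(h)
    gJ = np.zeros_like(J)
    nll = 0.0
    for i in range(Nout):
        nctx = Nin + i
        ctx = X[:, :nctx]
        logits = h[i] + np.einsum("jab,mjb->ma", J[i, :nctx], ctx, optimize=True)
        lp = sp_log_softmax(logits, axis=1)
        nll -= lp[np.arange(M), tgt[:, i]].sum()
        d = np.exp(lp)
        d[np.arange(M), tgt[:, i]] -= 1.0       # dNLL/dlogits
        gh[i] = d.sum(axis=0)
        gJ[i, :nctx] = np.einsum("ma,mjb->jab", d, ctx, optimize=True)
    obj = nll / M + (lam / M) * (np.sum(h * h) + np.sum(J * J))
    gh = gh / M + (2 * lam / M) * h
    gJ = gJ / M + (2 * lam / M) * J
    return obj, np.concatenate([gh.ravel(), gJ.ravel()])


def ardca_fit(pmsa_train: PairedMSA, l2_lambda: float = 0.01, seed: int = 0,
              tokenizer: Tokenizer | None = None, max_iter: int = 500,
              tol: float = 1e-7, site_order: list[int] | None = None) -> "ArdcaModel":
    """Fit fields and couplings by maximum conditional likelihood (L-BFGS).

    Deterministic: the optimizer starts from zero parameters, so ``seed`` only
    enters bookkeeping.  The recorded objective history is non-increasing up
    to line-search tolerance.  ``site_order`` permutes the target positions'
    autoregressive order (default: natural alignment order, for comparability
    with the Transformer).
    """
    if pmsa_train.M < 2:
        raise ValueError("arDCA fitting needs at least 2 training rows")
    tok = tokenizer or Tokenizer()
    Nin, Nout = pmsa_train.Nin, pmsa_train.Nout
    if site_order is not None and sorted(site_order) != list(range(Nout)):
        raise ValueError(f"site_order must permute 0..{Nout - 1}")
    src = np.array([tok.encode(s) for s in pmsa_train.source_seqs], dtype=np.int64)
    tgt = np.array([tok.encode(s) for s in pmsa_train.target_seqs], dtype=np.int64)
    if site_order is not None:
        tgt = tgt[:, site_order]
    X = _onehot(np.concatenate([src, tgt], axis=1))
    x0 = np.zeros(Nout * Q + Nout * (Nin + Nout - 1) * Q * Q)
    history: list[float] = []

    def fun(x):
        obj, grad = _nll_and_grad(x, X, tgt, Nin, Nout, l2_lambda)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"non-finite arDCA objective (lambda={l2_lambda}); aborting fit")
        return obj, grad

    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   callback=lambda xk: history.append(fun(xk)[0]),
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8})
    params = ArdcaParams(
        Nin, Nout,
        res.x[: Nout * Q].reshape(Nout, Q).copy(),
        res.x[Nout * Q:].reshape(Nout, Nin + Nout - 1, Q, Q).copy(),
        l2_lambda,
        site_order=list(site_order) if site_order is not None else None,
    )
    return ArdcaModel(params, tok, objective_history=history, seed=seed)


def ardca_loglik(params: ArdcaParams, source_tokens, target_tokens) -> float:
    """log P(A|B): sum of position-wise log conditionals."""
    src = np.asarray(source_tokens)
    tgt = np.asarray(target_tokens)
    total = 0.0
    for i in range(params.Nout):
        p = ardca_conditional(params, src, tgt[:i], i)
        total += float(np.log(p[tgt[i]]))
    return total


def ardca_sample(params: ArdcaParams, source_tokens: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Ancestral sampling of target rows given a batch of sources, (M, Nout)."""
    src = np.atleast_2d(source_tokens).astype(np.int64)
    M = src.shape[0]
    ctx = _onehot(src)
    out = np.empty((M, params.Nout), dtype=np.int64)
    for i in range(params.Nout):
        logits = _context_logits(params, ctx, i)
        lp = sp_log_softmax(logits, axis=1)
        p = np.exp(lp)
        u = rng.random((M, 1))
        choice = (p.cumsum(axis=1) < u).sum(axis=1).clip(max=Q - 1)
        out[:, i] = choice
        ctx = np.concatenate([ctx, _onehot(choice)[:, None, :]], axis=1)
    return out


@dataclass
class ArdcaModel:
    """Fitted arDCA baseline exposing the shared evaluation contract."""

    params: ArdcaParams
    tokenizer: Tokenizer
    objective_history: list[float] = field(default_factory=list)
    seed: int = 0

    def conditional_logprobs(self, src_tokens: np.ndarray,
                             tgt_tokens: np.ndarray) -> np.ndarray:
        """Teacher-forced log P(a | B, a_<i) over 21 symbols, (B, Nout, 21).

        Rows are exactly normalized over the residue alphabet (arDCA has no
        special tokens).  With a fitted ``site_order`` the conditionals follow
        that autoregressive order; rows are returned in alignment order.
        """
        src = np.atleast_2d(src_tokens)
        tgt = np.atleast_2d(tgt_tokens)
        order = self.params.site_order or list(range(self.params.Nout))
        X = _onehot(np.concatenate([src, tgt[:, order]], axis=1).astype(np.int64))
        out = np.empty((src.shape[0], self.params.Nout, Q))
        for i, pos in enumerate(order):
            logits = _context_logits(self.params, X[:, : self.params.Nin + i], i)
            out[:, pos] = sp_log_softmax(logits, axis=1)
        return out

    def save(self, path) -> None:
        import json
        meta = {"Nin": self.params.Nin, "Nout": self.params.Nout,
                "l2_lambda": self.params.l2_lambda, "seed": self.seed,
                "site_order": self.params.site_order,
                "tokenizer_hash": self.tokenizer.hash(), "kind": "ardca"}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 h=self.params.h, J=self.params.J)

    @classmethod
    def load(cls, path, tokenizer: Tokenizer) -> "ArdcaModel":
        import json
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta["tokenizer_hash"] != tokenizer.hash():
                raise ValueError("checkpoint tokenizer hash mismatch; refusing to load")
            params = ArdcaParams(meta["Nin"], meta["Nout"], z["h"].copy(),
                                 z["J"].copy(), meta["l2_lambda"],
                                 site_order=meta.get("site_order"))
        return cls(params, tokenizer, seed=meta["seed"])
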