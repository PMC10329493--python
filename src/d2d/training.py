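"""Teacher-forced training with optional entropic (Gumbel-softmax) regularization.

The base objective is the per-position cross-entropy of the true target given
the source.  The entropic regularizer draws, for every training pair (A, B),
S relaxed target sequences from the model's own teacher-forced conditionals
via Gumbel-softmax and computes the log-softmax contrast between the data
log-likelihood R_l and the sampled-sequence log-likelihoods R_{l,k},

    R_ent(A, B) = R_l - log( exp(R_l) + sum_k exp(R_{l,k}) ),

adding the (S+1)-way softmax cross-entropy -R_ent >= 0, scaled by alpha, to
the loss.  The term penalizes states in which the model's own samples score
very differently from the data (equivalently, it maximizes the conditional
Renyi entropy of order 2), suppressing the overconfident conditionals that
drive perplexity overfitting on small families.  Sampling conditions each
position on the *true* preceding residues, so all S relaxed sequences come
from the one teacher-forced pass; their exact likelihoods are then evaluated
in a second, differentiable decoder pass conditioned on the samples
themselves.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from . import _autodiff as ad
from ._autodiff import Adam, Tensor
from .alphabet import Tokenizer
from .models import TransformerModel
from .pmsa import PairedMSA, encode
from . import evaluation


@dataclass
class TrainConfig:
    """Optimization and regularization knobs.

    ``alpha = 0`` disables the entropic regularizer entirely (no sampling is
    performed).  When enabled, the standard setting is ``alpha = 0.7`` with
    ``S = 5`` samples per input.
    """

    batch_size: int = 32
    epochs: int = 50
    learning_rate: float = 5e-4
    optimizer: str = "adam"
    alpha: float = 0.0
    S: int = 5
    gumbel_tau: float = 1.0
    seed: int = 0
    weight_decay: float = 0.0
    dropout: float | None = None
    early_stop_patience: int | None = None
    straight_through: bool = False

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if self.gumbel_tau <= 0:
            raise ValueError("gumbel_tau must be positive")


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_perplexity: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    r_ent_mean: list[float] = field(default_factory=list)
    wall_time: list[float] = field(default_factory=list)
    best_epoch: int | None = None


def cross_entropy_loss(logprob_rows, target_out_tokens):
    """Mean negative log-probability of the targets over positions and batch.

    Accepts either a tape :class:`Tensor` (training) or a plain array
    (evaluation); rows are log-distributions over the full token set.
    """
    if isinstance(logprob_rows, Tensor):
        return -(ad.gather_last(logprob_rows, target_out_tokens)).mean()
    picked = np.take_along_axis(logprob_rows, target_out_tokens[..., None], axis=-1)
    return float(-picked.mean())


def entropic_reg_term(R_l: float, R_samples) -> float:
    """R_ent = R_l - logsumexp([R_l, R_1..R_S]); always in (-inf, 0]."""
    vals = np.concatenate([[R_l], np.asarray(R_samples, dtype=float)])
    return float(R_l - logsumexp(vals))


def _gumbel_noise(rng: np.random.Generator, shape, dtype):
    u = rng.random(shape)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return (-np.log(-np.log(u))).astype(dtype)


def _reg_terms(model, mem: Tensor, logp: Tensor, tgt_out: np.ndarray,
               Nout: int, S: int, tau: float, rng: np.random.Generator,
               straight_through: bool = False, drop_rng=None):
    """In-graph R_l, stacked [R_l, R_{l,k}] and relaxed samples.

    Sampling: for every position i a relaxed one-hot is drawn by
    Gumbel-softmax from the model's conditional at i given the *true* prefix
    (all positions in parallel, from the already-computed teacher-forced rows
    ``logp``; the softmax is shift-invariant, so the unrenormalized residue
    rows serve as logits).  Scoring: the sampled sequences' log-likelihoods
    R_{l,k} = log P(A^{l,k} | B^l) are evaluated in a second decoder pass
    teacher-forced on the relaxed samples themselves, with the relaxed
    vectors entering through linearly mixed embeddings so the whole term is
    differentiable with respect to the model parameters.  With
    ``straight_through`` the forward value is snapped to the exact Gumbel-max
    one-hot while gradients follow the soft relaxation.
    """
    n_res = model.tokenizer.n_residues
    T = logp.shape[0]
    lp_res = logp[:, :Nout, :n_res]                      # (T, Nout, 21)
    ll_rows = ad.gather_last(logp, tgt_out)              # (T, Nout+1)
    R_l = ll_rows[:, :Nout].sum(axis=1)                  # (T,)
    relaxed = []
    for _ in range(S):
        g = _gumbel_noise(rng, lp_res.shape, lp_res.data.dtype)
        y = ad.softmax((lp_res + g) * (1.0 / tau), axis=-1)
        if straight_through:
            hard = np.zeros_like(y.data)
            np.put_along_axis(hard, y.data.argmax(axis=-1)[..., None], 1.0, axis=-1)
            y = y + (hard - y.data)     # forward hard, backward soft
        relaxed.append(y)
    y_all = ad.concat(relaxed, axis=0)                   # (S*T, Nout, 21)
    mem_all = ad.concat([mem] * S, axis=0)               # (S*T, Nin, d)
    dec_in = model.relaxed_decoder_input(y_all)
    logp2 = model.decode(mem_all, dec_in, drop_rng)      # (S*T, Nout, V)
    R_flat = (y_all * logp2[:, :, :n_res]).sum(axis=(1, 2))
    R_samples = R_flat.reshape(S, T).swapaxes(0, 1)      # (T, S)
    stackedR = ad.concat([R_l.reshape(T, 1), R_samples], axis=1)   # (T, S+1)
    return R_l, stackedR, relaxed


def gumbel_teacher_forced_samples(model: TransformerModel, source_tokens,
                                  true_target_tokens, S: int, tau: float,
                                  seed: int):
    """Draw S relaxed target sequences per input, teacher-forced on the true
    prefix, and return them with their log-likelihoods.

    Returns ``(relaxed, R_samples, R_l)`` where ``relaxed`` is a list of S
    tape tensors of shape (T, Nout, 21), ``R_samples`` a (T, S) tensor of
    sampled-sequence log-likelihoods and ``R_l`` the (T,) data log-likelihood.
    The computation is differentiable with respect to the model parameters.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if S < 1:
        raise ValueError("S must be >= 1")
    tok = model.tokenizer
    src = np.atleast_2d(source_tokens)
    tgt = np.atleast_2d(true_target_tokens)
    T, Nout = tgt.shape
    sos = np.full((T, 1), tok.sos_id, dtype=np.int64)
    eos = np.full((T, 1), tok.eos_id, dtype=np.int64)
    mem = model.encode_source(src)
    logp = model.decode(mem, model._embed(np.concatenate([sos, tgt], axis=1)))
    rng = np.random.default_rng(seed)
    R_l, stackedR, relaxed = _reg_terms(
        model, mem, logp, np.concatenate([tgt, eos], axis=1), Nout, S, tau, rng)
    return relaxed, stackedR[:, 1:], R_l


class DivergenceError(RuntimeError):
    pass


def train(model: TransformerModel, pmsa: PairedMSA, split, cfg: TrainConfig,
          tokenizer: Tokenizer | None = None):
    """Train a Transformer on the training rows of ``split``.

    Total loss per batch is ``CE + alpha * mean(R_ent)``.  Returns the model
    (parameters of the best-validation-perplexity epoch when early stopping is
    enabled, final epoch otherwise) and a :class:`TrainHistory`.
    """
    tok = tokenizer or model.tokenizer
    if cfg.dropout is not None:
        model.config.dropout = cfg.dropout
    batch_all = encode(pmsa, tok, split.train_idx)
    val_idx = split.val_idx
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    hist = TrainHistory()
    n_train = batch_all.batch_size
    Nout = pmsa.Nout
    best_pp, best_state, patience_left = np.inf, None, cfg.early_stop_patience
    last_good = None

    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n_train)
        losses, rents = [], []
        for lo in range(0, n_train, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            src = batch_all.source_tokens[idx]
            tin = batch_all.target_in_tokens[idx]
            tout = batch_all.target_out_tokens[idx]
            drop_rng = rng if model.config.dropout > 0 else None
            mem = model.encode_source(src, drop_rng)
            logp = model.decode(mem, model._embed(tin), drop_rng)
            loss = cross_entropy_loss(logp, tout)
            if cfg.alpha > 0:
                _, stackedR, _ = _reg_terms(model, mem, logp, tout, Nout,
                                            cfg.S, cfg.gumbel_tau, rng,
                                            cfg.straight_through, drop_rng)
                r_ent = ad.log_softmax(stackedR, axis=-1)[:, 0]
                rents.append(float(r_ent.data.mean()))
                # The penalty is the (S+1)-way softmax cross-entropy of
                # identifying the true sequence among the model's own
                # samples, i.e. -R_ent >= 0.  It is bounded below, vanishes
                # once true and sampled sequences score alike, and maximizes
                # the conditional Renyi-2 entropy; the opposite orientation
                # (+R_ent) is unbounded below and demonstrably diverges.
                loss = loss - cfg.alpha * r_ent.mean()
            lval = loss.item()
            if not np.isfinite(lval):
                if last_good is not None:
                    _restore(model, last_good)
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}; restored last good checkpoint")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lval)
        last_good = _snapshot(model)

        hist.epochs.append(epoch)
        hist.train_loss.append(float(np.mean(losses)))
        hist.r_ent_mean.append(float(np.mean(rents)) if rents else 0.0)
        stop = False
        if val_idx:
            rep = evaluation.metrics_report(model, pmsa, val_idx, tok, "val")
            hist.val_perplexity.append(rep.perplexity)
            hist.val_accuracy.append(rep.accuracy)
            if rep.perplexity < best_pp:
                best_pp = rep.perplexity
                hist.best_epoch = epoch
                best_state = _snapshot(model)
                patience_left = cfg.early_stop_patience
            elif cfg.early_stop_patience is not None:
                patience_left -= 1
                stop = patience_left <= 0
        else:
            hist.val_perplexity.append(np.nan)
            hist.val_accuracy.append(np.nan)
        hist.wall_time.append(time.perf_counter() - t0)
        if stop:
            break

    if cfg.early_stop_patience is not None and best_state is not None:
        _restore(model, best_state)
    return model, hist


def _snapshot(model):
    return {k: p.data.copy() for k, p in model._params.items()}


def _restore(model, state):
    for k, p in model._params.items():
        p.data = state[k].copy()
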