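"""Synthetic paired MSAs with planted, analytically known inter-domain
dependence.

The generator is a latent-class model: each row draws a hidden interaction
class c, a handful of *informative* columns on each domain draw symbols from
class-specific distributions, and all other columns draw i.i.d. from a
background distribution.  Source and target are conditionally independent
given the class, so the per-sequence-pair mutual information MI(A; B) is
exactly computable — it reaches H(class) when the informative columns
identify the class on both sides.  This gives a hard oracle for the
log-likelihood-gap MI estimate and for matching specificity.

An optional "phylogeny" mode emulates the clustered redundancy of real MSAs:
rows are copies of a small number of cluster ancestors with per-site
mutations, which is what the near/far Hamming stratification is designed to
expose.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .alphabet import Tokenizer
from .pmsa import PairedMSA

MAX_INFORMATIVE = 4  # keeps exhaustive MI summation trivial


class SpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Generative recipe for a coupled paired MSA.

    ``source_dists`` / ``target_dists`` have shape (K, n_cols, 21): one symbol
    distribution per class per informative column.  The background includes
    the gap symbol by default, mirroring real alignments.
    """

    Nin: int
    Nout: int
    M: int
    K: int
    class_probs: np.ndarray
    source_informative_cols: list[int]
    target_informative_cols: list[int]
    source_dists: np.ndarray
    target_dists: np.ndarray
    background_dist: np.ndarray
    phylo: bool = False
    n_clusters: int = 20
    mu: float = 0.1
    seed: int = 0

    def __post_init__(self):
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        self.source_dists = np.asarray(self.source_dists, dtype=float)
        self.target_dists = np.asarray(self.target_dists, dtype=float)
        self.background_dist = np.asarray(self.background_dist, dtype=float)
        if self.class_probs.shape != (self.K,) or abs(self.class_probs.sum() - 1) > 1e-9:
            raise SpecError("class_probs must be a length-K distribution")
        for name, cols, N in (("source", self.source_informative_cols, self.Nin),
                              ("target", self.target_informative_cols, self.Nout)):
            if len(cols) > MAX_INFORMATIVE:
                raise SpecError(f"at most {MAX_INFORMATIVE} informative columns per domain")
            if len(set(cols)) != len(cols) or any(not 0 <= c < N for c in cols):
                raise SpecError(f"bad {name} informative column list {cols}")
        for name, d, ncols in (("source_dists", self.source_dists,
                                len(self.source_informative_cols)),
                               ("target_dists", self.target_dists,
                                len(self.target_informative_cols))):
            if d.shape != (self.K, ncols, 21):
                raise SpecError(f"{name} must have shape (K, n_cols, 21), got {d.shape}")
            if ncols and (np.any(d < 0) or np.abs(d.sum(axis=-1) - 1).max() > 1e-9):
                raise SpecError(f"{name} rows must be distributions")
        if self.background_dist.shape != (21,) or abs(self.background_dist.sum() - 1) > 1e-9:
            raise SpecError("background_dist must be a length-21 distribution")

    # ---------------------------------------------------------------- recipes
    @classmethod
    def coupled(cls, Nin: int = 8, Nout: int = 8, M: int = 5000, K: int = 2,
                noise: float = 0.0, phylo: bool = False, n_clusters: int = 40,
                mu: float = 0.1, seed: int = 0) -> "SyntheticSpec":
        """Symmetric K-class family with one informative column per domain.

        Class c writes residue symbol c on the informative column with
        probability ``1 - noise`` (rest spread uniformly over the other
        symbols); the background is uniform over all 21 symbols.  With
        ``noise=0`` and equal class probabilities the planted per-sequence
        MI is exactly H(class) = log K nats.
        """
        if K > 21:
            raise SpecError("K must be <= 21 for one-column class coding")
        dists = np.full((K, 1, 21), noise / 20.0)
        for c in range(K):
            dists[c, 0, c] = 1.0 - noise
        return cls(
            Nin=Nin, Nout=Nout, M=M, K=K,
            class_probs=np.full(K, 1.0 / K),
            source_informative_cols=[Nin // 2],
            target_informative_cols=[Nout // 2],
            source_dists=dists.copy(),
            target_dists=dists.copy(),
            background_dist=np.full(21, 1.0 / 21),
            phylo=phylo, n_clusters=n_clusters, mu=mu, seed=seed,
        )

    @classmethod
    def independent(cls, Nin: int = 8, Nout: int = 8, M: int = 5000,
                    seed: int = 0, **kw) -> "SyntheticSpec":
        """K=1 control: source and target are statistically independent."""
        return cls(
            Nin=Nin, Nout=Nout, M=M, K=1,
            class_probs=np.array([1.0]),
            source_informative_cols=[], target_informative_cols=[],
            source_dists=np.zeros((1, 0, 21)), target_dists=np.zeros((1, 0, 21)),
            background_dist=np.full(21, 1.0 / 21),
            seed=seed, **kw,
        )


def _sample_domain(rng, n_rows, N, cols, dists, background, classes):
    tok_bg = rng.choice(21, size=(n_rows, N), p=background)
    for ci, col in enumerate(cols):
        for c in np.unique(classes):
            mask = classes == c
            tok_bg[mask, col] = rng.choice(21, size=int(mask.sum()), p=dists[c, ci])
    return tok_bg


def generate(spec: SyntheticSpec) -> tuple[PairedMSA, np.ndarray]:
    """Draw a pMSA from the spec; returns hidden class labels for oracles."""
    rng = np.random.default_rng(spec.seed)
    tok = Tokenizer()
    if not spec.phylo:
        classes = rng.choice(spec.K, size=spec.M, p=spec.class_probs)
        src = _sample_domain(rng, spec.M, spec.Nin, spec.source_informative_cols,
                             spec.source_dists, spec.background_dist, classes)
        tgt = _sample_domain(rng, spec.M, spec.Nout, spec.target_informative_cols,
                             spec.target_dists, spec.background_dist, classes)
    else:
        # ancestors drawn i.i.d. from the model, descendants by per-site mutation
        n_anc = min(spec.n_clusters, spec.M)
        anc_classes = rng.choice(spec.K, size=n_anc, p=spec.class_probs)
        anc_src = _sample_domain(rng, n_anc, spec.Nin, spec.source_informative_cols,
                                 spec.source_dists, spec.background_dist, anc_classes)
        anc_tgt = _sample_domain(rng, n_anc, spec.Nout, spec.target_informative_cols,
                                 spec.target_dists, spec.background_dist, anc_classes)
        cluster = rng.integers(0, n_anc, size=spec.M)
        classes = anc_classes[cluster]
        src = anc_src[cluster].copy()
        tgt = anc_tgt[cluster].copy()
        for arr, N, cols, dists in ((src, spec.Nin, spec.source_informative_cols,
                                     spec.source_dists),
                                    (tgt, spec.Nout, spec.target_informative_cols,
                                     spec.target_dists)):
            mut = rng.random(arr.shape) < spec.mu
            fresh = _sample_domain(rng, spec.M, N, cols, dists,
                                   spec.background_dist, classes)
            arr[mut] = fresh[mut]
    ids = [f"syn{r:06d}" for r in range(spec.M)]
    pmsa = PairedMSA([tok.decode(row) for row in src],
                     [tok.decode(row) for row in tgt], ids)
    return pmsa, classes


def _support_configs(cols, dists, K):
    """Enumerate informative-column configurations with nonzero probability.

    Returns (configs, probs_given_class) where probs_given_class has shape
    (n_configs, K).
    """
    if not cols:
        return [()], np.ones((1, K))
    supports = []
    for ci in range(len(cols)):
        sup = sorted(set(np.nonzero(dists[:, ci].sum(axis=0) > 0)[0].tolist()))
        supports.append(sup)
    configs = list(product(*supports))
    probs = np.ones((len(configs), K))
    for n, cfg in enumerate(configs):
        for ci, sym in enumerate(cfg):
            probs[n] *= dists[:, ci, sym]
    return configs, probs


def analytic_mi(spec: SyntheticSpec) -> float:
    """Exact MI(A; B) in nats per sequence pair, by exhaustive summation over
    class and informative-column configurations (i.i.d. rows only)."""
    if spec.phylo:
        raise SpecError("analytic MI assumes i.i.d. rows (phylo off)")
    pi = spec.class_probs
    _, ps = _support_configs(spec.source_informative_cols, spec.source_dists, spec.K)
    _, pt = _support_configs(spec.target_informative_cols, spec.target_dists, spec.K)
    if ps.shape[0] * pt.shape[0] > 1_000_000:
        raise SpecError("informative-column support too large for exhaustive MI")
    p_s = ps @ pi            # (n_s,)
    p_t = pt @ pi            # (n_t,)
    joint = np.einsum("sk,tk,k->st", ps, pt, pi)
    mask = joint > 0
    ratio = joint[mask] / (np.outer(p_s, p_t)[mask])
    return float(np.sum(joint[mask] * np.log(ratio)))


def shuffle_pairs(pmsa: PairedMSA, seed: int = 0) -> PairedMSA:
    """Break the source/target pairing by permuting target rows uniformly.

    The target multiset is preserved; a derangement is not enforced.  The
    shuffled family is the null control with zero planted dependence.
    """
    if pmsa.M < 2:
        raise ValueError("need at least 2 rows to shuffle")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pmsa.M)
    return PairedMSA(list(pmsa.source_seqs),
                     [pmsa.target_seqs[j] for j in perm],
                     list(pmsa.ids))


def save_labels(classes: np.ndarray, ids, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tclass\n")
        for rid, c in zip(ids, classes):
            fh.write(f"{rid}\t{int(c)}\n")
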