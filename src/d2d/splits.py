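"""Train/validation/test splitting and Hamming-distance stratification.

Random splits ignore phylogeny, so held-out rows may sit next to near-identical
training rows.  To control for that, held-out rows are annotated with their
minimum Hamming distance to the training set and partitioned at the median
into a "near" and a "far" half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pmsa import PairedMSA


class SplitError(ValueError):
    pass


@dataclass
class DataSplit:
    train_idx: list[int]
    val_idx: list[int]
    test_idx: list[int]
    seed: int
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)

    def __post_init__(self):
        parts = [set(self.train_idx), set(self.val_idx), set(self.test_idx)]
        n = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != n:
            raise SplitError("split parts overlap")


@dataclass
class DistanceAnnotation:
    """Per held-out row: distance to the training set and a near/far label."""

    indices: list[int]          # row indices into the pMSA (validation rows)
    min_hamming: list[int]
    near_far_label: list[str]   # "near" | "far"
    median: float


def random_split(M: int, fractions=(0.70, 0.15, 0.15), seed: int = 0) -> DataSplit:
    """Deterministic random split; sizes floor-rounded, remainder to train."""
    if M < 3:
        raise SplitError(f"need M >= 3 to populate all three parts (got {M})")
    f = tuple(float(x) for x in fractions)
    if any(x <= 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
        raise SplitError(f"fractions must be positive and sum to 1 (got {f})")
    n_val = int(np.floor(f[1] * M))
    n_test = int(np.floor(f[2] * M))
    n_val, n_test = max(n_val, 1), max(n_test, 1)
    n_train = M - n_val - n_test
    if n_train < 1:
        raise SplitError(f"M={M} too small for fractions {f}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(M)
    return DataSplit(
        train_idx=sorted(int(i) for i in perm[:n_train]),
        val_idx=sorted(int(i) for i in perm[n_train:n_train + n_val]),
        test_idx=sorted(int(i) for i in perm[n_train + n_val:]),
        seed=seed,
        fractions=f,
    )


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def hamming_to_training(seq: str, training_seqs) -> int:
    """Smallest Hamming distance from ``seq`` to any training sequence.

    Gap/residue mismatches count like any substitution.
    """
    training_seqs = list(training_seqs)
    if not training_seqs:
        raise ValueError("training set is empty")
    L = len(seq)
    q = np.frombuffer(seq.encode(), dtype=np.uint8)
    best = L
    for t in training_seqs:
        if len(t) != L:
            raise ValueError(f"length mismatch: {L} vs {len(t)}")
        d = int(np.count_nonzero(q != np.frombuffer(t.encode(), dtype=np.uint8)))
        if d < best:
            best = d
            if best == 0:
                break
    return best


def _min_hamming_matrix(held: list[str], train: list[str]) -> np.ndarray:
    """Vectorized min-Hamming of each held-out sequence to the training set."""
    H = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in held])
    T = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in train])
    # (n_held, n_train) mismatch counts, chunked over held rows to bound memory
    out = np.empty(len(held), dtype=np.int64)
    step = max(1, 10_000_000 // (T.shape[0] * T.shape[1] + 1))
    for i in range(0, len(held), step):
        block = (H[i:i + step, None, :] != T[None, :, :]).sum(axis=2)
        out[i:i + step] = block.min(axis=1)
    return out


def stratify_by_distance(split: DataSplit, pmsa: PairedMSA, *, on: str = "target",
                         subset: str = "val") -> DistanceAnnotation:
    """Median-split held-out rows by min Hamming distance to the training set.

    ``on`` selects which side the distance is computed on ("target", "source"
    or "pair" for the concatenation); all reported metrics concern the target,
    so "target" is the default.  Ties at the median are labeled "near" so the
    far half is conservatively far.
    """
    held_idx = {"val": split.val_idx, "test": split.test_idx}[subset]
    if not held_idx:
        raise SplitError(f"{subset} set is empty; nothing to stratify")

    def side(i):
        if on == "target":
            return pmsa.target_seqs[i]
        if on == "source":
            return pmsa.source_seqs[i]
        if on == "pair":
            return pmsa.source_seqs[i] + pmsa.target_seqs[i]
        raise ValueError(f"unknown distance side {on!r}")

    train = [side(i) for i in split.train_idx]
    held = [side(i) for i in held_idx]
    dists = _min_hamming_matrix(held, train)
    med = float(np.median(dists))
    labels = ["near" if d <= med else "far" for d in dists]
    # degenerate case: all distances equal -> everything ties to "near";
    # rebalance so |#near - #far| <= 1, stable in row order
    if len(held_idx) >= 2 and ("far" not in labels or "near" not in labels):
        order = np.argsort(dists, kind="stable")
        n_near = int(np.ceil(len(held_idx) / 2))
        labels = ["far"] * len(held_idx)
        for r in order[:n_near]:
            labels[r] = "near"
    return DistanceAnnotation(
        indices=list(held_idx),
        min_hamming=[int(d) for d in dists],
        near_far_label=labels,
        median=med,
    )


def save_split(split: DataSplit, ann: DistanceAnnotation | None, ids, path) -> None:
    """Persist a split as (id, part, min_hamming) delimited text."""
    dist = {}
    if ann is not None:
        dist = {i: (d, lab) for i, d, lab in
                zip(ann.indices, ann.min_hamming, ann.near_far_label)}
    with open(path, "w") as fh:
        fh.write("id\tpart\tmin_hamming\n")
        for part, idxs in (("train", split.train_idx), ("val", split.val_idx),
                           ("test", split.test_idx)):
            for i in idxs:
                if i in dist:
                    d, lab = dist[i]
                    fh.write(f"{ids[i]}\t{part}_{lab}\t{d}\n")
                else:
                    fh.write(f"{ids[i]}\t{part}\tNA\n")
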