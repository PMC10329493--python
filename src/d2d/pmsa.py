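"""Paired multiple sequence alignments (pMSAs): containers and FASTA I/O.

A pMSA holds M rows, each pairing an aligned *source* domain sequence of fixed
length ``Nin`` with an aligned *target* domain sequence of fixed length
``Nout``.  Two on-disk dialects are supported: two parallel aligned FASTA files
(paired by record id when ids match, else by position), and a single
concatenated alignment with a declared split column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import Tokenizer


class PmsaFormatError(ValueError):
    """Malformed pMSA input (ragged alignment, unpaired ids, bad split)."""


@dataclass
class PairedMSA:
    """M aligned (source, target) sequence pairs with fixed per-family lengths."""

    source_seqs: list[str]
    target_seqs: list[str]
    ids: list[str]

    def __post_init__(self):
        if len(self.source_seqs) != len(self.target_seqs) or len(self.ids) != len(self.source_seqs):
            raise PmsaFormatError("source, target and id lists must have equal length")
        if self.M < 1:
            raise PmsaFormatError("a pMSA needs at least one row")
        if len(set(self.ids)) != self.M:
            raise PmsaFormatError("record ids must be unique")
        for name, seqs, L in (("source", self.source_seqs, self.Nin),
                              ("target", self.target_seqs, self.Nout)):
            for rid, s in zip(self.ids, seqs):
                if len(s) != L:
                    raise PmsaFormatError(
                        f"ragged alignment: {name} record {rid!r} has length "
                        f"{len(s)}, expected {L}"
                    )

    @property
    def M(self) -> int:
        return len(self.source_seqs)

    @property
    def Nin(self) -> int:
        return len(self.source_seqs[0])

    @property
    def Nout(self) -> int:
        return len(self.target_seqs[0])

    def subset(self, indices) -> "PairedMSA":
        idx = list(indices)
        return PairedMSA([self.source_seqs[i] for i in idx],
                         [self.target_seqs[i] for i in idx],
                         [self.ids[i] for i in idx])

    def __eq__(self, other):
        return (isinstance(other, PairedMSA)
                and self.source_seqs == other.source_seqs
                and self.target_seqs == other.target_seqs
                and self.ids == other.ids)


@dataclass
class EncodedBatch:
    """Token matrices for teacher-forced training/evaluation.

    ``target_in`` is the SOS-prefixed decoder input; ``target_out`` the
    EOS-suffixed prediction targets, shifted by one position relative to
    ``target_in``.  Fixed alignment lengths mean no PAD tokens appear.
    """

    source_tokens: np.ndarray      # (T, Nin) int
    target_in_tokens: np.ndarray   # (T, Nout+1) int, starts with SOS
    target_out_tokens: np.ndarray  # (T, Nout+1) int, ends with EOS

    @property
    def batch_size(self) -> int:
        return self.source_tokens.shape[0]


def _read_fasta(path) -> list[tuple[str, str]]:
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise PmsaFormatError(f"no FASTA records found in {path}")
    return records


def _check_lengths(records, path):
    L = len(records[0][1])
    for rid, s in records:
        if len(s) != L:
            raise PmsaFormatError(
                f"ragged alignment in {path}: record {rid!r} has length "
                f"{len(s)}, expected {L}"
            )
    return L


def read_pmsa(source_path, target_path, tokenizer: Tokenizer | None = None) -> PairedMSA:
    """Read a two-file pMSA, pairing records by id when possible.

    If the two files share exactly the same id set, rows are paired by id and
    ordered as in the source file; otherwise pairing falls back to file order
    with a warning.  Symbols are case-normalized and validated against the
    21-letter alphabet.
    """
    tok = tokenizer or Tokenizer()
    src = _read_fasta(source_path)
    tgt = _read_fasta(target_path)
    _check_lengths(src, source_path)
    _check_lengths(tgt, target_path)

    src_ids = [rid for rid, _ in src]
    tgt_ids = [rid for rid, _ in tgt]
    if set(src_ids) == set(tgt_ids) and len(set(src_ids)) == len(src_ids):
        tgt_by_id = dict(tgt)
        pairs = [(rid, s, tgt_by_id[rid]) for rid, s in src]
    else:
        only_src = set(src_ids) - set(tgt_ids)
        only_tgt = set(tgt_ids) - set(src_ids)
        if len(src) != len(tgt):
            raise PmsaFormatError(
                "cannot pair records: id sets differ and record counts differ "
                f"(unmatched source ids: {sorted(only_src)[:5]}; "
                f"unmatched target ids: {sorted(only_tgt)[:5]})"
            )
        warnings.warn(
            "source/target ids do not match; pairing records by file position",
            stacklevel=2,
        )
        pairs = [(rid, s, t) for (rid, s), (_, t) in zip(src, tgt)]

    ids = [p[0] for p in pairs]
    sources = [tok.normalize(p[1], context=f"source record {p[0]!r}") for p in pairs]
    targets = [tok.normalize(p[2], context=f"target record {p[0]!r}") for p in pairs]
    return PairedMSA(sources, targets, ids)


def read_concatenated_pmsa(path, split_col: int,
                           tokenizer: Tokenizer | None = None) -> PairedMSA:
    """Read a single concatenated alignment; columns ``[0, split_col)`` are the
    source domain, the rest the target domain."""
    tok = tokenizer or Tokenizer()
    records = _read_fasta(path)
    L = _check_lengths(records, path)
    if not 0 < split_col < L:
        raise ValueError(
            f"split_col must be strictly inside the alignment (got {split_col} "
            f"for alignment length {L})"
        )
    ids = [rid for rid, _ in records]
    sources = [tok.normalize(s[:split_col], context=f"record {rid!r}")
               for rid, s in records]
    targets = [tok.normalize(s[split_col:], context=f"record {rid!r}")
               for rid, s in records]
    return PairedMSA(sources, targets, ids)


def write_pmsa(pmsa: PairedMSA, source_path, target_path) -> None:
    """Write the two aligned FASTA files; inverse of :func:`read_pmsa`."""
    for path, seqs in ((source_path, pmsa.source_seqs), (target_path, pmsa.target_seqs)):
        recs = [SeqRecord(Seq(s), id=rid, description="")
                for rid, s in zip(pmsa.ids, seqs)]
        SeqIO.write(recs, str(path), "fasta")


def write_concatenated_pmsa(pmsa: PairedMSA, path) -> None:
    recs = [SeqRecord(Seq(s + t), id=rid, description="")
            for rid, s, t in zip(pmsa.ids, pmsa.source_seqs, pmsa.target_seqs)]
    SeqIO.write(recs, str(path), "fasta")


def encode(pmsa: PairedMSA, tok: Tokenizer, indices=None) -> EncodedBatch:
    """Tokenize rows of a pMSA into teacher-forcing matrices.

    The decoder input is SOS-prefixed and the prediction target EOS-suffixed,
    so the same contract extends to variable-length decoding even though
    aligned families have fixed lengths.
    """
    if indices is None:
        indices = range(pmsa.M)
    idx = list(indices)
    src = np.array([tok.encode(pmsa.source_seqs[i]) for i in idx], dtype=np.int64)
    tgt = np.array([tok.encode(pmsa.target_seqs[i]) for i in idx], dtype=np.int64)
    T = len(idx)
    sos = np.full((T, 1), tok.sos_id, dtype=np.int64)
    eos = np.full((T, 1), tok.eos_id, dtype=np.int64)
    return EncodedBatch(
        source_tokens=src,
        target_in_tokens=np.concatenate([sos, tgt], axis=1),
        target_out_tokens=np.concatenate([tgt, eos], axis=1),
    )
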