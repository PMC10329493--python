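"""Residue alphabet and token mapping for aligned protein domain sequences.

The sequence alphabet is the 20 standard amino acids plus the alignment gap
``'-'`` (21 symbols).  Three special tokens — start-of-sequence, end-of-sequence
and padding — are appended after the residues, giving 24 token ids in total.
Gaps are ordinary residues: they are predicted, scored and sampled like any
amino acid.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

RESIDUES = "ACDEFGHIKLMNPQRSTVWY-"


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the 21-letter residue alphabet."""


@dataclass(frozen=True)
class Tokenizer:
    """Bijection between residue symbols and integer token ids.

    Residues occupy ids ``0..20`` in the fixed order :data:`RESIDUES`;
    SOS, EOS and PAD follow at 21, 22 and 23.
    """

    symbols: str = RESIDUES
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(self.symbols) != 21 or len(set(self.symbols)) != 21:
            raise ValueError("tokenizer requires exactly 21 distinct residue symbols")
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.symbols)})

    # --- vocabulary layout -------------------------------------------------
    @property
    def n_residues(self) -> int:
        return 21

    @property
    def sos_id(self) -> int:
        return 21

    @property
    def eos_id(self) -> int:
        return 22

    @property
    def pad_id(self) -> int:
        return 23

    @property
    def total_tokens(self) -> int:
        return 24

    # --- encode / decode ---------------------------------------------------
    def normalize(self, seq: str, *, context: str = "") -> str:
        """Uppercase and map ``'.'`` to ``'-'``; reject anything else foreign.

        Ambiguity codes (B/J/O/U/X/Z) are rejected: the model vocabulary is
        exactly the 21 unambiguous symbols.
        """
        out = []
        for pos, ch in enumerate(seq):
            c = ch.upper()
            if c == ".":
                c = "-"
            if c not in self._index:
                where = f" in {context}" if context else ""
                raise AlphabetError(
                    f"invalid symbol {ch!r} at column {pos + 1}{where}; "
                    f"allowed symbols are {self.symbols!r}"
                )
            out.append(c)
        return "".join(out)

    def encode(self, seq: str) -> list[int]:
        return [self._index[c] for c in self.normalize(seq)]

    def decode(self, tokens) -> str:
        out = []
        for t in tokens:
            t = int(t)
            if not 0 <= t < self.n_residues:
                raise ValueError(f"token id {t} is not a residue id (0..20)")
            out.append(self.symbols[t])
        return "".join(out)

    def hash(self) -> str:
        """Stable digest of the vocabulary layout, stored in checkpoints."""
        return hashlib.sha256(self.symbols.encode()).hexdigest()[:16]
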