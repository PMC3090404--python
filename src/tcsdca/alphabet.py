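"""Residue alphabet shared by every matrix and tensor in the package.

All frequency tables, coupling matrices and feature vectors are indexed by
one fixed 21-symbol alphabet: the 20 standard amino acids in alphabetical
one-letter order followed by the gap character ``-`` at index 20.  Keeping a
single canonical order makes every exported matrix directly comparable
across runs and files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHAR: str = "-"

#: characters silently mapped to the gap state (ambiguity/rare codes)
AMBIGUOUS_CHARS: frozenset[str] = frozenset("BZXUO.*")


@dataclass(frozen=True)
class Alphabet:
    """Bijective mapping between residue characters and integer codes.

    Parameters
    ----------
    symbols : str
        Ordered residue characters; the gap must be the last symbol.
    """

    symbols: str = AMINO_ACIDS + GAP_CHAR
    index_of: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        object.__setattr__(
            self, "index_of", {c: i for i, c in enumerate(self.symbols)}
        )

    @property
    def q(self) -> int:
        """Number of states (20 amino acids + gap = 21 by default)."""
        return len(self.symbols)

    @property
    def gap_index(self) -> int:
        return self.q - 1

    def encode_char(self, c: str) -> tuple[int, bool]:
        """Encode one character; returns (code, was_ambiguous)."""
        c = c.upper()
        idx = self.index_of.get(c)
        if idx is not None:
            return idx, False
        if c in AMBIGUOUS_CHARS:
            return self.gap_index, True
        raise ValueError(f"unknown residue character {c!r}")

    def decode(self, codes) -> str:
        return "".join(self.symbols[int(i)] for i in codes)


#: module-level default; the order every matrix in this package uses
DEFAULT_ALPHABET = Alphabet()
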