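"""Sequence records: the universal currency passed between pipeline stages.

A :class:`SequenceRecord` is an identified nucleotide or protein sequence.
Residues are stored uppercase; the alphabet is validated at construction so
downstream code can rely on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_NT_CHARS = frozenset("ACGTN")
# 20 standard amino acids plus X (unknown) and * (stop).
_AA_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWY") | frozenset("X*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SequenceRecord:
    """An identified sequence over {A,C,G,T,N} or the amino-acid alphabet.

    Parameters
    ----------
    id:
        Free-text label (strain name, read id, ...).
    residues:
        Non-empty sequence; lowercased input is uppercased.
    alphabet:
        ``"nucleotide"`` or ``"protein"``.
    """

    id: str
    residues: str
    alphabet: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise InputError(f"sequence {self.id!r} is empty")
        if self.alphabet == NUCLEOTIDE:
            allowed = _NT_CHARS
        elif self.alphabet == PROTEIN:
            allowed = _AA_CHARS
        else:
            raise InputError(f"unknown alphabet {self.alphabet!r}")
        bad = set(self.residues) - allowed
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"not in the {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_nucleotide(self) -> bool:
        return self.alphabet == NUCLEOTIDE

    def reverse_complement(self) -> "SequenceRecord":
        """Reverse complement; nucleotide records only."""
        if not self.is_nucleotide:
            raise InputError("reverse_complement requires a nucleotide sequence")
        return SequenceRecord(self.id, self.residues.translate(_COMPLEMENT)[::-1], NUCLEOTIDE)

    def slice1(self, start: int, end: int) -> str:
        """Residues of the 1-based inclusive interval [start, end]."""
        if not (1 <= start <= end <= len(self.residues)):
            raise InputError(
                f"interval [{start},{end}] outside sequence {self.id!r} "
                f"of length {len(self.residues)}"
            )
        return self.residues[start - 1 : end]
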