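"""Global pairwise alignment, percent identity, and translation primitives.

The aligner is a Needleman–Wunsch / Gotoh dynamic program with affine gap
costs, filled by a numba kernel. Traceback tie-breaking is fixed (diagonal,
then up i.e. gap in the second sequence, then left) so that alignments are
bit-reproducible across runs and platforms. Reads can be aligned with free
terminal gaps (semi-global), the natural mode for short amplicons against a
longer reference region.

Percent identity is computed from the alignment columns; ambiguity codes
(``N`` for nucleotides, ``X`` for proteins) never count as matches. Two
denominators are supported: every alignment column, or the columns that
remain after trimming terminal gap runs (the default, so that partial
sequences are not penalised for covering less of the reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Seq import Seq
from numba import njit

from .errors import ComputationError, InputError
from .records import NUCLEOTIDE, PROTEIN, SequenceRecord

NT_ALPHABET = "ACGTN"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX*"

# identity denominator modes
ALL_COLUMNS = "all-columns"
EXCLUDE_TERMINAL_GAPS = "exclude-terminal-gaps"

_NT_INDEX = {c: i for i, c in enumerate(NT_ALPHABET)}
_AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}


def _nt_matrix(match: float, mismatch: float) -> np.ndarray:
    m = np.full((5, 5), mismatch, dtype=np.float64)
    for i in range(4):  # N scores as mismatch against everything, itself included
        m[i, i] = match
    return m


def _blosum62_matrix() -> np.ndarray:
    from Bio.Align import substitution_matrices

    b62 = substitution_matrices.load("BLOSUM62")
    m = np.zeros((len(AA_ALPHABET), len(AA_ALPHABET)), dtype=np.float64)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            m[i, j] = b62[a, b]
    return m


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring parameters.

    Gap penalties are stored as magnitudes: the first residue of a gap run
    costs ``gap_open``, each further residue ``gap_extend``. When
    ``substitution`` is given it overrides match/mismatch (protein scoring
    uses BLOSUM62 values by default).
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 2.0
    gap_extend: float = 0.5
    substitution: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise InputError("gap penalties are magnitudes and must be >= 0")
        if self.substitution is not None:
            s = np.asarray(self.substitution, dtype=np.float64)
            if s.ndim != 2 or s.shape[0] != s.shape[1] or not np.allclose(s, s.T):
                raise InputError("substitution table must be square and symmetric")
            object.__setattr__(self, "substitution", s)

    @classmethod
    def nucleotide_default(cls) -> "ScoringScheme":
        return cls(match=1.0, mismatch=-1.0, gap_open=2.0, gap_extend=0.5)

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        return cls(gap_open=11.0, gap_extend=1.0, substitution=_blosum62_matrix())

    def matrix(self, alphabet: str) -> np.ndarray:
        if self.substitution is not None:
            return self.substitution
        if alphabet == PROTEIN:
            return _blosum62_matrix()
        return _nt_matrix(self.match, self.mismatch)


def default_scheme(alphabet: str) -> ScoringScheme:
    return ScoringScheme.protein_default() if alphabet == PROTEIN else ScoringScheme.nucleotide_default()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences as two gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise InputError("gapped strings must have equal length")

    @property
    def columns(self) -> int:
        return len(self.aligned_a)

    @property
    def matches(self) -> int:
        return self._count(0, self.columns)[0]

    def _count(self, lo: int, hi: int) -> tuple[int, int]:
        """(matches, columns) over column window [lo, hi)."""
        matches = 0
        for x, y in zip(self.aligned_a[lo:hi], self.aligned_b[lo:hi]):
            if x == y and x not in "-NX":
                matches += 1
        return matches, hi - lo

    def _trimmed_window(self) -> tuple[int, int]:
        """Column window with the terminal gap runs of either string removed."""
        a, b = self.aligned_a, self.aligned_b
        lo = 0
        while lo < self.columns and (a[lo] == "-" or b[lo] == "-"):
            lo += 1
        hi = self.columns
        while hi > lo and (a[hi - 1] == "-" or b[hi - 1] == "-"):
            hi -= 1
        return lo, hi

    def identity(self, mode: str = EXCLUDE_TERMINAL_GAPS) -> float:
        return percent_identity(self, mode)

    def ungapped(self) -> tuple[str, str]:
        return self.aligned_a.replace("-", ""), self.aligned_b.replace("-", "")


@njit(cache=True)
def _gotoh_fill(a, b, sub, gap_open, gap_extend, free_ends):  # pragma: no cover - exercised via global_align
    m, n = a.shape[0], b.shape[0]
    NEG = -1e18
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in b (vertical, consumes a)
    Y = np.full((m + 1, n + 1), NEG)  # gap in a (horizontal, consumes b)
    pM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pX = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pY = np.zeros((m + 1, n + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = 0.0 if free_ends else -(gap_open + (i - 1) * gap_extend)
        pX[i, 0] = 1
    for j in range(1, n + 1):
        Y[0, j] = 0.0 if free_ends else -(gap_open + (j - 1) * gap_extend)
        pY[0, j] = 2
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = sub[ai, b[j - 1]]
            # state order encodes the tie-break: diagonal(M)=0 > up(X)=1 > left(Y)=2
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = s + best
            pM[i, j] = ptr

            best = M[i - 1, j] - gap_open
            ptr = 0
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                ptr = 1
            if Y[i - 1, j] - gap_open > best:
                best = Y[i - 1, j] - gap_open
                ptr = 2
            X[i, j] = best
            pX[i, j] = ptr

            best = M[i, j - 1] - gap_open
            ptr = 0
            if X[i, j - 1] - gap_open > best:
                best = X[i, j - 1] - gap_open
                ptr = 1
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                ptr = 2
            Y[i, j] = best
            pY[i, j] = ptr
    return M, X, Y, pM, pX, pY


def _encode(residues: str, alphabet: str) -> np.ndarray:
    index = _AA_INDEX if alphabet == PROTEIN else _NT_INDEX
    return np.fromiter((index[c] for c in residues), dtype=np.int64, count=len(residues))


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    scoring: Optional[ScoringScheme] = None,
    free_end_gaps: bool = False,
) -> PairwiseAlignment:
    """Optimal global (or, with ``free_end_gaps``, semi-global) alignment.

    Raises :class:`InputError` on alphabet mismatch or empty input.
    """
    if a.alphabet != b.alphabet:
        raise InputError(f"alphabet mismatch: {a.alphabet} vs {b.alphabet}")
    if scoring is None:
        scoring = default_scheme(a.alphabet)
    sub = scoring.matrix(a.alphabet)
    ea, eb = _encode(a.residues, a.alphabet), _encode(b.residues, b.alphabet)
    M, X, Y, pM, pX, pY = _gotoh_fill(
        ea, eb, sub, float(scoring.gap_open), float(scoring.gap_extend), free_end_gaps
    )
    m, n = len(ea), len(eb)

    if free_end_gaps:
        # best endpoint anywhere on the bottom row or right column; ties
        # resolved toward the corner, then the longer query prefix, then state
        candidates = [(i, n) for i in range(m + 1)] + [(m, j) for j in range(n)]
        best = None
        for i, j in candidates:
            for state, mat in ((0, M), (1, X), (2, Y)):
                sc = mat[i, j]
                key = (sc, i + j, i, -state)
                if best is None or key > best[0]:
                    best = (key, i, j, state)
        _, ei, ej, state = best
        score = best[0][0]
    else:
        ei, ej = m, n
        state = 0
        score = M[m, n]
        if X[m, n] > score:
            score, state = X[m, n], 1
        if Y[m, n] > score:
            score, state = Y[m, n], 2

    cols_a: list[str] = []
    cols_b: list[str] = []
    # unaligned suffix (free-end mode) rendered as terminal gap columns
    for k in range(m, ei, -1):
        cols_a.append(a.residues[k - 1])
        cols_b.append("-")
    for k in range(n, ej, -1):
        cols_a.append("-")
        cols_b.append(b.residues[k - 1])

    i, j = ei, ej
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:  # free-end boundary reached via M[0,0]
                break
            cols_a.append(a.residues[i - 1])
            cols_b.append(b.residues[j - 1])
            state = pM[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            cols_a.append(a.residues[i - 1])
            cols_b.append("-")
            state = pX[i, j]
            i -= 1
        else:
            cols_a.append("-")
            cols_b.append(b.residues[j - 1])
            state = pY[i, j]
            j -= 1
    # unaligned prefix
    while i > 0:
        cols_a.append(a.residues[i - 1])
        cols_b.append("-")
        i -= 1
    while j > 0:
        cols_a.append("-")
        cols_b.append(b.residues[j - 1])
        j -= 1

    return PairwiseAlignment("".join(reversed(cols_a)), "".join(reversed(cols_b)), float(score))


def percent_identity(aln: PairwiseAlignment, mode: str = EXCLUDE_TERMINAL_GAPS) -> float:
    """Fraction of matching columns under the chosen denominator mode."""
    if mode == ALL_COLUMNS:
        lo, hi = 0, aln.columns
    elif mode == EXCLUDE_TERMINAL_GAPS:
        lo, hi = aln._trimmed_window()
    else:
        raise InputError(f"unknown identity mode {mode!r}")
    matches, columns = aln._count(lo, hi)
    if columns == 0:
        raise ComputationError("identity undefined: no aligned columns")
    return matches / columns


def translate(nt: SequenceRecord, frame: int = 1) -> SequenceRecord:
    """Standard-code translation of a nucleotide record.

    Stops render as ``*``; codons containing ``N`` render as ``X``; a
    trailing partial codon is dropped.
    """
    if not nt.is_nucleotide:
        raise InputError("translate requires a nucleotide sequence")
    if frame not in (1, 2, 3):
        raise InputError("frame must be 1, 2 or 3")
    s = nt.residues[frame - 1 :]
    s = s[: len(s) - len(s) % 3]
    if not s:
        raise InputError(f"sequence {nt.id!r} has no complete codon in frame {frame}")
    aa = str(Seq(s).translate())
    return SequenceRecord(nt.id, aa, PROTEIN)
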