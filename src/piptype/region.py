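"""Extraction of the PIP hypervariable region by anchoring to conserved flanks.

The phage-infection protein (PIP) of *Enterococcus faecalis* is conserved at
its N and C termini but carries a central hypervariable region — amino acids
342–494 of the V583 reference product (nucleotides 1024–1482 of the gene by
codon arithmetic) — that determines which phages can infect the strain. This
module projects those reference coordinates onto any full-length homolog via
a global alignment and returns the homolog's own variable region.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import EXCLUDE_TERMINAL_GAPS, global_align, translate
from .errors import ComputationError, InputError
from .records import NUCLEOTIDE, PROTEIN, SequenceRecord

# reference variable-region bounds on the V583-like anchor (1-based, inclusive)
AA_START = 342
AA_END = 494


@dataclass(frozen=True)
class VariableRegion:
    """The extracted hypervariable segment with coordinates on its source."""

    source_id: str
    start: int  # 1-based inclusive, in units of `level`
    end: int
    residues: str
    level: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise InputError(f"invalid region coordinates [{self.start},{self.end}]")
        if len(self.residues) != self.end - self.start + 1:
            raise InputError("region residues do not match coordinate span")

    def as_record(self) -> SequenceRecord:
        return SequenceRecord(self.source_id, self.residues, self.level)


def region_length(region: VariableRegion) -> int:
    """Length of the region in residues (end − start + 1)."""
    return region.end - region.start + 1


@dataclass(frozen=True)
class ReferenceAnchor:
    """The full-length reference gene and its variable-region coordinates.

    Amino-acid coordinates map to nucleotides by codon arithmetic:
    ``nt_start = 3·aa_start − 2``, ``nt_end = 3·aa_end``.
    """

    reference: SequenceRecord  # nucleotide, ORF starting at codon 1
    aa_start: int = AA_START
    aa_end: int = AA_END

    def __post_init__(self) -> None:
        if not self.reference.is_nucleotide:
            raise InputError("anchor reference must be a nucleotide sequence")
        if self.nt_end > len(self.reference):
            raise InputError("variable-region coordinates exceed the reference length")

    @property
    def nt_start(self) -> int:
        return 3 * self.aa_start - 2

    @property
    def nt_end(self) -> int:
        return 3 * self.aa_end

    @property
    def protein(self) -> SequenceRecord:
        """Reference product without the terminal stop."""
        aa = translate(self.reference)
        residues = aa.residues[:-1] if aa.residues.endswith("*") else aa.residues
        return SequenceRecord(self.reference.id, residues, PROTEIN)

    def region_record(self, level: str = NUCLEOTIDE) -> SequenceRecord:
        if level == NUCLEOTIDE:
            return SequenceRecord(
                self.reference.id, self.reference.slice1(self.nt_start, self.nt_end), NUCLEOTIDE
            )
        return SequenceRecord(
            self.reference.id, self.protein.slice1(self.aa_start, self.aa_end), PROTEIN
        )

    def bounds(self, level: str) -> tuple[int, int]:
        if level == NUCLEOTIDE:
            return self.nt_start, self.nt_end
        return self.aa_start, self.aa_end


def extract_variable_region(
    query: SequenceRecord,
    anchor: ReferenceAnchor,
    level: str = NUCLEOTIDE,
    min_flank_identity: float = 0.30,
) -> VariableRegion:
    """Project the anchor's variable-region bounds onto a full-length homolog.

    The query is globally aligned to the reference at the requested level;
    reference boundary positions are projected onto query coordinates, with
    boundary gaps snapped inward so the returned interval never leaves the
    query. Queries whose conserved flanks align below ``min_flank_identity``
    are rejected as non-homologs.
    """
    if query.alphabet != level:
        raise InputError(f"query alphabet {query.alphabet!r} does not match level {level!r}")
    ref = anchor.reference if level == NUCLEOTIDE else anchor.protein
    start, end = anchor.bounds(level)
    aln = global_align(query, ref)

    # column window spanning reference positions [start, end], including
    # insertion columns interior to it
    rpos = 0
    win_lo = win_hi = None
    for c, rchar in enumerate(aln.aligned_b):
        if rchar != "-":
            rpos += 1
            if rpos == start:
                win_lo = c
            if rpos == end:
                win_hi = c
    if win_lo is None or win_hi is None:
        raise ComputationError("reference variable region not covered by the alignment")

    # flank identity guard: matches over flank columns, terminal gaps excluded
    t_lo, t_hi = aln._trimmed_window()
    fm = fc = 0
    for c in range(t_lo, t_hi):
        if win_lo <= c <= win_hi:
            continue
        fc += 1
        if aln.aligned_a[c] == aln.aligned_b[c] and aln.aligned_a[c] not in "-NX":
            fm += 1
    if fc > 0 and fm / fc < min_flank_identity:  # no flank columns: nothing to judge
        raise InputError(
            f"query {query.id!r} flank identity {fm / fc:.2f} "
            f"below {min_flank_identity}: not a PIP homolog"
        )

    # project onto query coordinates, snapping boundary gaps inward
    qpos = 0
    q_start = q_end = None
    for c, qchar in enumerate(aln.aligned_a):
        if qchar != "-":
            qpos += 1
            if win_lo <= c <= win_hi:
                if q_start is None:
                    q_start = qpos
                q_end = qpos
    if q_start is None:
        raise ComputationError(f"variable region absent from query {query.id!r}")
    return VariableRegion(query.id, q_start, q_end, query.slice1(q_start, q_end), level)
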