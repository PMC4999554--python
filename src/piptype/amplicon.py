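"""Amplicon read classification and variable-region variant profiling.

Environmental samples (the motivating case is raw sewage) are profiled by
amplifying the PIP variable region and sequencing short reads. Each read is
aligned semi-globally — terminal gaps free, since a 250-nt read covers only
part of the 459-nt region — against every clade representative, in both
orientations, and assigned to the best-identity clade subject to minimum
identity and margin thresholds; exact ties stay unassigned. Clade abundance
is then the fraction of assigned reads per clade. Independently, reads or
assembled contigs can be piled onto the reference region to count amino-acid
variants per reference position; sequences carrying frameshifting indels are
untranslatable in the reference frame and are excluded from the profile.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .align import EXCLUDE_TERMINAL_GAPS, global_align, percent_identity
from .clades import CladeScheme
from .errors import InputError
from .records import SequenceRecord
from .region import ReferenceAnchor

UNASSIGNED = "unassigned"

DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_MARGIN = 0.0


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    clade_id: str  # scheme clade id or "unassigned"
    best_identity: float
    margin: float


@dataclass(frozen=True)
class CladeAbundanceTable:
    """Per-clade read counts and fractions of assigned reads."""

    counts: dict  # clade_id -> count (assigned clades only)
    fractions: dict  # clade_id -> fraction of assigned reads
    unassigned: int
    total: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"clade": c, "count": self.counts[c], "fraction": self.fractions[c]}
            for c in sorted(self.counts)
        ]
        rows.append(
            {"clade": UNASSIGNED, "count": self.unassigned, "fraction": float("nan")}
        )
        return pd.DataFrame(rows, columns=["clade", "count", "fraction"])


def _best_orientation_identity(read: SequenceRecord, rep: SequenceRecord) -> float:
    fwd = percent_identity(global_align(read, rep, free_end_gaps=True))
    rev = percent_identity(global_align(read.reverse_complement(), rep, free_end_gaps=True))
    return max(fwd, rev)


def classify_reads(
    reads: Sequence[SequenceRecord],
    scheme: CladeScheme,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_margin: float = DEFAULT_MIN_MARGIN,
) -> list[ReadAssignment]:
    """Best-representative assignment of each read (strand-symmetric).

    A read is assigned when its best terminal-gap-free identity is at least
    ``min_identity`` and exceeds the runner-up by at least ``min_margin``;
    reads exactly equidistant between two representatives are unassigned.
    """
    if not reads:
        raise InputError("empty read set")
    reps = scheme.representatives()
    rep_records = [r.as_record() for r in reps]
    clade_ids = scheme.clade_ids
    out: list[ReadAssignment] = []
    for read in reads:
        if not read.is_nucleotide:
            raise InputError(f"read {read.id!r} is not nucleotide")
        scores = [_best_orientation_identity(read, rep) for rep in rep_records]
        order = sorted(range(len(scores)), key=lambda k: -scores[k])
        best, second = scores[order[0]], (scores[order[1]] if len(scores) > 1 else 0.0)
        margin = best - second
        if best < min_identity or margin < min_margin or (len(scores) > 1 and best == second):
            out.append(ReadAssignment(read.id, UNASSIGNED, best, margin))
        else:
            out.append(ReadAssignment(read.id, clade_ids[order[0]], best, margin))
    return out


def summarize_abundance(assignments: Sequence[ReadAssignment]) -> CladeAbundanceTable:
    """Counts and fractions per clade; unassigned reads are excluded from
    fractions and reported separately."""
    counts: Counter = Counter()
    unassigned = 0
    for a in assignments:
        if a.clade_id == UNASSIGNED:
            unassigned += 1
        else:
            counts[a.clade_id] += 1
    assigned = sum(counts.values())
    if assigned == 0:
        warnings.warn("no reads were assigned to any clade")
        fractions: dict = {}
    else:
        fractions = {c: n / assigned for c, n in counts.items()}
    return CladeAbundanceTable(dict(counts), fractions, unassigned, len(assignments))


@dataclass(frozen=True)
class PositionVariantProfile:
    """Per reference amino-acid position: residue counts from aligned reads.

    Positions are global product coordinates (342–494 for the default
    anchor). ``counts[pos]`` is a Counter of observed residues.
    """

    positions: tuple[int, ...]
    ref_residues: str
    counts: dict  # position -> Counter of residues
    n_used: int
    n_frameshifted: int
    n_skipped: int

    def coverage(self, pos: int) -> int:
        return sum(self.counts[pos].values())

    def variant_fraction(self, pos: int) -> float:
        cov = self.coverage(pos)
        if cov == 0:
            return 0.0
        ref = self.ref_residues[pos - self.positions[0]]
        return sum(n for r, n in self.counts[pos].items() if r != ref) / cov

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pos in self.positions:
            ref = self.ref_residues[pos - self.positions[0]]
            cov = self.coverage(pos)
            alts = [(n, r) for r, n in self.counts[pos].items() if r != ref]
            top_alt = max(alts)[1] if alts else ""
            rows.append(
                {
                    "position": pos,
                    "ref_residue": ref,
                    "coverage": cov,
                    "variant_fraction": self.variant_fraction(pos),
                    "top_alternate": top_alt,
                }
            )
        return pd.DataFrame(
            rows, columns=["position", "ref_residue", "coverage", "variant_fraction", "top_alternate"]
        )


def variant_profile(
    sequences: Sequence[SequenceRecord],
    anchor: ReferenceAnchor,
    min_identity: float = 0.75,
) -> PositionVariantProfile:
    """Amino-acid variation per reference position from reads or contigs.

    Each nucleotide sequence is aligned (better orientation kept) to the
    reference variable region; codons fully and gaplessly covered are
    translated in the reference frame and accumulated at their reference
    positions. Sequences with a frameshifting net indel are flagged and
    excluded; sequences not overlapping the region are skipped with a
    warning.
    """
    region_nt = anchor.region_record()
    region_aa = anchor.region_record(level="protein")
    positions = tuple(range(anchor.aa_start, anchor.aa_end + 1))
    counts = {pos: Counter() for pos in positions}
    n_used = n_frameshifted = n_skipped = 0

    for seq in sequences:
        if not seq.is_nucleotide:
            raise InputError(f"sequence {seq.id!r} is not nucleotide")
        fwd = global_align(seq, region_nt, free_end_gaps=True)
        rev = global_align(seq.reverse_complement(), region_nt, free_end_gaps=True)
        try:
            aln = fwd if percent_identity(fwd) >= percent_identity(rev) else rev
            ident = percent_identity(aln)
        except Exception:
            ident = 0.0
            aln = fwd
        if ident < min_identity:
            warnings.warn(f"sequence {seq.id!r} does not match the variable region; skipped")
            n_skipped += 1
            continue

        lo, hi = aln._trimmed_window()
        net = sum(1 for c in range(lo, hi) if aln.aligned_b[c] == "-") - sum(
            1 for c in range(lo, hi) if aln.aligned_a[c] == "-"
        )
        if net % 3 != 0:
            n_frameshifted += 1
            continue

        # map region nt positions -> query characters (None across gaps)
        rpos = 0
        by_ref: dict[int, Optional[str]] = {}
        insertion_after: set[int] = set()
        for c in range(aln.columns):
            qc, rc = aln.aligned_a[c], aln.aligned_b[c]
            if rc != "-":
                rpos += 1
                if lo <= c < hi:
                    by_ref[rpos] = qc if qc != "-" else None
            elif lo <= c < hi:
                insertion_after.add(rpos)
        for aa_idx in range(len(positions)):
            p0 = 3 * aa_idx + 1  # first region nt of this codon
            triplet = [by_ref.get(p0), by_ref.get(p0 + 1), by_ref.get(p0 + 2)]
            if None in triplet:
                continue
            if {p0, p0 + 1} & insertion_after:
                continue  # insertion splits the codon
            codon = "".join(triplet)
            if "N" in codon:
                continue
            counts[positions[aa_idx]][str(Seq(codon).translate())] += 1
        n_used += 1

    return PositionVariantProfile(
        positions, region_aa.residues, counts, n_used, n_frameshifted, n_skipped
    )
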