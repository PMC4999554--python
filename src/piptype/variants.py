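"""Mutation calling in a PIP gene relative to the reference, with consequence
annotation and predicted phage-resistance genotype.

Phage-resistant *E. faecalis* isolates carry loss-of-function lesions in the
PIP gene: premature stop codons, frameshifting indels, or disruption by a
long insertion-sequence (IS) element. The caller aligns an assembled or
Sanger-grade isolate gene to the reference, enumerates the differences
(indels left-aligned in homopolymer context, the VCF convention), annotates
each by its coding consequence, and classifies the isolate as predicted
resistant when any loss-of-function lesion — or a deletion truncating the
variable region — is present. Missense-only genotypes are reported sensitive
but flagged for review.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .align import ALL_COLUMNS, global_align, percent_identity
from .errors import ComputationError, InputError
from .records import SequenceRecord
from .region import ReferenceAnchor

SNP = "SNP"
INSERTION = "insertion"
DELETION = "deletion"
IS_INSERTION = "IS-insertion"

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"
IN_FRAME_INDEL = "in-frame-indel"
IS_DISRUPTION = "IS-disruption"

LOSS_OF_FUNCTION = frozenset({NONSENSE, FRAMESHIFT, IS_DISRUPTION})

DEFAULT_IS_FLOOR = 500


@dataclass(frozen=True)
class VariantCall:
    """One difference between an isolate gene and the reference.

    ``position`` is 1-based on the reference: for SNPs and deletions the
    first affected base, for insertions the base immediately left of the
    inserted material (0 when inserted before the first base).
    """

    kind: str
    position: int
    ref_allele: str
    alt_allele: str
    in_variable_region: Optional[bool] = None

    @property
    def net_length(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass(frozen=True)
class ConsequenceAnnotation:
    consequence: str
    codon: int  # 1-based codon number of the affected position
    truncated_length: Optional[int] = None  # residues before the first novel stop


@dataclass(frozen=True)
class IsolateGenotype:
    isolate_id: str
    variants: tuple  # of (VariantCall, ConsequenceAnnotation)
    phenotype: str  # "resistant" | "sensitive"
    reason: str


def left_align_indel(reference: str, position: int, allele: str, kind: str) -> tuple[int, str]:
    """Shift an indel to its leftmost equivalent position (VCF convention).

    ``position`` follows :class:`VariantCall` conventions. Returns the
    normalised (position, allele) pair.
    """
    if kind in (INSERTION, IS_INSERTION):
        p, s = position, allele
        while p > 0 and reference[p - 1] == s[-1]:
            s = reference[p - 1] + s[:-1]
            p -= 1
        return p, s
    if kind == DELETION:
        p, k = position, len(allele)
        while p > 1 and reference[p - 2] == reference[p + k - 2]:
            p -= 1
        return p, reference[p - 1 : p - 1 + k]
    raise InputError(f"not an indel kind: {kind!r}")


def call_variants(
    isolate: SequenceRecord,
    reference: SequenceRecord,
    is_floor: int = DEFAULT_IS_FLOOR,
    anchor: Optional[ReferenceAnchor] = None,
) -> list[VariantCall]:
    """Enumerate SNPs and indels from a global alignment to the reference.

    Insertions of at least ``is_floor`` nucleotides are reported as IS-like
    insertions. Raises :class:`ComputationError` when the isolate shares less
    than 50% identity with the reference (not comparable).
    """
    if not (isolate.is_nucleotide and reference.is_nucleotide):
        raise InputError("variant calling requires nucleotide sequences")
    aln = global_align(isolate, reference)
    if percent_identity(aln, ALL_COLUMNS) < 0.5:
        raise ComputationError(
            f"isolate {isolate.id!r} shares <50% identity with the reference: not comparable"
        )
    ref = reference.residues
    calls: list[VariantCall] = []
    rpos = 0
    i = 0
    qa, qb = aln.aligned_a, aln.aligned_b
    n = aln.columns
    while i < n:
        qc, rc = qa[i], qb[i]
        if rc == "-":  # insertion run in the isolate
            j = i
            while j < n and qb[j] == "-":
                j += 1
            inserted = qa[i:j]
            pos, allele = left_align_indel(ref, rpos, inserted, INSERTION)
            kind = IS_INSERTION if len(allele) >= is_floor else INSERTION
            calls.append(VariantCall(kind, pos, "", allele))
            i = j
        elif qc == "-":  # deletion run in the isolate
            j = i
            while j < n and qa[j] == "-":
                j += 1
            deleted = qb[i:j]
            pos, allele = left_align_indel(ref, rpos + 1, deleted, DELETION)
            calls.append(VariantCall(DELETION, pos, allele, ""))
            rpos += j - i
            i = j
        else:
            rpos += 1
            if qc != rc:
                calls.append(VariantCall(SNP, rpos, rc, qc))
            i += 1
    calls.sort(key=lambda c: (c.position, c.kind))
    if anchor is not None:
        calls = [
            VariantCall(
                c.kind, c.position, c.ref_allele, c.alt_allele,
                in_variable_region=_overlaps_region(c, anchor),
            )
            for c in calls
        ]
    return calls


def _overlaps_region(call: VariantCall, anchor: ReferenceAnchor) -> bool:
    lo, hi = anchor.nt_start, anchor.nt_end
    if call.kind in (INSERTION, IS_INSERTION):
        return lo <= call.position < hi  # inserted between position and position+1
    span_end = call.position + max(len(call.ref_allele), 1) - 1
    return call.position <= hi and span_end >= lo


def apply_variant(reference: str, call: VariantCall) -> str:
    """The reference sequence with a single call applied."""
    p = call.position
    if call.kind in (INSERTION, IS_INSERTION):
        return reference[:p] + call.alt_allele + reference[p:]
    if call.kind == DELETION:
        return reference[: p - 1] + reference[p - 1 + len(call.ref_allele) :]
    return reference[: p - 1] + call.alt_allele + reference[p:]


def _codon_aa(codon: str) -> str:
    return str(Seq(codon).translate())


def annotate_consequence(call: VariantCall, reference: SequenceRecord) -> ConsequenceAnnotation:
    """Coding consequence of a single call on an ORF starting at base 1."""
    ref = reference.residues
    is_ins = call.kind in (INSERTION, IS_INSERTION)
    lo = 0 if is_ins else 1
    if not (lo <= call.position <= len(ref)):
        raise InputError(f"call position {call.position} outside the reference")
    n_codons = len(ref) // 3
    # insertions affect the codon containing the base to their right
    codon_num = call.position // 3 + 1 if is_ins else (call.position - 1) // 3 + 1
    if call.kind == IS_INSERTION:
        return ConsequenceAnnotation(IS_DISRUPTION, min(codon_num, n_codons))
    if call.kind == SNP:
        idx = (call.position - 1) // 3
        off = (call.position - 1) % 3
        ref_codon = ref[3 * idx : 3 * idx + 3]
        if len(ref_codon) < 3:
            return ConsequenceAnnotation(MISSENSE, idx + 1)  # partial terminal codon
        alt_codon = ref_codon[:off] + call.alt_allele + ref_codon[off + 1 :]
        ref_aa, alt_aa = _codon_aa(ref_codon), _codon_aa(alt_codon)
        if alt_aa == ref_aa:
            return ConsequenceAnnotation(SYNONYMOUS, idx + 1)
        if alt_aa == "*" and idx + 1 < n_codons:
            return ConsequenceAnnotation(NONSENSE, idx + 1, truncated_length=idx)
        return ConsequenceAnnotation(MISSENSE, idx + 1)
    # small indels
    if call.net_length % 3 != 0:
        mutated = apply_variant(ref, call)
        mutated = mutated[: len(mutated) - len(mutated) % 3]
        aa = str(Seq(mutated).translate())
        stop = aa.find("*")
        truncated = stop if stop >= 0 else None
        return ConsequenceAnnotation(FRAMESHIFT, min(codon_num, n_codons), truncated_length=truncated)
    return ConsequenceAnnotation(IN_FRAME_INDEL, min(codon_num, n_codons))


def classify_resistance(
    isolate_id: str,
    annotated: Sequence[tuple[VariantCall, ConsequenceAnnotation]],
    anchor: ReferenceAnchor,
) -> IsolateGenotype:
    """Predicted phenotype from annotated calls.

    Resistant iff any loss-of-function lesion (nonsense, frameshift,
    IS disruption) or any deletion overlapping the variable region is
    present; otherwise sensitive, with missense-only genotypes flagged.
    """
    for call, ann in annotated:
        if ann.consequence in LOSS_OF_FUNCTION:
            return IsolateGenotype(
                isolate_id, tuple(annotated), "resistant",
                f"{ann.consequence} at nt {call.position}",
            )
    for call, ann in annotated:
        if call.kind == DELETION and _overlaps_region(call, anchor):
            return IsolateGenotype(
                isolate_id, tuple(annotated), "resistant",
                f"deletion overlapping the variable region at nt {call.position}",
            )
    if any(ann.consequence == MISSENSE for _, ann in annotated):
        return IsolateGenotype(
            isolate_id, tuple(annotated), "sensitive",
            "missense only; flagged for review",
        )
    return IsolateGenotype(isolate_id, tuple(annotated), "sensitive", "no loss-of-function call")
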