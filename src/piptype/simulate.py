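"""Synthetic-data generation with complete ground truth.

Every input the pipeline consumes can be simulated here: clade-structured
PIP genes (a conserved ORF whose central variable region diverges between
clades but not within them), 250-nt amplicon reads drawn from a clade
mixture with sequencing error, and mutagenised isolate genes carrying one
planted lesion each (premature stop, missense, small indel, or a long
IS-like cassette). All outputs are pure functions of the configuration,
seed included.

The packaged V583-like reference gene and the five packaged clade
representatives are synthetic stand-ins generated deterministically with the
documented dimensions (2,667-nt gene, 888-aa product, variable region at
amino acids 342–494); the real public sequences are not shipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .clades import (
    Clade,
    CladeScheme,
    PHAGE_VFW,
    PHAGE_VPE25,
    RESISTANT,
    SENSITIVE,
    identity_matrix,
    medoid_index,
)
from .errors import ComputationError, InputError
from .records import NUCLEOTIDE, SequenceRecord
from .region import AA_END, AA_START, ReferenceAnchor, VariableRegion
from .variants import (
    DELETION,
    FRAMESHIFT,
    IN_FRAME_INDEL,
    INSERTION,
    IS_DISRUPTION,
    IS_INSERTION,
    MISSENSE,
    NONSENSE,
    SNP,
    VariantCall,
    left_align_indel,
)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)
_CODON_TABLE = {}


def _aa(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for c in [a + b + c for a in _BASES for b in _BASES for c in _BASES]:
            _CODON_TABLE[c] = str(Seq(c).translate())
    return _CODON_TABLE[codon]


# internal fixed seeds for the packaged synthetic reference objects; these are
# part of the package definition and independent of any user-supplied seed
_REFERENCE_SEED = 858
_REPRESENTATIVE_SEED = 859


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for all three generators.

    Defaults mirror the system being emulated: five clades holding
    10/1/2/2/4 strains, within-clade variable-region identity above the 95%
    typing threshold and between-clade identity below it, an 888-codon gene
    with the variable region at amino acids 342–494 (459 nt), 250-nt reads
    with 1% substitution error, and a four-way lesion spectrum including a
    1,300-nt IS-like cassette.
    """

    seed: int = 0
    clade_sizes: tuple[int, ...] = (10, 1, 2, 2, 4)
    within_identity: float = 0.98
    between_identity: float = 0.80
    flank_identity: float = 0.995
    gene_length_aa: int = 888  # product length; the gene adds a stop codon
    region_start_aa: int = AA_START
    region_end_aa: int = AA_END
    read_length: int = 250
    read_substitution_rate: float = 0.01
    read_indel_rate: float = 0.0
    mixture: Optional[tuple[float, ...]] = None  # default: uniform over clades
    # lesion spectrum: nonsense SNP, missense SNP, small indel, IS insertion
    spectrum: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    small_indel_lengths: tuple[int, ...] = tuple(range(1, 11))
    small_indel_span: Optional[tuple[int, int]] = None  # restrict indel start positions
    is_length: int = 1300
    calibration_tolerance: float = 0.02
    max_calibration_attempts: int = 15

    def __post_init__(self) -> None:
        for name in ("within_identity", "between_identity", "flank_identity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise InputError(f"{name} must be in (0, 1], got {v}")
        if self.between_identity >= self.within_identity:
            raise InputError(
                "between-clade identity target must be below the within-clade target"
            )
        if self.mixture is not None and abs(sum(self.mixture) - 1.0) > 1e-6:
            raise InputError("mixture weights must sum to 1")
        if abs(sum(self.spectrum) - 1.0) > 1e-6:
            raise InputError("spectrum weights must sum to 1")
        if self.region_end_aa * 3 > self.gene_length_aa * 3:
            raise InputError("variable region extends past the gene")

    @property
    def n_clades(self) -> int:
        return len(self.clade_sizes)

    @property
    def nt_start(self) -> int:
        return 3 * self.region_start_aa - 2

    @property
    def nt_end(self) -> int:
        return 3 * self.region_end_aa


def _random_orf(rng: np.random.Generator, n_codons_coding: int) -> str:
    """Random ORF: ATG, then non-stop codons, then TAA."""
    body = rng.choice(len(_NONSTOP_CODONS), size=n_codons_coding - 1)
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in body) + "TAA"


def _fix_internal_stops(seq: str) -> str:
    """Recode any internal stop codon (third base → C keeps the frame clean)."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for k in range(1, len(codons) - 1):
        while codons[k] in _STOPS:
            codons[k] = codons[k][:2] + ("C" if codons[k][2] != "C" else "G")
    return "".join(codons)


def _mutate_sites(
    seq: str, rate: float, rng: np.random.Generator, lo: int = 0, hi: Optional[int] = None
) -> str:
    """Substitute each site of seq[lo:hi] with probability ``rate``.

    The first and last codons are never touched so the ORF endpoints survive.
    """
    hi = len(seq) if hi is None else hi
    chars = list(seq)
    span = np.arange(max(lo, 3), min(hi, len(seq) - 3))
    hits = span[rng.random(len(span)) < rate]
    for p in hits:
        old = chars[p]
        choices = [b for b in _BASES if b != old]
        chars[p] = choices[rng.integers(3)]
    return _fix_internal_stops("".join(chars))


@dataclass(frozen=True)
class SimulatedScheme:
    """Clade-structured genes plus the derived scheme and ground truth."""

    genes: tuple[SequenceRecord, ...]
    regions: dict  # strain -> VariableRegion
    scheme: CladeScheme
    truth: dict  # strain -> clade_id
    anchor: ReferenceAnchor


_SYNTHETIC_PATTERNS = (
    {PHAGE_VPE25: SENSITIVE, PHAGE_VFW: SENSITIVE},
    {PHAGE_VPE25: SENSITIVE, PHAGE_VFW: RESISTANT},
    {PHAGE_VPE25: RESISTANT, PHAGE_VFW: SENSITIVE},
)


def generate_clade_scheme(cfg: SimulationConfig) -> SimulatedScheme:
    """Clade-structured full-length genes with a calibrated identity profile.

    One random ancestral ORF seeds the population; each clade ancestor
    diverges from it inside the variable region (calibrated to the
    between-clade identity target), each member diverges from its clade
    ancestor (within-clade target) with near-identical flanks. Realised mean
    identities are verified against the targets (±2 percentage points by
    default) and the draw is repeated otherwise.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestor = _random_orf(rng, cfg.gene_length_aa)
    anchor = ReferenceAnchor(
        SequenceRecord("sim_ancestor", ancestor),
        cfg.region_start_aa,
        cfg.region_end_aa,
    )
    lo, hi = anchor.nt_start - 1, anchor.nt_end  # 0-based half-open region span
    p_between = (1.0 - cfg.between_identity) / 2.0
    p_within = (1.0 - cfg.within_identity) / 2.0
    p_flank = (1.0 - cfg.flank_identity) / 2.0

    for _ in range(cfg.max_calibration_attempts):
        clade_ancestors = [
            _mutate_sites(ancestor, p_between, rng, lo, hi) for _ in cfg.clade_sizes
        ]
        strains: list[tuple[str, str, int]] = []  # (name, gene, clade index)
        for k, size in enumerate(cfg.clade_sizes):
            for m in range(size):
                gene = _mutate_sites(clade_ancestors[k], p_within, rng, lo, hi)
                gene = _mutate_sites(gene, p_flank, rng, 0, lo)
                gene = _mutate_sites(gene, p_flank, rng, hi, len(gene))
                strains.append((f"sim_c{k + 1}_m{m + 1:02d}", gene, k))

        regions = {
            name: VariableRegion(name, anchor.nt_start, anchor.nt_end, gene[lo:hi])
            for name, gene, _ in strains
        }
        if _calibrated(cfg, anchor, clade_ancestors, strains, lo, hi):
            break
    else:
        raise ComputationError(
            "could not calibrate identities to the configured targets; "
            "targets may be too close to each other"
        )

    # number clades by descending size, then first-member order
    by_clade: dict[int, list[str]] = {}
    for name, _, k in strains:
        by_clade.setdefault(k, []).append(name)
    order = sorted(by_clade, key=lambda k: (-len(by_clade[k]), k))
    matrix = identity_matrix(list(regions.values()))
    clades = []
    susceptibility = {}
    truth = {}
    for rank, k in enumerate(order, start=1):
        members = by_clade[k]
        rep = regions[medoid_index(matrix, members)]
        clades.append(Clade(str(rank), rep, tuple(members)))
        susceptibility[str(rank)] = dict(_SYNTHETIC_PATTERNS[(rank - 1) % 3])
        for name in members:
            truth[name] = str(rank)

    genes = tuple(SequenceRecord(name, gene) for name, gene, _ in strains)
    scheme = CladeScheme(tuple(clades), susceptibility, level=NUCLEOTIDE)
    return SimulatedScheme(genes, regions, scheme, truth, anchor)


def _hamming_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _calibrated(cfg, anchor, clade_ancestors, strains, lo, hi) -> bool:
    """Mean realised identities within ±tolerance of the targets."""
    anc_regions = [g[lo:hi] for g in clade_ancestors]
    if len(anc_regions) > 1:
        vals = [
            _hamming_identity(anc_regions[i], anc_regions[j])
            for i in range(len(anc_regions))
            for j in range(i + 1, len(anc_regions))
        ]
        if abs(float(np.mean(vals)) - cfg.between_identity) > cfg.calibration_tolerance:
            return False
    within_vals = []
    for k in range(len(cfg.clade_sizes)):
        members = [g[lo:hi] for name, g, kk in strains if kk == k]
        within_vals += [
            _hamming_identity(members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
    if within_vals and abs(float(np.mean(within_vals)) - cfg.within_identity) > cfg.calibration_tolerance:
        return False
    return True


def synthetic_reference() -> SequenceRecord:
    """Deterministic synthetic stand-in for the V583 PIP reference gene.

    2,667 nt: an 888-codon ORF (ATG start) plus a TAA stop, translating to an
    888-residue product. Synthetic — generated from a fixed internal seed,
    not the public sequence.
    """
    rng = np.random.default_rng(_REFERENCE_SEED)
    return SequenceRecord("PIP_V583_synthetic", _random_orf(rng, 888))


def packaged_anchor() -> ReferenceAnchor:
    """Reference anchor over the synthetic V583-like gene (aa 342–494)."""
    return ReferenceAnchor(synthetic_reference())


def packaged_representatives() -> dict:
    """Synthetic variable-region representatives for the packaged five clades.

    Clade 4 (the reference's clade) carries the reference region verbatim;
    the other clades diverge from it at ~20% of region sites, placing every
    between-clade identity well under the 95% threshold. Deterministic and
    synthetic — stand-ins for the unpublished representative sequences.
    """
    anchor = packaged_anchor()
    ref_gene = anchor.reference.residues
    lo, hi = anchor.nt_start - 1, anchor.nt_end
    rng = np.random.default_rng(_REPRESENTATIVE_SEED)
    strain_for_clade = {"1": "D6", "2": "Merz96", "3": "OG1RF", "4": "V583", "5": "T3"}
    reps = {}
    for clade_id, strain in strain_for_clade.items():
        if clade_id == "4":
            region = ref_gene[lo:hi]
        else:
            region = _mutate_sites(ref_gene, 0.10, rng, lo, hi)[lo:hi]
        reps[clade_id] = VariableRegion(strain, anchor.nt_start, anchor.nt_end, region)
    return reps


def simulate_amplicon_reads(
    scheme: CladeScheme,
    n_reads: int,
    cfg: SimulationConfig,
    mixture: Optional[Sequence[float]] = None,
) -> tuple[list[SequenceRecord], dict]:
    """Amplicon reads from a clade mixture, with per-read source-clade truth.

    Each read draws a source clade by mixture weight, a uniform window of
    ``cfg.read_length`` from that clade representative's region, a random
    orientation, and substitution (and optionally indel) errors at the
    configured rates. Returns ``(reads, truth)`` with ``truth[read_id]`` the
    planted clade id.
    """
    reps = scheme.representatives()
    weights = np.asarray(
        mixture if mixture is not None else (cfg.mixture or [1.0 / len(reps)] * len(reps)),
        dtype=float,
    )
    if len(weights) != len(reps) or abs(weights.sum() - 1.0) > 1e-6:
        raise InputError("mixture must give one weight per scheme clade, summing to 1")
    min_len = min(len(r.residues) for r in reps)
    if cfg.read_length > min_len:
        raise InputError(
            f"read length {cfg.read_length} exceeds the shortest representative "
            f"region ({min_len} nt)"
        )
    rng = np.random.default_rng(cfg.seed)
    reads: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    clade_ids = scheme.clade_ids
    for i in range(n_reads):
        k = int(rng.choice(len(reps), p=weights))
        rep = reps[k].residues
        start = int(rng.integers(0, len(rep) - cfg.read_length + 1))
        seq = rep[start : start + cfg.read_length]
        seq = _apply_read_errors(seq, cfg, rng)
        rec = SequenceRecord(f"read_{i + 1:06d}", seq)
        if rng.random() < 0.5:
            rec = SequenceRecord(rec.id, rec.reverse_complement().residues)
        reads.append(rec)
        truth[rec.id] = clade_ids[k]
    return reads, truth


def _apply_read_errors(seq: str, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    chars = list(seq)
    if cfg.read_substitution_rate > 0:
        hits = np.nonzero(rng.random(len(chars)) < cfg.read_substitution_rate)[0]
        for p in hits:
            choices = [b for b in _BASES if b != chars[p]]
            chars[p] = choices[rng.integers(3)]
    if cfg.read_indel_rate > 0:
        out = []
        for c in chars:
            if rng.random() < cfg.read_indel_rate:
                if rng.random() < 0.5:
                    out.append(_BASES[rng.integers(4)])  # insertion before c
                    out.append(c)
                # else: deletion of c
            else:
                out.append(c)
        chars = out if out else chars
    return "".join(chars)


@dataclass(frozen=True)
class PlantedMutation:
    """Ground truth for one planted lesion."""

    call: VariantCall  # left-aligned, caller conventions
    label: str  # nonsense | missense | small_indel | is_insertion
    expected_consequence: str
    expected_phenotype: str  # resistant | sensitive


def _expected_for_indel(call: VariantCall, cfg: SimulationConfig) -> tuple[str, str]:
    if call.net_length % 3 != 0:
        return FRAMESHIFT, "resistant"
    overlaps = (
        call.kind == DELETION
        and call.position <= cfg.nt_end
        and call.position + len(call.ref_allele) - 1 >= cfg.nt_start
    )
    return IN_FRAME_INDEL, "resistant" if overlaps else "sensitive"


def simulate_resistant_isolates(
    reference: SequenceRecord,
    n_isolates: int,
    cfg: SimulationConfig,
) -> tuple[list[SequenceRecord], dict]:
    """Isolate gene copies carrying one planted lesion each.

    Lesion types are drawn from ``cfg.spectrum`` (nonsense SNP, missense
    SNP, small indel, IS-like cassette insertion). Returns ``(isolates,
    truth)`` with ``truth[isolate_id]`` a :class:`PlantedMutation` whose call
    is left-aligned exactly as the caller reports it.
    """
    if not reference.is_nucleotide:
        raise InputError("reference must be a nucleotide ORF")
    rng = np.random.default_rng(cfg.seed)
    ref = reference.residues
    n_codons = len(ref) // 3
    isolates: list[SequenceRecord] = []
    truth: dict[str, PlantedMutation] = {}
    kinds = ("nonsense", "missense", "small_indel", "is_insertion")
    for i in range(n_isolates):
        label = kinds[int(rng.choice(4, p=np.asarray(cfg.spectrum)))]
        if label == "nonsense":
            call = _plant_nonsense(ref, n_codons, rng)
            expected = (NONSENSE, "resistant")
        elif label == "missense":
            call = _plant_missense(ref, n_codons, rng)
            expected = (MISSENSE, "sensitive")
        elif label == "small_indel":
            call = _plant_small_indel(ref, cfg, rng)
            expected = _expected_for_indel(call, cfg)
        else:
            call = _plant_is_insertion(ref, cfg, rng)
            expected = (IS_DISRUPTION, "resistant")
        from .variants import apply_variant

        seq = apply_variant(ref, call)
        rec = SequenceRecord(f"iso_{i + 1:03d}", seq)
        isolates.append(rec)
        truth[rec.id] = PlantedMutation(call, label, expected[0], expected[1])
    return isolates, truth


def _plant_nonsense(ref: str, n_codons: int, rng: np.random.Generator) -> VariantCall:
    while True:
        idx = int(rng.integers(1, n_codons - 1))  # internal codon, 0-based
        codon = ref[3 * idx : 3 * idx + 3]
        options = []
        for stop in _STOPS:
            diffs = [k for k in range(3) if codon[k] != stop[k]]
            if len(diffs) == 1:
                options.append((diffs[0], stop[diffs[0]]))
        if options:
            off, base = options[int(rng.integers(len(options)))]
            pos = 3 * idx + off + 1
            return VariantCall(SNP, pos, ref[pos - 1], base)


def _plant_missense(ref: str, n_codons: int, rng: np.random.Generator) -> VariantCall:
    while True:
        pos = int(rng.integers(4, 3 * (n_codons - 1) + 1))  # skip start & stop codons
        idx, off = (pos - 1) // 3, (pos - 1) % 3
        codon = ref[3 * idx : 3 * idx + 3]
        alts = [b for b in _BASES if b != ref[pos - 1]]
        alt = alts[int(rng.integers(3))]
        alt_codon = codon[:off] + alt + codon[off + 1 :]
        if _aa(alt_codon) != _aa(codon) and _aa(alt_codon) != "*":
            return VariantCall(SNP, pos, ref[pos - 1], alt)


def _plant_small_indel(ref: str, cfg: SimulationConfig, rng: np.random.Generator) -> VariantCall:
    length = int(cfg.small_indel_lengths[int(rng.integers(len(cfg.small_indel_lengths)))])
    lo, hi = cfg.small_indel_span if cfg.small_indel_span else (4, len(ref) - 3)
    if rng.random() < 0.5:  # insertion
        pos = int(rng.integers(max(lo - 1, 3), hi))
        allele = "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
        pos, allele = left_align_indel(ref, pos, allele, INSERTION)
        return VariantCall(INSERTION, pos, "", allele)
    pos = int(rng.integers(lo, min(hi, len(ref) - 2 - length)))
    allele = ref[pos - 1 : pos - 1 + length]
    pos, allele = left_align_indel(ref, pos, allele, DELETION)
    return VariantCall(DELETION, pos, allele, "")


def _plant_is_insertion(ref: str, cfg: SimulationConfig, rng: np.random.Generator) -> VariantCall:
    pos = int(rng.integers(3, len(ref) - 3))
    cassette = "".join(_BASES[b] for b in rng.integers(0, 4, size=cfg.is_length))
    pos, cassette = left_align_indel(ref, pos, cassette, INSERTION)
    return VariantCall(IS_INSERTION, pos, "", cassette)
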