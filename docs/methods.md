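# Methods

## Model and procedure

`piptype` operationalises a marker-gene typing scheme for *E. faecalis*
phage tropism. The marker is the hypervariable center of the phage
infection protein (PIP) gene: amino acids 342–494 of the 888-residue V583
product, equivalently nucleotides 1024–1482 of the 2,667-nt gene by codon
arithmetic (`nt_start = 3·aa_start − 2`, `nt_end = 3·aa_end`). The pipeline
has five stages, each usable on its own:

1. **Alignment primitives.** Global Needleman–Wunsch with Gotoh affine
   gaps; semi-global (terminal gaps free) for short reads against a longer
   region. Percent identity is matches over alignment columns, by default
   with terminal gap runs excluded so partial sequences are not penalised
   for covering less of the reference; an all-columns mode is available.
   Ambiguity codes (N, X) never count as matches.
2. **Region extraction.** A query homolog is globally aligned to the
   reference; the reference boundary positions are projected onto query
   coordinates, with boundary gaps snapped inward so the reported interval
   never leaves the query. Queries whose conserved flanks align below a
   configurable identity floor are rejected as non-homologs.
3. **Clade typing.** Pairwise region identities feed single-linkage
   clustering at the 95% nucleotide threshold (clades = connected
   components of the ≥-threshold graph, numbered by descending size, then
   first-member order). New sequences are assigned to the best-identity
   representative if above threshold, else reported novel; clade membership
   predicts φVPE25/φVFW susceptibility via the packaged phenotype map.
4. **Amplicon profiling.** Reads are aligned semi-globally to every clade
   representative in both orientations and assigned to the best clade
   subject to minimum identity (default 0.90) and margin (default 0)
   thresholds; exact ties stay unassigned. Abundance fractions are over
   assigned reads only. Separately, reads/contigs are piled onto the
   reference region and codons fully and gaplessly covered are translated
   in the reference frame to count amino-acid variants per position.
5. **Resistance calling.** Isolate genes (assembly/Sanger-grade consensus,
   not raw reads) are globally aligned to the reference; mismatches become
   SNPs and gap runs become indels, left-aligned in homopolymer context
   (VCF convention). Insertions of at least 500 nt (configurable) are
   reported as IS-like. Consequences: SNPs by codon translation
   (synonymous / missense / nonsense with truncated-product length),
   indels by net length mod 3 (frameshift vs in-frame), IS insertions as
   disruptions. An isolate is predicted resistant iff it carries a
   nonsense, frameshift or IS-disruption call, or a deletion overlapping
   the variable region; missense-only genotypes are reported sensitive and
   flagged for review.

Cohort statistics are percent resistance (100·k/n with an exact
Clopper–Pearson 95% interval), resistance frequency (colonies/CFU, with the
rule-of-three upper bound 3/CFU when zero colonies are observed), and fold
reduction (control/treated loads).

## Scoring and numerical choices

- Nucleotide scoring: match +1, mismatch −1, gap open −2, gap extend −0.5.
  Protein scoring: BLOSUM62 with open −11 / extend −1. Both configurable;
  the first residue of a gap run pays the open penalty, the rest extend.
- Traceback tie-breaking is fixed — diagonal, then up (gap in the second
  sequence), then left — so alignments are bit-reproducible. Semi-global
  endpoints resolve ties toward the corner, then the longer prefix.
- Identity-threshold decisions default to the nucleotide level; amino-acid
  clustering is supported but the 95% cutoff is defined on nucleotides.
- Under this scoring, an optimal global alignment of *unrelated* same-length
  DNA still attains ≈0.51 matched-column identity (gaps recruit spurious
  matches), so the default homolog floor of 0.30 on flank identity only
  rejects grossly non-alignable inputs; raise it to ≈0.6 for stringent
  nucleotide-level screening. The variant-profiler's overlap floor is 0.75:
  below what genuinely diverged clade sequences reach (≈0.80 between-clade
  identity), above what random short sequences attain (≤≈0.7).
- The caller's comparability guard uses all-columns identity < 0.5, which
  tolerates a full-length IS insertion (identity ≈ 0.67) while rejecting
  fragments of unrelated sequence.
- All reported coordinates are 1-based inclusive. Insertions are addressed
  by the reference base to their left (0 = before the first base).

## Synthetic data: what it emulates and what it does not

The generator (`piptype.simulate`) produces every pipeline input with
complete ground truth. Defaults encode the study conditions: five clades
holding 10/1/2/2/4 strains; within-clade variable-region identity 0.98 and
between-clade identity 0.80 (straddling the 0.95 threshold); flanks ≥99.5%
identical; an 888-codon gene with the region at aa 342–494; 250-nt reads
with 1% substitution error (indels optional, off by default since the
classifier is alignment-based either way); a four-way lesion spectrum
(premature-stop SNP, missense SNP, 1–10-nt indel, 1,300-nt IS-like
cassette) drawn uniformly. Divergence is planted by per-site substitution
at rate (1 − identity target)/2, predominantly inside the region, mirroring
the conserved-flank/variable-center architecture that makes anchor-based
extraction possible; realised mean identities are verified to ±2 percentage
points of the targets and the draw is repeated otherwise (the between-clade
check applies to clade ancestors; member pairs sit slightly lower because
within-clade noise adds divergence). Internal stop codons created by
mutation are recoded so genes remain ORFs. All outputs are pure functions
of the configuration, seed included.

Deliberately not emulated: coalescent/phylogenetic realism, recombination,
position- or quality-dependent sequencing error profiles, paired-end reads,
chimeras, and real IS-element sequence (the cassette is random DNA of
configurable length — IS identity is an annotation matter, not something
this caller verifies by sequence). Passing tests on these simulations
therefore demonstrate the correctness of the algorithms under the stated
identity structure, not robustness to every artefact of real amplicon or
isolate data.

### Packaged reference objects are synthetic stand-ins

The public V583 PIP gene and the 19 strains' sequences are not shipped.
`synthetic_reference()` generates, from a fixed internal seed, a
V583-like 2,667-nt ORF with the documented dimensions, and
`packaged_representatives()` derives five clade representatives from it
(clade 4 carries the reference region verbatim; the others diverge at ~20%
of region sites, placing all between-clade identities well below the
threshold). The packaged roster and phenotype map are real; the sequences
behind them are synthetic. Analyses of real strains should supply their own
reference via `--anchor`/`--reference`.

## Design choices where the design was open

- **Single linkage** for clade grouping: reproduces the chaining behaviour
  implied by a bare identity cutoff and is deterministic; the linkage is a
  parameter in the API.
- **Medoid representatives**: each clade is represented by the member with
  the highest mean identity to its clade-mates (first on ties).
- **Read assignment margin** defaults to 0 with an explicit exact-tie →
  unassigned rule, keeping the default permissive while still refusing
  ambiguous evidence.
- **De novo assembly is out of scope**: community variation is profiled by
  direct read/contig alignment to the reference region; externally
  assembled contigs can be supplied as FASTA.
- **Missense ≠ resistance**: observed resistant isolates carry
  loss-of-function lesions, so missense-only genotypes predict sensitive —
  but are flagged rather than silently passed.
- The library is single-threaded and deterministic; there is no thread
  count to configure, so results are trivially independent of parallelism.

## Problem sizes used in the test and acceptance runs

Planted-partition recovery uses 25 sequences (5×5) over three seeds and a
19-gene (10/1/2/2/4) run through the full extraction → clustering path;
mixture recovery uses 1,000 reads of a 60/40 clade-4/5 mixture at 1%
substitution error, judged against exact binomial 99% intervals; caller
fidelity uses 200 single-lesion genotypes at zero sequencing error
(precision = recall = 1.0); the alignment dynamic program is checked
against exhaustive enumeration on 500 random pairs of length ≤ 8 plus a
library cross-check on longer pairs. These sizes were chosen as the
smallest that make the binomial checks meaningful.

## Known limitations

- Identity-based guards cannot reject unrelated DNA whose gapped alignment
  identity exceeds the floor (see above); score-based screening would be
  stronger but is not what an identity-threshold scheme specifies.
- The resistance caller takes consensus gene sequences; read-level variant
  discovery (pileups, quality weighting) is out of scope.
- Exact reproduction of identities reported by other alignment tools is not
  guaranteed: alignment parameters and identity denominators differ between
  programs, and the packaged defaults are one defensible choice.
- Amino-acid-level clustering of highly diverged regions can differ from
  nucleotide-level clustering near the threshold; the scheme's decision
  level is nucleotide.
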