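# piptype

Typing of *Enterococcus faecalis* phage tropism from the PIP variable region.

Lytic phages such as φVPE25 and φVFW infect *E. faecalis* through PIP, a
conserved integral membrane protein (phage infection protein; the V583 gene
is 2,667 nt and encodes an 888-residue product). PIP carries a central
hypervariable region — amino acids 342–494 of the V583 product, nucleotides
1024–1482 of the gene — that determines which phages can infect a strain,
and loss-of-function mutations in the gene make a strain phage-resistant.
`piptype` packages the analysis pipeline built around this marker for
microbiologists evaluating candidate therapeutic phages or tracking
resistance: region extraction, identity-threshold clade typing with
susceptibility prediction, amplicon-based community profiling, and mutation
calling in resistant isolates.

## The typing scheme

Two strains belong to the same clade when their variable regions share at
least 95% nucleotide identity. With pairwise identities
`I(i,j) = matches / aligned columns` from global (Needleman–Wunsch, affine
gap) alignments, clades are the connected components of the graph with edges
`I(i,j) ≥ 0.95` (single linkage). The packaged scheme encodes the five known
clades over 19 strains and their phage phenotypes:

| clade | strains | φVPE25 | φVFW |
|---|---|---|---|
| 1 | D6, JH1, DS5, AR01/DG, T8, ATCC 29212, T2, T1, X98, Fly1 | sensitive | sensitive |
| 2 | Merz96 | sensitive | resistant |
| 3 | OG1RF, HIP11704 | sensitive | resistant |
| 4 | V583, T11 | sensitive | sensitive |
| 5 | T3, CH188, ATCC 4200, E1Sol | resistant | sensitive |

So typing a new strain's variable region predicts its phage susceptibility:
12 of the 19 packaged strains are sensitive to both phages, 3 to φVPE25
only, 4 to φVFW only. An isolate is predicted phage-resistant when its PIP
gene carries a loss-of-function lesion: a premature stop codon, a
frameshifting indel, disruption by an IS-like element (insertions ≥ 500 nt),
or a deletion truncating the variable region.

The packaged reference gene and clade representative sequences are synthetic
stand-ins generated deterministically with the documented clade structure
and dimensions; see `docs/methods.md`.

## Worked example

Simulate five isolate gene copies, each carrying one planted lesion, then
call mutations and classify resistance:

```
piptype simulate isolates --seed 4 --n 5 --out iso.fasta --truth truth.tsv
piptype call-resistance iso.fasta --variants variants.tsv --genotypes genotypes.tsv
```

`genotypes.tsv`:

```
isolate	n_variants	phenotype	reason
iso_001	1	resistant	IS-disruption at nt 2348
iso_002	1	sensitive	missense only; flagged for review
iso_003	1	resistant	nonsense at nt 2357
iso_004	1	resistant	frameshift at nt 162
iso_005	1	resistant	nonsense at nt 865
```

Each isolate's single lesion is recovered at its exact planted position:
the 1,300-nt IS-like cassette after nt 2348 disrupts the reading frame
(resistant); the C→T change at nt 398 only swaps an amino acid, so the
isolate stays sensitive but is flagged; the C→A change at nt 2357 creates a
premature stop at codon 786 (resistant); the 5-nt insertion at nt 162
shifts the frame (resistant). The `variants.tsv` report lists the calls
with 1-based reference positions, alleles, consequences and affected
codons.

Other subcommands: `simulate scheme|reads`, `extract-region`, `type`
(clade assignment + susceptibility), `profile` (read classification and
per-position amino-acid variation), `stats` (percent-resistance time
courses with exact binomial intervals). All accept `--help`.

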