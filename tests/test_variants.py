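"""Variant calling against the reference gene, consequence annotation, and
resistance genotype classification."""

import pytest

from piptype import (
    ComputationError,
    InputError,
    SequenceRecord,
    annotate_consequence,
    call_variants,
    classify_resistance,
)
from piptype.simulate import SimulationConfig, simulate_resistant_isolates
from piptype.variants import (
    DELETION,
    FRAMESHIFT,
    IN_FRAME_INDEL,
    INSERTION,
    IS_DISRUPTION,
    IS_INSERTION,
    MISSENSE,
    NONSENSE,
    SNP,
    SYNONYMOUS,
    ConsequenceAnnotation,
    VariantCall,
    apply_variant,
    left_align_indel,
)


@pytest.fixture(scope="module")
def reference(anchor):
    return anchor.reference


class TestCallVariants:
    def test_identical_isolate_yields_no_calls(self, reference):
        assert call_variants(SequenceRecord("iso", reference.residues), reference) == []

    def test_planted_snp_called_at_exact_position(self, reference):
        ref = reference.residues
        alt = "T" if ref[299] != "T" else "G"
        iso = SequenceRecord("iso", ref[:299] + alt + ref[300:])
        calls = call_variants(iso, reference)
        assert calls == [VariantCall(SNP, 300, ref[299], alt)]

    def test_planted_spectrum_recovered_exactly(self, reference, rng):
        """2 SNPs, one 4-nt deletion, one 1,300-nt insertion, all recovered."""
        ref = reference.residues
        cassette = "".join("ACGT"[k] for k in rng.integers(0, 4, 1300))
        seq = ref
        seq = seq[:2100] + cassette + seq[2100:]  # insertion after nt 2100
        seq = seq[:1599] + seq[1603:]  # 4-nt deletion at 1600
        alt900 = "A" if ref[899] != "A" else "C"
        seq = seq[:899] + alt900 + seq[900:]
        alt120 = "G" if ref[119] != "G" else "T"
        seq = seq[:119] + alt120 + seq[120:]
        calls = call_variants(SequenceRecord("iso", seq), reference)
        by_kind = {c.kind for c in calls}
        assert by_kind == {SNP, DELETION, IS_INSERTION}
        snps = [c for c in calls if c.kind == SNP]
        assert {(c.position, c.alt_allele) for c in snps} == {(120, alt120), (900, alt900)}
        (dele,) = [c for c in calls if c.kind == DELETION]
        exp_pos, exp_allele = left_align_indel(ref, 1600, ref[1599:1603], DELETION)
        assert (dele.position, dele.ref_allele) == (exp_pos, exp_allele)
        (ins,) = [c for c in calls if c.kind == IS_INSERTION]
        assert len(ins.alt_allele) == 1300
        assert [c.position for c in calls] == sorted(c.position for c in calls)

    def test_deletion_left_aligned_in_homopolymer(self):
        ref = SequenceRecord("ref", "ATG" + "AAAA" + "CGTCGTCGTCGTTAA")
        iso = SequenceRecord("iso", "ATG" + "AAA" + "CGTCGTCGTCGTTAA")
        (call,) = call_variants(iso, ref)
        assert (call.kind, call.position, call.ref_allele) == (DELETION, 4, "A")

    def test_unrelated_sequence_not_comparable(self, reference, rng):
        short = "".join("ACGT"[k] for k in rng.integers(0, 4, 300))
        with pytest.raises(ComputationError, match="not comparable"):
            call_variants(SequenceRecord("x", short), reference)

    def test_variable_region_flag_set_with_anchor(self, reference, anchor):
        ref = reference.residues
        alt = "T" if ref[1099] != "T" else "G"
        iso = SequenceRecord("iso", ref[:1099] + alt + ref[1100:])
        (call,) = call_variants(iso, reference, anchor=anchor)
        assert call.in_variable_region is True


class TestConsequences:
    def test_premature_stop_truncates_product(self):
        # 888-codon product; TAC -> TAA at codon 100 is a nonsense change
        body = ["ATG"] + ["GGC"] * 887 + ["TAA"]
        body[99] = "TAC"
        ref = SequenceRecord("ref", "".join(body))
        call = VariantCall(SNP, 99 * 3 + 3, "C", "A")
        ann = annotate_consequence(call, ref)
        assert ann == ConsequenceAnnotation(NONSENSE, 100, truncated_length=99)

    def test_single_nt_deletion_is_frameshift(self, reference):
        call = VariantCall(DELETION, 500, reference.residues[499], "")
        ann = annotate_consequence(call, reference)
        assert ann.consequence == FRAMESHIFT
        assert ann.truncated_length is not None

    def test_three_nt_deletion_is_in_frame(self, reference):
        call = VariantCall(DELETION, 501, reference.residues[500:503], "")
        assert annotate_consequence(call, reference).consequence == IN_FRAME_INDEL

    def test_is_insertion_annotated_as_disruption(self, reference):
        call = VariantCall(IS_INSERTION, 150, "", "A" * 1300)
        ann = annotate_consequence(call, reference)
        assert ann.consequence == IS_DISRUPTION
        assert ann.codon == 51

    def test_synonymous_and_missense_classified_by_codon(self):
        ref = SequenceRecord("ref", "ATG" + "CTGGAA" + "TAA")  # M L E *
        assert annotate_consequence(VariantCall(SNP, 6, "G", "A"), ref).consequence == SYNONYMOUS
        assert annotate_consequence(VariantCall(SNP, 7, "G", "C"), ref).consequence == MISSENSE

    def test_position_outside_reference_rejected(self, reference):
        with pytest.raises(InputError):
            annotate_consequence(VariantCall(SNP, 99999, "A", "C"), reference)


class TestResistanceClassification:
    def test_no_variants_predicts_sensitive(self, anchor):
        geno = classify_resistance("iso", [], anchor)
        assert geno.phenotype == "sensitive"

    def test_is_disruption_in_5prime_region_predicts_resistant(self, anchor):
        call = VariantCall(IS_INSERTION, 150, "", "A" * 1300)
        ann = annotate_consequence(call, anchor.reference)
        geno = classify_resistance("iso", [(call, ann)], anchor)
        assert geno.phenotype == "resistant"
        assert "IS" in geno.reason

    def test_missense_only_flagged_but_sensitive(self, anchor):
        call = VariantCall(SNP, 7, anchor.reference.residues[6], "A")
        ann = ConsequenceAnnotation(MISSENSE, 3)
        geno = classify_resistance("iso", [(call, ann)], anchor)
        assert geno.phenotype == "sensitive"
        assert "flagged" in geno.reason

    def test_in_frame_deletion_inside_region_predicts_resistant(self, anchor):
        ref = anchor.reference.residues
        call = VariantCall(DELETION, 1100, ref[1099:1102], "")
        ann = annotate_consequence(call, anchor.reference)
        assert ann.consequence == IN_FRAME_INDEL
        geno = classify_resistance("iso", [(call, ann)], anchor)
        assert geno.phenotype == "resistant"

    def test_adding_loss_of_function_never_flips_to_sensitive(self, anchor):
        missense = (VariantCall(SNP, 7, anchor.reference.residues[6], "A"),
                    ConsequenceAnnotation(MISSENSE, 3))
        lof_call = VariantCall(DELETION, 500, anchor.reference.residues[499], "")
        lof = (lof_call, annotate_consequence(lof_call, anchor.reference))
        assert classify_resistance("a", [missense], anchor).phenotype == "sensitive"
        assert classify_resistance("b", [missense, lof], anchor).phenotype == "resistant"
        assert classify_resistance("c", [lof, missense], anchor).phenotype == "resistant"


class TestRoundTrip:
    def test_planted_lesions_recovered_exactly(self, anchor):
        """Caller precision = recall = 1.0 on simulated genotypes at zero error."""
        cfg = SimulationConfig(seed=17)
        isolates, truth = simulate_resistant_isolates(anchor.reference, 50, cfg)
        for iso in isolates:
            calls = call_variants(iso, anchor.reference)
            planted = truth[iso.id]
            assert len(calls) == 1
            call = calls[0]
            assert (call.kind, call.position, call.ref_allele, call.alt_allele) == (
                planted.call.kind, planted.call.position,
                planted.call.ref_allele, planted.call.alt_allele,
            )
            ann = annotate_consequence(call, anchor.reference)
            assert ann.consequence == planted.expected_consequence
            geno = classify_resistance(iso.id, [(call, ann)], anchor)
            assert geno.phenotype == planted.expected_phenotype


def test_apply_variant_round_trips_with_caller(anchor):
    ref = anchor.reference
    call = VariantCall(INSERTION, 1000, "", "TTAGC")
    mutated = SequenceRecord("mut", apply_variant(ref.residues, call))
    (recovered,) = call_variants(mutated, ref)
    norm_pos, norm_allele = left_align_indel(ref.residues, 1000, "TTAGC", INSERTION)
    assert (recovered.position, recovered.alt_allele) == (norm_pos, norm_allele)
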