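"""Clade typing: identity matrices, threshold clustering, assignment,
susceptibility prediction, and the packaged 19-strain scheme."""

import warnings

import numpy as np
import pandas as pd
import pytest

from piptype import (
    ALL_COLUMNS,
    Clade,
    CladeAssignment,
    CladeScheme,
    InputError,
    SequenceRecord,
    VariableRegion,
    assign_clade,
    cluster_clades,
    global_align,
    identity_matrix,
    packaged_scheme,
    percent_identity,
    predict_susceptibility,
)
from piptype.clades import NOVEL, PHAGE_VFW, PHAGE_VPE25, medoid_index


def _region(name, seq):
    return VariableRegion(name, 1, len(seq), seq)


class TestIdentityMatrix:
    def test_identical_pair_is_fully_identical(self):
        m = identity_matrix([_region("a", "ACGTACGT"), _region("b", "ACGTACGT")])
        assert m.loc["a", "b"] == 1.0

    def test_single_substitution_in_100mer(self):
        base = "ACGT" * 25
        other = base[:50] + ("A" if base[50] != "A" else "C") + base[51:]
        m = identity_matrix([_region("a", base), _region("b", other)], mode=ALL_COLUMNS)
        assert m.loc["a", "b"] == pytest.approx(0.99)

    def test_matrix_equals_pairwise_recomputation(self, sim_scheme):
        regions = list(sim_scheme.regions.values())[:6]
        m = identity_matrix(regions)
        for i in range(6):
            for j in range(i + 1, 6):
                direct = percent_identity(
                    global_align(regions[i].as_record(), regions[j].as_record())
                )
                assert m.iloc[i, j] == pytest.approx(direct)
                assert m.iloc[j, i] == m.iloc[i, j]

    def test_mixed_levels_rejected(self):
        nt = _region("a", "ACGT")
        aa = VariableRegion("b", 1, 3, "MKV", level="protein")
        with pytest.raises(InputError):
            identity_matrix([nt, aa])


class TestClustering:
    def test_single_input_forms_one_clade(self):
        m = pd.DataFrame([[1.0]], index=["only"], columns=["only"])
        assert cluster_clades(m) == [["only"]]

    def test_single_linkage_chains_through_intermediates(self):
        m = pd.DataFrame(
            [[1.0, 0.96, 0.90], [0.96, 1.0, 0.96], [0.90, 0.96, 1.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        assert cluster_clades(m, 0.95) == [["A", "B", "C"]]

    def test_planted_five_clade_partition_recovered(self, sim_scheme):
        m = identity_matrix(list(sim_scheme.regions.values()))
        clusters = cluster_clades(m, 0.95)
        planted = {}
        for strain, clade in sim_scheme.truth.items():
            planted.setdefault(clade, set()).add(strain)
        assert set(map(frozenset, clusters)) == set(map(frozenset, planted.values()))

    def test_raising_threshold_only_refines_partition(self, sim_scheme):
        m = identity_matrix(list(sim_scheme.regions.values()))
        coarse = cluster_clades(m, 0.80)
        fine = cluster_clades(m, 0.97)
        coarse_sets = [set(c) for c in coarse]
        for clade in fine:
            assert any(set(clade) <= c for c in coarse_sets)

    def test_partition_invariant_to_input_order(self, sim_scheme, rng):
        regions = list(sim_scheme.regions.values())
        m1 = identity_matrix(regions)
        shuffled = list(regions)
        rng.shuffle(shuffled)
        m2 = identity_matrix(shuffled)
        p1 = set(map(frozenset, cluster_clades(m1, 0.95)))
        p2 = set(map(frozenset, cluster_clades(m2, 0.95)))
        assert p1 == p2

    def test_clades_numbered_by_descending_size(self, sim_scheme):
        cfg_sizes = sorted((len(c.roster) for c in sim_scheme.scheme.clades), reverse=True)
        assert [len(c.roster) for c in sim_scheme.scheme.clades] == cfg_sizes

    def test_medoid_has_highest_mean_identity(self, sim_scheme):
        m = identity_matrix(list(sim_scheme.regions.values()))
        members = list(sim_scheme.scheme.clades[0].roster)
        medoid = medoid_index(m, members)
        sub = m.loc[members, members]
        means = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
        assert means[medoid] == means.max()


class TestAssignment:
    def test_representative_assigned_to_its_own_clade(self, scheme):
        rep = scheme.clades[3].representative  # clade 4
        a = assign_clade(rep, scheme)
        assert a.clade_id == "4"
        assert a.best_identity == 1.0
        assert a.margin > 0

    def test_diverged_member_assigned_to_planted_clade(self, sim_scheme, rng):
        sim = sim_scheme
        strain = sim.scheme.clades[1].roster[0]
        region = sim.regions[strain]
        # an extra 1% substitution load must not change the assignment
        seq = list(region.residues)
        for i in rng.choice(len(seq), size=int(0.01 * len(seq)), replace=False):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        noisy = VariableRegion(strain, region.start, region.end, "".join(seq))
        assert assign_clade(noisy, sim.scheme).clade_id == sim.truth[strain]

    def test_distant_sequence_is_novel(self, scheme, rng):
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 459))
        a = assign_clade(_region("junk", junk), scheme)
        assert a.clade_id == NOVEL

    def test_exact_tie_reports_novel_with_warning(self, scheme):
        rep = scheme.clades[0].representative
        twin = Clade("6", rep, ("twin",))
        sus = dict(scheme.susceptibility)
        sus["6"] = sus["1"]
        tied = CladeScheme(
            (*[Clade(c.clade_id, c.representative, c.roster) for c in scheme.clades], twin),
            sus,
        )
        with pytest.warns(UserWarning, match="ties"):
            a = assign_clade(rep, tied)
        assert a.clade_id == NOVEL


class TestSusceptibility:
    def test_clade4_sensitive_to_both_phages(self, scheme):
        a = CladeAssignment("V583", "4", 1.0, 0.1)
        pred = predict_susceptibility(a, scheme)
        assert pred.phenotypes == {PHAGE_VPE25: "sensitive", PHAGE_VFW: "sensitive"}

    def test_clade5_resists_vpe25_only(self, scheme):
        pred = predict_susceptibility(CladeAssignment("E1Sol", "5", 1.0, 0.1), scheme)
        assert pred.phenotypes[PHAGE_VPE25] == "resistant"
        assert pred.phenotypes[PHAGE_VFW] == "sensitive"

    def test_novel_assignment_yields_unknown_phenotypes(self, scheme):
        pred = predict_susceptibility(CladeAssignment("x", NOVEL, 0.5, 0.0), scheme)
        assert set(pred.phenotypes.values()) == {"unknown"}

    def test_unknown_clade_id_rejected(self, scheme):
        with pytest.raises(InputError):
            predict_susceptibility(CladeAssignment("x", "99", 1.0, 0.1), scheme)


class TestPackagedScheme:
    def test_roster_counts_by_phenotype(self, scheme):
        dual = vpe_only = vfw_only = 0
        for clade in scheme.clades:
            phenos = scheme.susceptibility[clade.clade_id]
            n = len(clade.roster)
            if phenos[PHAGE_VPE25] == "sensitive" and phenos[PHAGE_VFW] == "sensitive":
                dual += n
            elif phenos[PHAGE_VPE25] == "sensitive":
                vpe_only += n
            elif phenos[PHAGE_VFW] == "sensitive":
                vfw_only += n
        assert (dual, vpe_only, vfw_only) == (12, 3, 4)

    def test_nineteen_strains_in_five_clades(self, scheme):
        assert len(scheme.clades) == 5
        assert sum(len(c.roster) for c in scheme.clades) == 19

    def test_representatives_fall_below_threshold_of_each_other(self, scheme):
        m = identity_matrix(scheme.representatives())
        off = m.values[~np.eye(5, dtype=bool)]
        assert (off < scheme.threshold).all()

    def test_overlapping_rosters_rejected(self, scheme):
        clades = list(scheme.clades)
        clades[1] = Clade("2", clades[1].representative, ("V583",))  # already in clade 4
        with pytest.raises(InputError):
            CladeScheme(tuple(clades), scheme.susceptibility)

    def test_susceptibility_map_must_cover_both_phages(self, scheme):
        broken = {k: {PHAGE_VPE25: v[PHAGE_VPE25]} for k, v in scheme.susceptibility.items()}
        with pytest.raises(InputError):
            CladeScheme(scheme.clades, broken)
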