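import numpy as np
import pandas as pd
import pytest

from conftest import make_profiles
from hemimeth.amd import gene_profiles
from hemimeth.demethylation import ConditionMatrix
from hemimeth.io import pair_dyads
from hemimeth.zones import (
    active_exceeds_passive,
    build_mimic_groups,
    classify_zones,
    inter_cpg_distance_enrichment,
    matched_demethylation_selection,
    methylation_bin_curve,
    mimic_comparison,
    split_high_low_enrichment,
    vc_response_selection,
)


class TestZoneClassification:
    @pytest.mark.parametrize(
        "n_cpg,level,zone",
        [
            (50, 50, "II"),
            (30, 50, "none"),
            (60, 80, "I"),
            (42, 40, "II"),  # all four boundaries are inclusive
            (83, 60, "II"),
            (41, 50, "none"),
            (84, 50, "none"),
            (50, 39.9, "I"),
            (50, 60.1, "I"),
        ],
    )
    def test_boundaries(self, n_cpg, level, zone):
        profiles = make_profiles([("g", n_cpg, level, 1.0)])
        assert classify_zones(profiles)["zone"].iloc[0] == zone

    def test_zone_nesting_on_simulated_genes(self, default_bundle, mef_dyads):
        profiles = gene_profiles(mef_dyads["control"], default_bundle.genes)
        z = classify_zones(profiles)
        n2 = (z["zone"] == "II").sum()
        n1 = (z["zone"] == "I").sum() + n2
        assert 0 < n2 <= n1 <= len(z)

    def test_zone_genes_have_larger_amd_than_genome_mean(self, default_bundle, mef_dyads):
        profiles = gene_profiles(mef_dyads["control"], default_bundle.genes)
        z = classify_zones(profiles)
        measured = z[z["n_cpg"] > 0]
        in_zone = measured[measured["zone"] != "none"]
        assert in_zone["gene_amd"].mean() > measured["gene_amd"].mean()


class TestInterCpGDistance:
    def _dyads(self, positions, amd=10.0, level=50.0):
        n = len(positions)
        return pd.DataFrame(
            {
                "chrom": "c",
                "plus_pos": positions,
                "plus_level": level + amd / 2,
                "minus_level": level - amd / 2,
                "plus_depth": 10,
                "minus_depth": 10,
                "plus_meth": 5,
                "minus_meth": 5,
                "amd": amd,
            }
        )

    def test_nearest_neighbour_distances(self):
        d = self._dyads([100, 160, 400])
        out = inter_cpg_distance_enrichment(d, distance_edges=(0, 45, 90, np.inf))
        # distances are 60, 60, 240: two dyads in (45,90], one in (90,inf]
        by_band = out.set_index(out["distance_band"].astype(str))
        assert by_band.loc["(45.0, 90.0]", "n"] == 2
        assert by_band.loc["(90.0, inf]", "n"] == 1

    def test_single_dyad_chromosome_excluded(self):
        out = inter_cpg_distance_enrichment(self._dyads([500]))
        assert len(out) == 0 or out["n"].sum() == 0

    def test_hemi_band_enrichment_recovered(self, default_bundle, mef_dyads):
        # pluripotency-like promoters carry both the 45-90 bp spacing and the
        # elevated hemi fraction, so that band's mean AMD must stand out
        out = inter_cpg_distance_enrichment(mef_dyads["control"])
        mid = out[out["meth_band"].astype(str) == "(20.0, 85.0]"]
        mid = mid.set_index(mid["distance_band"].astype(str))
        assert mid.loc["(45.0, 90.0]", "mean_amd"] > mid.loc["(90.0, 180.0]", "mean_amd"]
        assert mid.loc["(45.0, 90.0]", "mean_amd"] > mid.loc["(180.0, 360.0]", "mean_amd"]


class TestHighLowSplit:
    def test_two_gene_bin_splits_at_median(self):
        profiles = make_profiles([("a", 10, 50.5, 1.0), ("b", 10, 50.4, 5.0)])
        labels = split_high_low_enrichment(profiles)
        assert labels.tolist() == ["low", "high"]

    def test_identical_amds_all_high(self):
        profiles = make_profiles([("a", 10, 50.5, 2.0), ("b", 10, 50.4, 2.0)])
        assert set(split_high_low_enrichment(profiles)) == {"high"}

    def test_lonely_bin_unassigned(self):
        profiles = make_profiles([("a", 10, 50.5, 2.0), ("b", 10, 80.5, 2.0)])
        assert set(split_high_low_enrichment(profiles)) == {"unassigned"}

    def test_high_subgroup_recovers_hemi_genes(self, default_bundle, mef_dyads):
        profiles = gene_profiles(mef_dyads["control"], default_bundle.genes)
        labels = split_high_low_enrichment(profiles)
        hemi_by_gene = default_bundle.truth.groupby("gene_id")["true_amd"].mean()
        df = profiles.assign(label=labels).set_index("gene_id").join(hemi_by_gene)
        df = df[df["label"].isin(["high", "low"]) & (df["n_cpg"] > 0)]
        hemi_genes = df[df["true_amd"] > 10]
        assert (hemi_genes["label"] == "high").mean() > 0.9


class TestMethylationBinCurve:
    def test_identity_values_track_bin_levels(self):
        rows = [(f"g{i}", 10, lv, 1.0) for i, lv in enumerate(np.linspace(1, 99, 200))]
        profiles = make_profiles(rows)
        values = profiles.set_index("gene_id")["gene_level"]
        curve = methylation_bin_curve(profiles, values, n_bins=20, min_n=1)
        assert np.allclose(curve["mean_value"], curve["mean_level"])

    def test_small_bins_suppressed(self):
        profiles = make_profiles([("a", 10, 3.0, 1.0), ("b", 10, 97.0, 1.0)])
        curve = methylation_bin_curve(profiles, profiles.set_index("gene_id")["gene_level"],
                                      n_bins=20, min_n=2)
        assert len(curve) == 0


class TestMimicGroups:
    def fixture_profiles(self):
        return make_profiles(
            [
                ("a", 30, 35.0, 0.5),   # ratio 0.0143 -> II
                ("b", 30, 35.0, 5.0),   # ratio 0.143 -> III
                ("c", 30, 35.0, 2.0),   # ratio 0.057 -> between thresholds, no group
                ("d", 30, 5.0, 0.05),   # ratio 0.01 -> I
                ("e", 30, 65.0, 0.5),   # ratio 0.0077 -> IV
                ("f", 30, 65.0, 8.0),   # ratio 0.123 -> V
                ("g", 30, 95.0, 1.0),   # ratio 0.0105 -> VI
                ("h", 30, 40.0, 0.4),   # boundary level 40 inclusive, ratio 0.01 -> II
                ("i", 30, 35.0, 0.7),   # ratio exactly 0.02 -> excluded (strict)
                ("j", 30, 35.0, 3.5),   # ratio exactly 0.1 -> excluded (strict)
            ]
        )

    def test_hand_derived_membership(self):
        groups = build_mimic_groups(self.fixture_profiles(), min_size=0)
        members = {gid: set(g.members) for gid, g in groups.items()}
        assert members["I"] == {"d"}
        assert members["II"] == {"a", "h"}
        assert members["III"] == {"b"}
        assert members["IV"] == {"e"}
        assert members["V"] == {"f"}
        assert members["VI"] == {"g"}

    def test_groups_pairwise_disjoint(self):
        groups = build_mimic_groups(self.fixture_profiles(), min_size=0)
        seen = set()
        for g in groups.values():
            assert not (seen & set(g.members))
            seen |= set(g.members)

    def test_under_powered_flag(self):
        groups = build_mimic_groups(self.fixture_profiles(), min_size=100)
        assert all(g.under_powered for g in groups.values())

    def test_comparison_ordering_tracks_hemi_penalty(self, default_bundle, mef_dyads):
        profiles = gene_profiles(mef_dyads["control"], default_bundle.genes)
        groups = build_mimic_groups(profiles, min_size=3)
        acc = default_bundle.accessibility.set_index("gene_id")["accessibility"]
        comp = mimic_comparison(groups, acc)
        # accessibility penalises both methylation and hemi content: the
        # strand-symmetric mimic of each target beats the hemi-rich mimic
        assert active_exceeds_passive(comp)

    def test_identical_values_give_zero_contrasts(self):
        groups = build_mimic_groups(self.fixture_profiles(), min_size=0)
        values = pd.Series(1.0, index=list("abcdefghij"))
        comp = mimic_comparison(groups, values)
        assert (comp["mean_diff"].dropna() == 0).all()

    def test_missing_group_skipped_with_note(self):
        profiles = self.fixture_profiles()
        groups = build_mimic_groups(profiles[profiles["gene_id"] != "e"], min_size=0)
        values = pd.Series(1.0, index=list("abcdefghij"))
        comp = mimic_comparison(groups, values).set_index(["group_a", "group_b"])
        assert "skipped" in comp.loc[("II", "IV"), "note"]


def matrix_from_levels(rows):
    recs = []
    for gene, (ctrl, tet, shd) in rows.items():
        recs += [
            {"entity": gene, "system": "MEF", "perturbation": "control", "level": ctrl},
            {"entity": gene, "system": "MEF", "perturbation": "Tet1", "level": tet},
            {"entity": gene, "system": "MEF", "perturbation": "sh-Dnmt1", "level": shd},
        ]
    return ConditionMatrix.from_long(pd.DataFrame(recs))


class TestMatchedDemethylation:
    def test_double_clause_binds(self):
        # deltas 25/22 pass; diff 3 < 5 but 3 > 0.1 * 26.5 -> criterion 3 fails
        m = matrix_from_levels({"g": (50, 25, 28)})
        assert len(matched_demethylation_selection(m, "MEF")) == 0

    def test_passing_gene(self):
        # deltas 23/21; diff 2 < 5 and 2 <= 0.1 * 28 -> passes
        m = matrix_from_levels({"g": (50, 27, 29)})
        assert list(matched_demethylation_selection(m, "MEF")) == ["g"]

    def test_control_band_is_hard(self):
        m = matrix_from_levels({"g": (70, 27, 29)})
        assert len(matched_demethylation_selection(m, "MEF")) == 0

    def test_both_arms_must_drop_by_default(self):
        m = matrix_from_levels({"g": (50, 27, 45)})  # passive arm drops only 5
        assert len(matched_demethylation_selection(m, "MEF")) == 0
        assert list(
            matched_demethylation_selection(m, "MEF", require_both=False, max_diff=100,
                                            max_diff_frac=10)
        ) == ["g"]

    def test_order_invariant_and_deterministic(self):
        rows = {f"g{i}": (50, 27 + (i % 3), 29) for i in range(10)}
        m1 = matrix_from_levels(rows)
        m2 = matrix_from_levels(dict(reversed(list(rows.items()))))
        s1 = set(matched_demethylation_selection(m1, "MEF"))
        s2 = set(matched_demethylation_selection(m2, "MEF"))
        assert s1 == s2


class TestVcResponse:
    def _matrix(self, d_plus, d_minus):
        recs = []
        for sysname, delta in (("OKMS-Vc+", d_plus), ("OKMS-Vc-", d_minus)):
            recs += [
                {"entity": "g", "system": sysname, "perturbation": "control", "level": 60.0},
                {"entity": "g", "system": sysname, "perturbation": "Tet1", "level": 60.0 - delta},
            ]
        return ConditionMatrix.from_long(pd.DataFrame(recs))

    def test_selected_when_vc_boosts_and_upregulated(self):
        m = self._matrix(30, 15)
        assert list(vc_response_selection(m, pd.Series({"g": 1.0}))) == ["g"]

    def test_rejected_when_downregulated(self):
        m = self._matrix(30, 15)
        assert len(vc_response_selection(m, pd.Series({"g": -0.2}))) == 0

    def test_rejected_without_vc_boost(self):
        m = self._matrix(15, 30)
        assert len(vc_response_selection(m, pd.Series({"g": 1.0}))) == 0

    def test_selection_enriched_for_fully_methylated_genes(self, default_bundle):
        from hemimeth.amd import gene_profiles as gp

        levels = {}
        for system in ("OKMS-Vc+", "OKMS-Vc-"):
            for pert in ("control", "Tet1"):
                prof = gp(pair_dyads(default_bundle.calls[(system, pert)], 5),
                          default_bundle.genes)
                levels[(system, pert)] = prof.set_index("gene_id")["gene_level"]
        recs = []
        for (system, pert), s in levels.items():
            for gene, lv in s.dropna().items():
                recs.append({"entity": gene, "system": system, "perturbation": pert, "level": lv})
        matrix = ConditionMatrix.from_long(pd.DataFrame(recs))
        expr = default_bundle.expression
        fc = expr[(expr["system"] == "OKMS-Vc+") & (expr["perturbation"] == "Tet1")]
        sel = vc_response_selection(matrix, fc.set_index("gene_id")["log2fc"])
        # vitamin C doubles the rate on fully methylated substrate but only
        # multiplies the hemi rate by 1.3, so fully methylated (EMT-like)
        # genes enter the selection at a higher rate than the hemi-rich,
        # Zone-II-like pluripotency genes
        cls = default_bundle.genes.set_index("gene_id")["gene_class"]
        measured = matrix.wide.index
        rate = {
            c: np.isin(cls.index[cls == c], sel).sum()
            / max(1, np.isin(cls.index[cls == c], measured).sum())
            for c in ("emt_like", "pluripotency_like")
        }
        assert rate["emt_like"] > rate["pluripotency_like"]
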