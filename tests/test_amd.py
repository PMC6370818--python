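import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemimeth.amd import (
    NullModelError,
    amd_excess,
    combine_sample_amds,
    exact_abs_mean_diff_expectation,
    expected_site_amd,
    gene_profile,
    gene_profiles,
    hplc_methylation_fraction,
    meth_bin_index,
    meth_bin_representative,
    site_amd,
    theoretical_gene_null,
    theoretical_site_null,
)
from hemimeth.io import add_windows
from hemimeth.simulate import simulate_null_dyads


def brute_force_expectation(n1: int, n2: int, p: float) -> float:
    """Independent oracle: pure-Python enumeration of E|X/n1 - Y/n2| * 100."""

    def pmf(k, n):
        return math.comb(n, k) * p**k * (1 - p) ** (n - k)

    total = 0.0
    for x in range(n1 + 1):
        for y in range(n2 + 1):
            total += pmf(x, n1) * pmf(y, n2) * abs(x / n1 - y / n2)
    return 100.0 * total


class TestExactExpectation:
    @pytest.mark.parametrize(
        "n1,n2,p",
        [(1, 1, 0.5), (5, 5, 0.1), (10, 10, 0.195), (10, 7, 0.8), (30, 30, 0.5), (3, 12, 0.33)],
    )
    def test_matches_brute_force_oracle(self, n1, n2, p):
        assert exact_abs_mean_diff_expectation(n1, n2, p) == pytest.approx(
            brute_force_expectation(n1, n2, p), abs=1e-10
        )

    @pytest.mark.parametrize("p", [0.0, 0.1, 0.25, 0.5, 0.9, 1.0])
    def test_bernoulli_closed_form(self, p):
        assert exact_abs_mean_diff_expectation(1, 1, p) == pytest.approx(
            200.0 * p * (1 - p), abs=1e-9
        )

    @settings(deadline=None, max_examples=60)
    @given(
        n1=st.integers(1, 40),
        n2=st.integers(1, 40),
        p=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_symmetries_and_range(self, n1, n2, p):
        e = exact_abs_mean_diff_expectation(n1, n2, p)
        assert 0.0 <= e <= 100.0
        assert e == pytest.approx(exact_abs_mean_diff_expectation(n2, n1, p), abs=1e-9)
        assert e == pytest.approx(exact_abs_mean_diff_expectation(n1, n2, 1 - p), abs=1e-9)

    def test_degenerate_p_gives_zero(self):
        for n in (1, 4, 25):
            assert exact_abs_mean_diff_expectation(n, n, 0.0) == 0.0
            assert exact_abs_mean_diff_expectation(n, n, 1.0) == 0.0

    def test_monotone_decreasing_in_depth(self):
        depths = [1, 2, 5, 10, 20, 50, 100]
        vals = [exact_abs_mean_diff_expectation(n, n, 0.3) for n in depths]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_non_integer_depth_rejected(self):
        with pytest.raises(ValueError):
            exact_abs_mean_diff_expectation(2.5, 10, 0.3)


class TestBinScheme:
    def test_point_and_interval_bins(self):
        idx = meth_bin_index(np.array([0.0, 0.2, 1.0, 1.01, 99.5, 100.0]))
        assert idx.tolist() == [0, 1, 1, 2, 100, 101]
        reps = meth_bin_representative(idx)
        assert reps.tolist() == [0.0, 0.5, 0.5, 1.5, 99.5, 100.0]

    def test_weights_sum_to_one_and_point_bins_zero(self):
        dyads, _ = simulate_null_dyads(500, 20, seed=3)
        null = theoretical_site_null(dyads)
        assert null.table["weight"].sum() == pytest.approx(1.0)
        point = null.table[null.table["bin"].isin([0, 101])]
        assert (point["expectation"] == 0.0).all()


class TestSiteAndGeneAMD:
    def test_site_amd_arithmetic(self):
        assert site_amd(80, 30) == 50
        assert site_amd(40, 40) == 0
        assert site_amd(0, 100) == 100

    def _dyads(self, rows):
        df = pd.DataFrame(rows, columns=["plus_level", "minus_level"])
        df["chrom"] = "c"
        df["plus_pos"] = 100 * (1 + np.arange(len(df)))
        df["plus_depth"] = 10
        df["minus_depth"] = 10
        df["amd"] = (df["plus_level"] - df["minus_level"]).abs()
        return df

    def test_opposite_extremes_cancel_at_gene_level(self):
        prof = gene_profile(self._dyads([(100, 0), (0, 100)]), "g")
        assert prof["plus_mean"] == 50 and prof["minus_mean"] == 50
        assert prof["gene_amd"] == 0 and prof["gene_level"] == 50

    def test_single_dyad_gene_equals_site(self):
        prof = gene_profile(self._dyads([(60, 20)]), "g")
        assert prof["gene_amd"] == 40

    def test_three_dyad_average(self):
        prof = gene_profile(self._dyads([(80, 20), (40, 40), (60, 60)]), "g")
        assert prof["plus_mean"] == 60 and prof["minus_mean"] == 40
        assert prof["gene_amd"] == pytest.approx(20)

    def test_empty_window_flagged_not_zero(self):
        prof = gene_profile(self._dyads([]).iloc[0:0], "g")
        assert prof["n_cpg"] == 0 and math.isnan(prof["gene_amd"])

    @settings(deadline=None, max_examples=40)
    @given(
        levels=st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)), min_size=1, max_size=25
        )
    )
    def test_gene_amd_never_exceeds_mean_site_amd(self, levels):
        prof = gene_profile(self._dyads(levels), "g")
        mean_site = np.mean([abs(a - b) for a, b in levels])
        assert prof["gene_amd"] <= mean_site + 1e-9

    def test_gene_profiles_assigns_by_window(self):
        genes = add_windows(
            pd.DataFrame(
                {"gene_id": ["g1", "g2"], "chrom": ["c", "c"],
                 "strand": ["+", "+"], "tss": [10000, 50000]}
            )
        )
        dyads = self._dyads([(80, 20), (40, 40)])
        dyads["plus_pos"] = [10000, 30000]  # second dyad in neither window
        profs = gene_profiles(dyads, genes).set_index("gene_id")
        assert profs.loc["g1", "n_cpg"] == 1
        assert profs.loc["g1", "gene_amd"] == 60
        assert profs.loc["g2", "n_cpg"] == 0


class TestSampleCombination:
    def test_mean_and_completeness_rule(self):
        g1 = pd.Series({"a": 10.0, "b": 30.0})
        g2m = pd.Series({"a": 20.0})
        combined = combine_sample_amds({"G1": g1, "G2M": g2m})
        assert combined.to_dict() == {"a": 15.0}

    def test_single_sample_identity(self):
        g1 = pd.Series({"a": 10.0, "b": 30.0})
        assert combine_sample_amds({"G1": g1}).equals(g1)

    def test_no_overlap_is_an_error(self):
        with pytest.raises(ValueError):
            combine_sample_amds({"x": pd.Series({"a": 1.0}), "y": pd.Series({"b": 2.0})})


class TestTheoreticalNull:
    def _uniform_dyads(self, plus, minus, depth=10, n=4):
        return pd.DataFrame(
            {
                "chrom": "c",
                "plus_pos": 100 * (1 + np.arange(n)),
                "plus_level": plus,
                "minus_level": minus,
                "plus_depth": depth,
                "minus_depth": depth,
                "plus_meth": int(round(depth * plus / 100)),
                "minus_meth": int(round(depth * minus / 100)),
                "amd": abs(plus - minus),
            }
        )

    def test_fully_methylated_sample_has_zero_null(self):
        null = theoretical_site_null(self._uniform_dyads(100.0, 100.0))
        assert null.aggregate == 0.0

    def test_single_cell_table_reduces_to_expectation(self):
        dyads = self._uniform_dyads(19.5, 19.5, depth=10)
        null = theoretical_site_null(dyads)
        assert null.aggregate == pytest.approx(
            exact_abs_mean_diff_expectation(10, 10, 0.195)
        )

    def test_aggregate_is_weight_linear(self):
        a = self._uniform_dyads(19.5, 19.5, depth=10, n=2)
        b = self._uniform_dyads(50.0, 50.0, depth=10, n=2)
        both = pd.concat([a, b], ignore_index=True)
        e1 = theoretical_site_null(a).aggregate
        e2 = theoretical_site_null(b).aggregate
        assert theoretical_site_null(both).aggregate == pytest.approx((e1 + e2) / 2)

    def test_aggregate_invariant_to_site_order(self):
        dyads, _ = simulate_null_dyads(300, 15, seed=9)
        shuffled = dyads.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert theoretical_site_null(dyads).aggregate == pytest.approx(
            theoretical_site_null(shuffled).aggregate
        )

    def test_empty_input_rejected(self):
        with pytest.raises(NullModelError):
            theoretical_site_null(self._uniform_dyads(50.0, 50.0).iloc[0:0])

    def test_gene_null_reductions(self):
        assert theoretical_gene_null(0.0, 200) == 0.0
        assert theoretical_gene_null(19.5, 20) == pytest.approx(
            exact_abs_mean_diff_expectation(10, 10, 0.195)
        )
        # pooling across a window shrinks the null below the per-site value
        assert theoretical_gene_null(50.0, 200) < exact_abs_mean_diff_expectation(
            10, 10, 0.5
        )
        with pytest.raises(NullModelError):
            theoretical_gene_null(50.0, 1)


class TestAMDExcess:
    def test_zero_when_observed_equals_expectation(self):
        dyads, _ = simulate_null_dyads(400, 20, seed=5)
        dyads = dyads.copy()
        dyads["amd"] = expected_site_amd(dyads)
        res = amd_excess(dyads, n_permutations=19, seed=0)
        assert res.excess == pytest.approx(0.0, abs=1e-12)

    def test_positive_excess_detected_under_hemi(self):
        dyads, _ = simulate_null_dyads(3000, 30, seed=6, hemi=0.3)
        res = amd_excess(dyads, n_permutations=199, seed=1)
        assert res.excess > 10
        assert res.p_value <= 0.005

    def test_null_data_not_rejected(self):
        dyads, _ = simulate_null_dyads(3000, 30, seed=8, hemi=0.0)
        res = amd_excess(dyads, n_permutations=199, seed=2)
        assert abs(res.excess) < 0.5
        assert res.p_value > 0.05


class TestHplcFraction:
    @pytest.mark.parametrize("dc,mdc,expected", [(80, 20, 20), (5, 0, 0), (0, 7, 100)])
    def test_fraction(self, dc, mdc, expected):
        assert hplc_methylation_fraction(dc, mdc) == expected

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            hplc_methylation_fraction(0, 0)
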