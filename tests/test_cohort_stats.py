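"""Group comparisons, correlation matrices, cohort simulation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragkin.errors import AnalysisError, SpecificationError
from fragkin.cohort_stats import (
    compare_groups,
    correlation_matrix,
    mannwhitney_u,
    median_ci,
    significance_stars,
    summarize,
)
from fragkin.synthetic.cohort_sim import (
    COHORT_MARKERS,
    CohortSpec,
    default_cohort_specs,
    simulate_cohort,
)


def brute_force_mw_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    combined = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(combined)) + 1.0
    nx = len(x)
    observed_u = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    mu = nx * len(y) / 2.0
    us = []
    for idx in itertools.combinations(range(len(combined)), nx):
        u = ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
        us.append(u)
    us = np.asarray(us)
    return float((np.abs(us - mu) >= abs(observed_u - mu) - 1e-12).mean())


class TestMannWhitney:
    def test_identical_groups_give_p_one(self):
        _, p = mannwhitney_u([1.0, 2, 3], [1.0, 2, 3])
        assert p == 1.0

    def test_complete_separation_u_zero(self):
        u, p = mannwhitney_u([1.0, 2, 3], [10.0, 20, 30])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # two-sided, exact 3v3 null

    @pytest.mark.parametrize("nx,ny", [(2, 2), (3, 3), (2, 8), (5, 4), (8, 8), (6, 7)])
    def test_exact_p_matches_brute_force_enumeration(self, nx, ny):
        rng = np.random.default_rng(nx * 100 + ny)
        for _ in range(3):
            x = rng.permutation(np.arange(1.0, nx + ny + 1))[:nx]
            y = np.setdiff1d(np.arange(1.0, nx + ny + 1), x)
            _, p = mannwhitney_u(x, y)
            assert p == pytest.approx(brute_force_mw_p(x, y), rel=1e-9)

    def test_simulated_disease_vs_healthy_strongly_significant(self):
        table = simulate_cohort(default_cohort_specs(), seed=3)
        c = compare_groups(table, "cir_nDNA", "COVID-19", "HI")
        assert c.p_value < 1e-4
        assert c.stars == "****"
        assert c.median_a > c.median_b

    def test_empty_group_is_an_error(self):
        table = pd.DataFrame({"group": ["A", "A"], "m": [1.0, 2.0]})
        with pytest.raises(AnalysisError):
            compare_groups(table, "m", "A", "B")

    def test_median_ci_brackets_the_median(self):
        rng = np.random.default_rng(0)
        values = rng.normal(10, 2, 101)
        lo, hi = median_ci(values)
        med = np.median(values)
        assert lo <= med <= hi
        assert (lo, hi) != (values.min(), values.max())

    def test_stars_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.00009) == "****"
        assert significance_stars(0.5) == "ns"


class TestCorrelation:
    def test_marker_with_itself_is_unity(self):
        table = simulate_cohort(default_cohort_specs(), seed=4)
        res = correlation_matrix(table, ["cir_nDNA", "NE"], group="HI")
        assert res.r.loc["cir_nDNA", "cir_nDNA"] == 1.0
        assert np.allclose(res.r.values, res.r.values.T, equal_nan=True)

    def test_anticorrelated_pair_reaches_minus_one(self):
        table = pd.DataFrame(
            {"group": "G", "a": [1.0, 2, 3, 4], "b": [8.0, 6, 4, 2]}
        )
        res = correlation_matrix(table, ["a", "b"])
        assert res.r.loc["a", "b"] == pytest.approx(-1.0)

    def test_sle_like_correlation_recovered_within_fisher_bound(self):
        """Log-scale target r = 0.85 at n = 10^4: sample r within 0.03."""
        sle = default_cohort_specs()[2]
        big = CohortSpec("SLE", 10_000, sle.medians, sle.log_sd, sle.correlation)
        table = simulate_cohort([big], seed=5)
        res = correlation_matrix(table, ["cir_nDNA", "NE"], log_scale=True)
        assert abs(res.r.loc["cir_nDNA", "NE"] - 0.85) < 0.03

    def test_null_correlation_small_at_large_n(self):
        hi = default_cohort_specs()[0]
        big = CohortSpec("HI", 10_000, hi.medians, hi.log_sd, hi.correlation)
        table = simulate_cohort([big], seed=6)
        res = correlation_matrix(table, ["cir_nDNA", "NE"], log_scale=True)
        assert abs(res.r.loc["cir_nDNA", "NE"]) < 0.05

    def test_zero_variance_marker_yields_nan_with_warning(self):
        table = pd.DataFrame({"group": "G", "a": [1.0, 1, 1, 1], "b": [1.0, 2, 3, 4]})
        with pytest.warns(UserWarning, match="zero"):
            res = correlation_matrix(table, ["a", "b"])
        assert math.isnan(res.r.loc["a", "b"])

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(0.01, 100), shift=st.floats(-50, 50))
    def test_pearson_invariant_under_positive_affine_transform(self, scale, shift):
        table = pd.DataFrame(
            {"group": "G", "a": [1.0, 3, 2, 5, 4], "b": [2.0, 5, 3, 9, 7]}
        )
        base = correlation_matrix(table, ["a", "b"]).r.loc["a", "b"]
        table["a"] = table["a"] * scale + shift
        transformed = correlation_matrix(table, ["a", "b"]).r.loc["a", "b"]
        assert transformed == pytest.approx(base, rel=1e-9)


class TestSummarizeAndSimulate:
    def test_single_row_echoed_as_median(self):
        table = pd.DataFrame({"group": ["G"], "m": [7.5]})
        out = summarize(table, ["m"])
        assert out.loc[0, "median"] == 7.5
        assert out.loc[0, "n"] == 1

    def test_three_value_group_median_is_middle(self):
        table = pd.DataFrame({"group": "G", "m": [9.0, 1.0, 5.0]})
        assert summarize(table, ["m"]).loc[0, "median"] == 5.0

    def test_row_permutation_invariance(self):
        table = simulate_cohort(default_cohort_specs(), seed=7)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = summarize(table).set_index(["group", "marker"])
        b = summarize(shuffled).set_index(["group", "marker"])
        pd.testing.assert_frame_equal(a, b)

    def test_group_medians_track_spec_locations(self):
        table = simulate_cohort(default_cohort_specs(), seed=8)
        med = table.groupby("group")["cir_nDNA"].median()
        assert med["COVID-19"] > 10 * med["HI"]  # ~20x by spec medians
        assert (table[list(COHORT_MARKERS)] > 0).all().all()

    def test_invalid_cohort_specs_rejected(self):
        good = default_cohort_specs()[0]
        with pytest.raises(SpecificationError):
            CohortSpec("G", 1, good.medians, good.log_sd, good.correlation)
        bad_corr = np.eye(len(COHORT_MARKERS))
        bad_corr[0, 1] = bad_corr[1, 0] = 1.5  # non-PSD
        with pytest.raises(SpecificationError):
            CohortSpec("G", 5, good.medians, good.log_sd, bad_corr)
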