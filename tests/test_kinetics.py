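"""Rate estimation, the subtraction attribution scheme, and decay fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragkin.errors import SpecificationError
from fragkin.kinetics import (
    TimeCourse,
    attributable_fraction,
    degradation_rate,
    enzyme_rate,
    excess_ratio,
    fit_decay,
    fold_decrease,
    nuclease_rate,
    percent_degraded,
)


def tc(cond, times, concs):
    return TimeCourse(cond, np.asarray(times, float), np.asarray(concs, float))


class TestDegradationRate:
    def test_two_hour_serum_control_rate(self):
        course = tc("serum", [0, 120], [500, 207])
        assert degradation_rate(course, 0, 120).rate == pytest.approx((500 - 207) / 120)

    def test_constant_course_rate_zero(self):
        course = tc("plasma_EDTA", [0, 120, 480], [500, 500, 500])
        assert degradation_rate(course, 0, 480).rate == 0.0

    def test_eight_hour_combined_enzyme_rate(self):
        course = tc("serum+NE+MPO", [0, 480], [500, 5])
        assert degradation_rate(course, 0, 480).rate == pytest.approx(495 / 480)

    def test_interval_endpoints_must_be_sampled(self):
        course = tc("serum", [0, 120], [500, 207])
        with pytest.raises(Exception):
            degradation_rate(course, 0, 60)

    def test_negative_rate_flagged_not_clipped(self):
        course = tc("serum", [0, 120], [100, 150])
        with pytest.warns(UserWarning, match="negative"):
            est = degradation_rate(course, 0, 120)
        assert est.rate < 0
        assert est.flagged

    def test_additivity_over_subintervals(self):
        course = tc("serum", [0, 120, 480], [500, 207, 124])
        r_full = degradation_rate(course, 0, 480).rate
        r1 = degradation_rate(course, 0, 120).rate
        r2 = degradation_rate(course, 120, 480).rate
        assert r_full == pytest.approx((r1 * 120 + r2 * 360) / 480)


class TestSubtractionScheme:
    def test_identical_courses_give_zero_nuclease_rate(self):
        a = tc("serum", [0, 120], [500, 207])
        b = tc("plasma_EDTA", [0, 120], [500, 207])
        assert nuclease_rate(a, b, (0, 120)).rate == 0.0

    def test_flat_plasma_attributes_all_to_nucleases(self):
        serum = tc("serum", [0, 120], [500, 207])
        plasma = tc("plasma_EDTA", [0, 120], [500, 500])
        assert nuclease_rate(serum, plasma, (0, 120)).rate == pytest.approx(293 / 120)

    def test_enzyme_rate_from_printed_two_hour_values(self):
        serum = tc("serum", [0, 120], [500, 207])
        ne = tc("serum+NE", [0, 120], [500, 64])
        est = enzyme_rate(ne, serum, (0, 120), attribution="NE")
        assert est.rate == pytest.approx((436 - 293) / 120)
        assert est.attribution == "NE"

    def test_enzyme_rate_from_printed_eight_hour_values(self):
        serum = tc("serum", [0, 480], [500, 124])
        both = tc("serum+NE+MPO", [0, 480], [500, 5])
        assert enzyme_rate(both, serum, (0, 480)).rate == pytest.approx(
            (495 - 376) / 480
        )

    def test_antisymmetric_under_argument_swap(self):
        serum = tc("serum", [0, 120], [500, 207])
        ne = tc("serum+NE", [0, 120], [500, 64])
        forward = enzyme_rate(ne, serum, (0, 120)).rate
        with pytest.warns(UserWarning):
            backward = enzyme_rate(serum, ne, (0, 120)).rate
        assert forward == pytest.approx(-backward)

    def test_mismatched_grids_error_without_interpolation(self):
        serum = tc("serum", [0, 120], [500, 207])
        plasma = tc("plasma_EDTA", [0, 100], [500, 480])
        with pytest.raises(Exception):
            nuclease_rate(serum, plasma, (0, 120))


class TestFoldAndPercent:
    @pytest.mark.parametrize(
        "control,treated,rounding,expected",
        [
            (124.0, 23.0, "auto", 5.4),
            (124.0, 16.0, "auto", 8.0),
            (124.0, 5.0, "auto", 25.0),
            (207.0, 64.0, "integer", 3.0),
            (100.0, 100.0, "none", 1.0),
        ],
    )
    def test_reporting_rules(self, control, treated, rounding, expected):
        assert fold_decrease(control, treated, rounding) == pytest.approx(expected)

    def test_zero_treated_is_infinite_and_flagged(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert math.isinf(fold_decrease(100.0, 0.0))

    @settings(max_examples=50, deadline=None)
    @given(
        c=st.floats(1e-3, 1e6),
        fold=st.floats(1.0, 1e3),
        scale=st.floats(1e-3, 1e3),
    )
    def test_fold_scale_invariant(self, c, fold, scale):
        raw = fold_decrease(c * fold, c)
        scaled = fold_decrease(c * fold * scale, c * scale)
        assert raw == pytest.approx(scaled, rel=1e-9)
        assert fold_decrease(c, c) == pytest.approx(1.0)

    def test_percent_degraded_examples(self):
        assert percent_degraded(500.0, 5.0) == pytest.approx(99.0)
        assert percent_degraded(500.0, 500.0) == 0.0
        assert percent_degraded(100.0, 28.7) == pytest.approx(71.3)

    def test_net_vs_serum_excess(self):
        assert excess_ratio(0.36, 0.012) == pytest.approx(30.0)
        assert attributable_fraction(0.36, 0.012) >= 0.95


class TestFitDecay:
    def test_noiseless_single_exponential_recovered(self):
        t = np.array([0.0, 10, 30, 60, 120, 240, 480])
        k = 0.01
        course = tc("serum", t, 300.0 * np.exp(-k * t))
        fit = fit_decay(course, "single_exponential")
        assert fit.params["k"] == pytest.approx(k, rel=1e-6)
        assert fit.params["A"] == pytest.approx(300.0, rel=1e-6)
        assert not fit.underdetermined

    def test_noiseless_fit_matches_loglinear_slope(self):
        t = np.array([0.0, 60, 120, 240, 480])
        k = 0.004
        course = tc("serum", t, 100.0 * np.exp(-k * t))
        fit = fit_decay(course)
        slope = np.polyfit(t, np.log(course.concentrations), 1)[0]
        assert fit.params["k"] == pytest.approx(-slope, rel=1e-9)

    def test_biexponential_parameter_recovery_under_noise(self):
        """Median parameter error < 10% over 50 noisy replicates (5% CV)."""
        rng = np.random.default_rng(13)
        t = np.array([0.0, 2, 4, 7, 10, 15, 20, 30, 60, 120, 240, 480, 1440])
        truth = {"A_fast": 60.0, "k_fast": 0.07, "A_slow": 40.0, "k_slow": 0.0005}
        clean = truth["A_fast"] * np.exp(-truth["k_fast"] * t) + truth["A_slow"] * np.exp(
            -truth["k_slow"] * t
        )
        errors = {name: [] for name in truth}
        for _ in range(50):
            noisy = clean * np.exp(rng.normal(0.0, 0.05, t.size))
            fit = fit_decay(tc("serum", t, noisy), "biexponential")
            for name in truth:
                errors[name].append(abs(fit.params[name] - truth[name]) / truth[name])
        for name, errs in errors.items():
            assert np.median(errs) < 0.10, name

    def test_three_point_biexponential_flagged_underdetermined(self):
        """The printed 28/48/71% losses define only 3 points for 4 parameters."""
        course = tc("serum", [0.0, 10, 30, 1440], [100.0, 72, 52, 29])
        fit = fit_decay(course, "biexponential")
        assert fit.underdetermined
        assert fit.rss == pytest.approx(0.0, abs=1e-8)

    def test_insufficient_points_rejected(self):
        with pytest.raises(SpecificationError):
            fit_decay(tc("serum", [0.0, 10, 30], [100, 70, 50]), "biexponential")
        with pytest.raises(SpecificationError):
            fit_decay(tc("serum", [0.0, 10], [100, 0]), "single_exponential")
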