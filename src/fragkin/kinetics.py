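"""Degradation kinetics of DNA incubated in blood fluids.

High-molecular-weight chromatin spiked into serum is degraded by serum
nucleases; adding neutrophil elastase (NE) and/or myeloperoxidase (MPO)
accelerates the loss. Because EDTA plasma inhibits nucleases almost
completely, the plasma control isolates the baseline, and rate
differences between conditions attribute degradation to nucleases or to
the added enzymes:

* overall rate: ``(C(t0) - C(t1)) / (t1 - t0)`` in ng DNA/mL/min;
* nuclease rate: overall rate in control serum minus control plasma;
* enzyme rate: overall rate in enzyme-supplemented serum minus control
  serum.

These are bulk concentration rates, not enzymatic activities. Decay
model fits (single or biexponential) are provided for parameter
recovery on simulated time courses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from fragkin.errors import AnalysisError, SpecificationError

__all__ = [
    "TimeCourse",
    "RateEstimate",
    "DecayFit",
    "degradation_rate",
    "nuclease_rate",
    "enzyme_rate",
    "fold_decrease",
    "percent_degraded",
    "excess_ratio",
    "attributable_fraction",
    "fit_decay",
]


@dataclass
class TimeCourse:
    """Concentration-vs-time series for one incubation condition."""

    condition: str
    times: np.ndarray  # minutes
    concentrations: np.ndarray  # ng/mL of source fluid
    analyte: str = "total"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise SpecificationError("times and concentrations must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise SpecificationError("times must be strictly increasing")
        if (self.concentrations < 0).any():
            raise SpecificationError("concentrations must be non-negative")

    def at(self, t: float) -> float:
        idx = np.flatnonzero(self.times == t)
        if idx.size == 0:
            raise AnalysisError(f"time {t} min is not on the sampling grid of {self.condition}")
        return float(self.concentrations[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "analyte": self.analyte,
                "time_min": self.times,
                "conc_ng_per_ml": self.concentrations,
            }
        )


@dataclass(frozen=True)
class RateEstimate:
    """A degradation rate over an interval, in ng DNA/mL/min."""

    t0: float
    t1: float
    rate: float
    attribution: str = "overall"
    flagged: bool = False  # set when the estimate is negative (concentration rose)


def degradation_rate(tc: TimeCourse, t0: float, t1: float) -> RateEstimate:
    """Overall degradation rate ``(C(t0) - C(t1)) / (t1 - t0)``."""
    if t1 <= t0:
        raise SpecificationError("t1 must exceed t0")
    c0, c1 = tc.at(t0), tc.at(t1)
    rate = (c0 - c1) / (t1 - t0)
    flagged = rate < 0
    if flagged:
        warnings.warn(
            f"negative degradation rate for {tc.condition} over ({t0}, {t1}) min",
            stacklevel=2,
        )
    return RateEstimate(t0, t1, rate, "overall", flagged)


def _rate_difference(
    a: TimeCourse, b: TimeCourse, interval: tuple[float, float], attribution: str
) -> RateEstimate:
    t0, t1 = interval
    ra = degradation_rate(a, t0, t1)
    rb = degradation_rate(b, t0, t1)
    rate = ra.rate - rb.rate
    flagged = rate < 0
    if flagged:
        warnings.warn(
            f"negative {attribution} rate over ({t0}, {t1}) min; reported unclipped",
            stacklevel=3,
        )
    return RateEstimate(t0, t1, rate, attribution, flagged)


def nuclease_rate(
    serum_ctrl: TimeCourse, plasma_ctrl: TimeCourse, interval: tuple[float, float]
) -> RateEstimate:
    """Serum-nuclease rate: control serum minus control (EDTA) plasma.

    EDTA chelation suppresses nuclease activity in plasma, so the
    difference in overall rates attributes degradation to serum
    nucleases. Both courses must sample the interval endpoints exactly;
    no interpolation is performed.
    """
    return _rate_difference(serum_ctrl, plasma_ctrl, interval, "nuclease")


def enzyme_rate(
    treated_serum: TimeCourse,
    serum_ctrl: TimeCourse,
    interval: tuple[float, float],
    attribution: str = "enzyme",
) -> RateEstimate:
    """Enzyme-specific rate: enzyme-supplemented serum minus control serum."""
    return _rate_difference(treated_serum, serum_ctrl, interval, attribution)


def fold_decrease(
    c_control: float, c_treated: float, rounding: str = "none"
) -> float:
    """Fold decrease of concentration relative to a control.

    ``rounding`` selects the reporting convention: ``"none"`` returns the
    raw ratio; ``"decimal"`` rounds to one decimal; ``"integer"`` rounds
    to the nearest integer; ``"auto"`` mimics mixed report style —
    nearest integer for folds >= 7.5, one decimal otherwise.
    """
    if c_control < 0 or c_treated < 0:
        raise SpecificationError("concentrations must be non-negative")
    if c_treated == 0:
        warnings.warn("treated concentration is zero; fold decrease is infinite", stacklevel=2)
        return math.inf
    fold = c_control / c_treated
    if rounding == "none":
        return fold
    if rounding == "decimal":
        return round(fold, 1)
    if rounding == "integer":
        return float(round(fold))
    if rounding == "auto":
        return float(round(fold)) if fold >= 7.5 else round(fold, 1)
    raise SpecificationError(f"unknown rounding rule {rounding!r}")


def percent_degraded(c0: float, ct: float) -> float:
    """Percent of the initial concentration lost: ``100 (c0 - ct) / c0``."""
    if c0 <= 0:
        raise SpecificationError("initial concentration must be positive")
    return 100.0 * (c0 - ct) / c0


def excess_ratio(c_a: float, c_b: float) -> float:
    """Ratio of two concentrations (e.g. NET DNA over background cirDNA)."""
    if c_b <= 0:
        raise SpecificationError("denominator concentration must be positive")
    return c_a / c_b


def attributable_fraction(c_source: float, c_background: float) -> float:
    """Fraction of total DNA attributable to a source over background.

    ``c_source / (c_source + c_background)`` — e.g. the fraction of
    fragments in a mixed fluid that originate from spiked NET DNA rather
    than the fluid's endogenous cirDNA.
    """
    total = c_source + c_background
    if total <= 0:
        raise SpecificationError("total concentration must be positive")
    return c_source / total


@dataclass
class DecayFit:
    """Result of an exponential decay fit."""

    model: str
    params: dict[str, float]
    rss: float
    residuals: np.ndarray
    converged: bool
    underdetermined: bool

    def halflife(self, which: str = "k") -> float:
        return math.log(2.0) / self.params[which]


def _single_exp_log(t, log_a, k):
    return log_a - k * t


def _biexp_log(t, log_a1, k_fast, log_a2, k_slow):
    return np.log(np.exp(log_a1 - k_fast * t) + np.exp(log_a2 - k_slow * t))


def fit_decay(tc: TimeCourse, model: str = "single_exponential") -> DecayFit:
    """Fit an exponential decay model to a time course.

    Nonlinear least squares on log-concentration. The single model is
    ``C(t) = A exp(-k t)``; the biexponential is
    ``C(t) = A_fast exp(-k_fast t) + A_slow exp(-k_slow t)`` with
    ``k_fast > k_slow > 0`` enforced by sorting the fitted pair. A fit
    with no more data points than parameters is flagged as
    underdetermined (and its residuals are ~0 by construction).
    """
    if (tc.concentrations <= 0).any():
        raise SpecificationError("decay fitting requires strictly positive concentrations")
    t = tc.times
    log_c = np.log(tc.concentrations)
    n_params = 2 if model == "single_exponential" else 4
    if t.size < n_params:
        raise SpecificationError(
            f"{model} fit needs at least {n_params} points, got {t.size}"
        )
    underdetermined = t.size <= n_params

    if model == "single_exponential":
        slope, intercept, *_ = stats.linregress(t, log_c)
        k0 = max(-slope, 1e-8)
        try:
            popt, _ = optimize.curve_fit(
                _single_exp_log, t, log_c, p0=[intercept, k0], maxfev=10_000
            )
            converged = True
        except RuntimeError:
            popt, converged = np.array([intercept, k0]), False
        fitted = _single_exp_log(t, *popt)
        params = {"A": float(np.exp(popt[0])), "k": float(popt[1])}
    elif model == "biexponential":
        # heuristic start: fast phase from the first interval, slow from the last
        k_fast0 = max((log_c[0] - log_c[1]) / (t[1] - t[0] + 1e-12), 1e-4)
        k_slow0 = max((log_c[-2] - log_c[-1]) / (t[-1] - t[-2] + 1e-12), 1e-6)
        if k_slow0 >= k_fast0:
            k_slow0 = k_fast0 / 10.0
        a0 = np.log(max(tc.concentrations[0] / 2.0, 1e-12))
        p0 = [a0, k_fast0, a0, k_slow0]
        try:
            popt, _ = optimize.curve_fit(
                _biexp_log,
                t,
                log_c,
                p0=p0,
                bounds=([-np.inf, 1e-12, -np.inf, 1e-12], [np.inf, np.inf, np.inf, np.inf]),
                maxfev=20_000,
            )
            converged = True
        except RuntimeError:
            popt, converged = np.array(p0), False
        phases = sorted(
            [(float(popt[1]), float(np.exp(popt[0]))), (float(popt[3]), float(np.exp(popt[2])))],
            reverse=True,
        )
        params = {
            "A_fast": phases[0][1],
            "k_fast": phases[0][0],
            "A_slow": phases[1][1],
            "k_slow": phases[1][0],
        }
        fitted = _biexp_log(t, *popt)
    else:
        raise SpecificationError(f"unknown decay model {model!r}")

    residuals = log_c - fitted
    if not converged:
        warnings.warn(f"{model} fit did not converge for {tc.condition}", stacklevel=2)
    return DecayFit(
        model=model,
        params=params,
        rss=float(residuals @ residuals),
        residuals=residuals,
        converged=converged,
        underdetermined=underdetermined,
    )
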