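"""Group-level biomarker statistics for cirDNA/NET marker cohorts.

Group comparisons use the two-sided Mann-Whitney rank test (exact null
for small untied samples, tie-corrected normal approximation with
continuity correction otherwise) with medians and binomial
order-statistic 95% confidence intervals; association is measured by
Pearson correlation matrices with pairwise-complete observations. Raw
p-values are reported by default (the optional Benjamini-Hochberg
adjustment is off unless requested).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from fragkin.errors import AnalysisError, SpecificationError

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "mannwhitney_u",
    "compare_groups",
    "correlation_matrix",
    "summarize",
    "median_ci",
    "significance_stars",
]

_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def median_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Distribution-free CI of the median from binomial order statistics.

    The interval [x_(l), x_(u)] with l = qbinom(alpha/2, n, 1/2) and
    u = n + 1 - l covers the median with at least the nominal level;
    for very small n it spans the whole sample.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise AnalysisError("median CI needs at least 2 values")
    alpha = 1.0 - level
    l = int(stats.binom.ppf(alpha / 2.0, n, 0.5))  # 0-based lower index
    u = n - 1 - l
    if l > u:
        l, u = 0, n - 1
    return float(x[l]), float(x[u])


def mannwhitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U of the first sample, p).

    Exact null distribution when min(n_x, n_y) <= 20 and there are no
    ties; otherwise a normal approximation with tie correction and a
    continuity correction of the form max(0, |U - mu| - 1/2), which
    yields p = 1 exactly for identical samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise AnalysisError("both groups must be non-empty")
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    ranks = stats.rankdata(combined)
    rank_sum_x = ranks[:nx].sum()
    u_x = rank_sum_x - nx * (nx + 1) / 2.0

    if not has_ties and min(nx, ny) <= 20:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(u_x), float(res.pvalue)

    mu = nx * ny / 2.0
    n = nx + ny
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u_x), 1.0  # all values identical
    z = max(0.0, abs(u_x - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return float(u_x), p


@dataclass
class GroupComparison:
    marker: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    u_statistic: float
    p_value: float
    stars: str


def compare_groups(
    table: pd.DataFrame, marker: str, group_a: str, group_b: str
) -> GroupComparison:
    """Compare one marker between two cohort groups.

    Missing values are dropped per group; each group needs at least two
    non-missing observations.
    """
    if marker not in table.columns:
        raise SpecificationError(f"marker {marker!r} not in table")
    vals = {}
    for g in (group_a, group_b):
        v = table.loc[table["group"] == g, marker].dropna().to_numpy(dtype=float)
        if v.size < 2:
            raise AnalysisError(f"group {g!r} has fewer than 2 non-missing values")
        vals[g] = v
    x, y = vals[group_a], vals[group_b]
    u, p = mannwhitney_u(x, y)
    return GroupComparison(
        marker=marker,
        group_a=group_a,
        group_b=group_b,
        n_a=x.size,
        n_b=y.size,
        median_a=float(np.median(x)),
        median_b=float(np.median(y)),
        ci_a=median_ci(x),
        ci_b=median_ci(y),
        u_statistic=u,
        p_value=p,
        stars=significance_stars(p),
    )


@dataclass
class CorrelationResult:
    """Pearson correlation matrix with per-pair p-values and counts."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    method: str = "pearson, pairwise-complete observations"


def correlation_matrix(
    table: pd.DataFrame,
    markers: list[str],
    group: str | None = None,
    log_scale: bool = False,
) -> CorrelationResult:
    """Pairwise Pearson correlations between markers (optionally one group).

    Pairwise-complete handling: each pair uses the subjects with both
    markers present. ``log_scale`` correlates log-transformed values
    (appropriate for log-normally distributed concentrations). A
    zero-variance marker yields NaN correlations with a warning.
    """
    df = table if group is None else table[table["group"] == group]
    missing = set(markers) - set(df.columns)
    if missing:
        raise SpecificationError(f"markers not in table: {sorted(missing)}")
    k = len(markers)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            sub = df[[markers[i], markers[j]]].dropna()
            xi = sub.iloc[:, 0].to_numpy(dtype=float)
            xj = sub.iloc[:, 1].to_numpy(dtype=float)
            n[i, j] = n[j, i] = xi.size
            if i == j:
                if np.ptp(xi) == 0:
                    warnings.warn(f"marker {markers[i]!r} has zero variance", stacklevel=2)
                    continue
                r[i, i], p[i, i] = 1.0, 0.0
                continue
            if xi.size < 3:
                raise AnalysisError(
                    f"pair ({markers[i]}, {markers[j]}) has fewer than 3 complete records"
                )
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                warnings.warn(
                    f"zero-variance marker in pair ({markers[i]}, {markers[j]})",
                    stacklevel=2,
                )
                continue
            if log_scale:
                xi, xj = np.log(xi), np.log(xj)
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    method = "pearson, pairwise-complete observations" + (", log scale" if log_scale else "")
    return CorrelationResult(
        r=pd.DataFrame(r, index=markers, columns=markers),
        p=pd.DataFrame(p, index=markers, columns=markers),
        n=pd.DataFrame(n, index=markers, columns=markers),
        method=method,
    )


def summarize(table: pd.DataFrame, markers: list[str] | None = None) -> pd.DataFrame:
    """Per-group median / IQR / n for each marker, deterministically ordered."""
    if table.empty:
        raise AnalysisError("cohort table is empty")
    if markers is None:
        markers = [
            c
            for c in table.columns
            if c not in ("subject", "group") and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for g in sorted(table["group"].unique()):
        sub = table[table["group"] == g]
        for m in markers:
            v = sub[m].dropna().to_numpy(dtype=float)
            rows.append(
                {
                    "group": g,
                    "marker": m,
                    "n": int(sub.shape[0]),
                    "median": float(np.median(v)) if v.size else math.nan,
                    "q1": float(np.percentile(v, 25)) if v.size else math.nan,
                    "q3": float(np.percentile(v, 75)) if v.size else math.nan,
                }
            )
    return pd.DataFrame(rows)
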