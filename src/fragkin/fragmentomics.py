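"""Fragment-size profiling of cell-free DNA from aligned read pairs.

Shallow whole-genome sequencing of cfDNA measures each fragment's length
through the signed template-length (TLEN) field of its aligned read
pair, giving a 1 bp resolution size profile. This module extracts insert
sizes with the standard hygiene filters (supplementary/secondary
alignments, PCR duplicates, low mapping quality, 0-1000 bp window),
builds 1 bp histograms, and quantifies nucleosomal structure: peak
positions, the ~10 bp sub-nucleosomal periodicity, mono-/di-/tri-
nucleosome/long fragment fractions, and capillary-electrophoresis style
smear summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import signal

from fragkin.errors import AnalysisError, SpecificationError

__all__ = [
    "FragmentProfile",
    "FractionBins",
    "Peak",
    "PeakSet",
    "CETrace",
    "extract_insert_sizes",
    "read_fragment_tsv",
    "build_profile",
    "detect_peaks",
    "estimate_periodicity",
    "nucleosomal_fractions",
    "ce_summary",
    "DEFAULT_BINS",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class FragmentProfile:
    """1 bp resolution fragment-length histogram.

    ``counts[i]`` holds the count (or frequency, if ``normalized``) of
    fragments of length ``min_len + i`` bp.
    """

    counts: np.ndarray
    min_len: int
    max_len: int
    normalized: bool = False
    source: str = "all"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.max_len - self.min_len + 1,):
            raise SpecificationError("counts length must equal max_len - min_len + 1")
        if (self.counts < 0).any():
            raise SpecificationError("profile counts must be non-negative")

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.min_len, self.max_len + 1)

    @property
    def n_total(self) -> float:
        return float(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise AnalysisError("profile has zero total mass")
        return self.counts / total

    def normalize(self) -> "FragmentProfile":
        """Return a frequency-normalized copy (idempotent)."""
        if self.normalized:
            return self
        return FragmentProfile(
            self.frequencies(), self.min_len, self.max_len, normalized=True, source=self.source
        )

    def to_frame(self) -> pd.DataFrame:
        freq = self.frequencies() if self.counts.sum() > 0 else self.counts
        return pd.DataFrame(
            {"length_bp": self.lengths, "count": self.counts, "frequency": freq}
        )


@dataclass(frozen=True)
class FractionBins:
    """Inclusive bp intervals for nucleosomal fragment classes.

    Defaults: mono 20-259, di 260-459 (the di-nucleosome peak interval),
    tri 460-700, long 701-1000, all within the 20-1000 bp window used
    for profile fractions.
    """

    mono_range: tuple[int, int] = (20, 259)
    di_range: tuple[int, int] = (260, 459)
    tri_range: tuple[int, int] = (460, 700)
    long_range: tuple[int, int] = (701, 1000)
    overall_range: tuple[int, int] = (20, 1000)

    def __post_init__(self) -> None:
        ranges = [self.mono_range, self.di_range, self.tri_range, self.long_range]
        lo, hi = self.overall_range
        prev_end = lo - 1
        for a, b in ranges:
            if a > b:
                raise SpecificationError(f"invalid interval ({a}, {b})")
            if a <= prev_end:
                raise SpecificationError("fraction intervals must be ordered and disjoint")
            if a < lo or b > hi:
                raise SpecificationError("fraction intervals must lie within overall_range")
            prev_end = b


DEFAULT_BINS = FractionBins()


@dataclass(frozen=True)
class Peak:
    position: int
    frequency: float
    prominence: float


@dataclass
class PeakSet:
    """Detected profile peaks; the global mode is listed first."""

    peaks: list[Peak]
    periodicity_estimate: int | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def positions(self) -> list[int]:
        return [p.position for p in self.peaks]


@dataclass
class CETrace:
    """Capillary-electrophoresis trace: signal intensity vs fragment size."""

    sizes: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.sizes.shape != self.signals.shape:
            raise SpecificationError("sizes and signals must have the same shape")
        if np.any(np.diff(self.sizes) <= 0):
            raise SpecificationError("trace sizes must be strictly increasing")
        if (self.signals < 0).any():
            raise SpecificationError("trace signals must be non-negative")


# ---------------------------------------------------------------------------
# insert-size extraction


def _iter_records(records) -> Iterable[pysam.AlignedSegment]:
    if isinstance(records, (str, Path)):
        with pysam.AlignmentFile(str(records), check_sq=False) as fh:
            yield from fh
    else:
        yield from records


def extract_insert_sizes(
    records,
    chrom_filter: set[str] | None = None,
    mapq_min: int = 20,
    size_window: tuple[int, int] = (0, 1000),
) -> np.ndarray:
    """Extract fragment lengths from aligned read pairs.

    One length is emitted per retained pair, taken from the mate with
    positive template length so each pair is counted exactly once.
    Pairs are dropped when any of the following holds: supplementary or
    secondary alignment, PCR-duplicate flag, unmapped, mapping quality
    below ``mapq_min``, or absolute template length outside the
    half-open window ``(size_window[0], size_window[1]]``. When
    ``chrom_filter`` is given, only pairs on those reference names are
    retained (e.g. ``{"chrY"}`` for a sex-mismatch spike-in design).

    Parameters
    ----------
    records
        Path to a SAM/BAM file, or an iterable of ``pysam.AlignedSegment``.
    """
    lo, hi = size_window
    out: list[int] = []
    saw_paired = False
    for rec in _iter_records(records):
        if rec.is_paired:
            saw_paired = True
        tlen = rec.template_length
        if tlen <= 0:  # count each pair once, via the leftmost mate
            continue
        if (
            rec.is_supplementary
            or rec.is_secondary
            or rec.is_duplicate
            or rec.is_unmapped
            or rec.mapping_quality < mapq_min
        ):
            continue
        if not (lo < tlen <= hi):
            continue
        if chrom_filter is not None and rec.reference_name not in chrom_filter:
            continue
        out.append(tlen)
    if not saw_paired and not out:
        warnings.warn("no paired records found in stream", stacklevel=2)
    return np.asarray(out, dtype=np.int64)


def read_fragment_tsv(
    path,
    chrom_filter: set[str] | None = None,
    size_window: tuple[int, int] = (0, 1000),
    deduplicate: bool = True,
) -> np.ndarray:
    """Read fragment lengths from a (chrom, length[, start]) TSV.

    When a ``start`` column is present and ``deduplicate`` is true,
    identical (chrom, start, length) rows collapse to one fragment,
    mirroring coordinate-based PCR-duplicate marking.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "length"}
    if not required.issubset(df.columns):
        raise SpecificationError(f"fragment TSV needs columns {sorted(required)}")
    if deduplicate and "start" in df.columns:
        df = df.drop_duplicates(subset=["chrom", "start", "length"])
    if chrom_filter is not None:
        df = df[df["chrom"].isin(chrom_filter)]
    lo, hi = size_window
    lengths = df["length"].to_numpy(dtype=np.int64)
    return lengths[(lengths > lo) & (lengths <= hi)]


# ---------------------------------------------------------------------------
# profiles


def build_profile(
    lengths: Sequence[int] | np.ndarray,
    min_len: int = 1,
    max_len: int = 1000,
    clip: bool = False,
    source: str = "all",
) -> FragmentProfile:
    """Histogram fragment lengths at 1 bp resolution over [min_len, max_len].

    Lengths outside the range are dropped (or clipped to the range edges
    when ``clip`` is true). An empty input is an error: a profile of
    nothing is undefined.
    """
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise AnalysisError("cannot build a profile from zero fragments")
    if clip:
        arr = np.clip(arr, min_len, max_len)
    else:
        arr = arr[(arr >= min_len) & (arr <= max_len)]
        if arr.size == 0:
            raise AnalysisError("no fragments within [min_len, max_len]")
    counts = np.bincount(arr - min_len, minlength=max_len - min_len + 1).astype(float)
    return FragmentProfile(counts, min_len, max_len, normalized=False, source=source)


def _smooth(freq: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return freq
    kernel = np.ones(window) / window
    # reflect-pad so edge bins keep comparable support
    pad = window // 2
    padded = np.concatenate([freq[pad:0:-1], freq, freq[-2 : -pad - 2 : -1]])
    return np.convolve(padded, kernel, mode="valid")


def detect_peaks(
    profile: FragmentProfile,
    smooth_window: int = 3,
    min_prominence: float = 0.10,
) -> PeakSet:
    """Locate local maxima of the smoothed size profile.

    The profile is smoothed with a centered moving average
    (``smooth_window`` bp) and local maxima are kept when their
    prominence exceeds ``min_prominence`` times the global-mode
    frequency. The global mode is reported first; remaining peaks follow
    in order of decreasing prominence, ties broken toward the smaller
    length. A flat profile yields an empty set.
    """
    prof = profile.normalize()
    freq = prof.counts
    if np.allclose(freq, freq[0]):
        return PeakSet(peaks=[])
    if np.count_nonzero(freq) == 1:
        mode = int(np.argmax(freq))
        pos = prof.min_len + mode
        return PeakSet(peaks=[Peak(pos, float(freq[mode]), float(freq[mode]))])
    smoothed = _smooth(freq, smooth_window)
    idx, props = signal.find_peaks(smoothed, prominence=0.0)
    if idx.size == 0:
        return PeakSet(peaks=[])
    prominences = props["prominences"]
    threshold = min_prominence * smoothed.max()
    keep = prominences >= threshold
    idx, prominences = idx[keep], prominences[keep]
    if idx.size == 0:
        return PeakSet(peaks=[])
    order = sorted(range(idx.size), key=lambda i: (-prominences[i], idx[i]))
    peaks = [
        Peak(int(prof.min_len + idx[i]), float(freq[idx[i]]), float(prominences[i]))
        for i in order
    ]
    # global mode of the smoothed profile leads; ties toward smaller length
    mode_val = max(smoothed[i] for i in idx)
    mode_idx = min(int(i) for i in idx if smoothed[i] == mode_val)
    mode_pos = int(prof.min_len + mode_idx)
    peaks.sort(key=lambda p: (p.position != mode_pos,))
    return PeakSet(peaks=peaks)


def estimate_periodicity(
    profile: FragmentProfile,
    window: tuple[int, int] = (41, 166),
    lag_range: tuple[int, int] = (5, 15),
    n_permutations: int = 1000,
    random_state: int = 0,
) -> int | None:
    """Estimate the sub-nucleosomal subpeak spacing (bp).

    The profile restricted to ``window`` is detrended by subtracting a
    centered moving-average baseline (the size profile rises steeply
    toward the mononucleosome mode, so a linear detrend alone leaves
    curvature that masks the oscillation), and the autocorrelation of
    the residual is maximized over integer lags in ``lag_range``. The
    winning lag is returned only if its autocorrelation exceeds the 95th
    percentile of the maxima obtained from ``n_permutations`` random
    shuffles of the residual (otherwise ``None``: no periodic structure
    detected).
    """
    prof = profile.normalize()
    lo, hi = window
    if lo < prof.min_len or hi > prof.max_len:
        raise SpecificationError("periodicity window must lie within the profile support")
    seg = prof.counts[lo - prof.min_len : hi - prof.min_len + 1].astype(float)
    if seg.size < 3 * lag_range[0]:
        raise SpecificationError("window too short for periodicity estimation")
    baseline_window = 2 * lag_range[0] + 1
    detrended = seg - _smooth(seg, baseline_window)
    # a smooth (e.g. strictly monotone) profile has no residual oscillation
    if float(detrended @ detrended) <= 1e-12 * max(float(seg @ seg), 1e-300):
        return None

    def max_acf(x: np.ndarray) -> tuple[int, float]:
        x = x - x.mean()
        denom = float(x @ x)
        if denom == 0:
            return lag_range[0], -np.inf
        best_lag, best = lag_range[0], -np.inf
        for lag in range(lag_range[0], lag_range[1] + 1):
            r = float(x[:-lag] @ x[lag:]) / denom
            if r > best:
                best, best_lag = r, lag
        return best_lag, best

    lag, observed = max_acf(detrended)
    rng = np.random.default_rng(random_state)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = max_acf(rng.permutation(detrended))[1]
    if observed <= np.quantile(null, 0.95):
        return None
    return int(lag)


def nucleosomal_fractions(
    profile: FragmentProfile, bins: FractionBins = DEFAULT_BINS
) -> dict[str, float]:
    """Mono/di/tri-nucleosome and long fragment fractions of profile mass.

    Each fraction is the profile mass inside its interval divided by the
    mass inside ``bins.overall_range``; together with ``residual`` (mass
    in the overall range not assigned to any class) they sum to one.
    Invariant to whether the profile is count- or frequency-scaled.
    """
    lo, hi = bins.overall_range
    if lo < profile.min_len or hi > profile.max_len:
        raise AnalysisError("profile does not cover bins.overall_range")
    counts = profile.counts

    def mass(a: int, b: int) -> float:
        return float(counts[a - profile.min_len : b - profile.min_len + 1].sum())

    total = mass(lo, hi)
    if total == 0:
        raise AnalysisError("zero profile mass in overall_range")
    out = {
        "mono": mass(*bins.mono_range) / total,
        "di": mass(*bins.di_range) / total,
        "tri": mass(*bins.tri_range) / total,
        "long": mass(*bins.long_range) / total,
    }
    out["residual"] = 1.0 - sum(out.values())
    return out


def ce_summary(
    trace: CETrace, long_range: tuple[float, float] = (1000.0, 10_000.0)
) -> tuple[float, float | None]:
    """Long-fragment smear summary of a capillary-electrophoresis trace.

    Returns ``(fraction, mean_size)``: the fraction of total trapezoidal
    signal area within ``long_range`` and the signal-weighted mean
    fragment size inside that range (``None`` when the range holds no
    signal).
    """
    total = float(np.trapezoid(trace.signals, trace.sizes))
    if total <= 0:
        raise AnalysisError("CE trace has zero total signal")
    lo, hi = long_range
    if lo < trace.sizes[0] or hi > trace.sizes[-1]:
        raise AnalysisError("trace does not span long_range")
    mask = (trace.sizes >= lo) & (trace.sizes <= hi)
    if mask.sum() < 2:
        return 0.0, None
    s, y = trace.sizes[mask], trace.signals[mask]
    area = float(np.trapezoid(y, s))
    if area <= 0:
        return 0.0, None
    mean_size = float(np.trapezoid(y * s, s) / area)
    return area / total, mean_size
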