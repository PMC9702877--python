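"""Synthetic cell-free DNA fragment-length populations.

Circulating DNA size profiles are dominated by nucleosome-protected
fragment populations: a mononucleosome (chromatosome) mode near 167 bp,
a dinucleosome mode near 320-365 bp, a fainter trinucleosome mode near
560 bp, a sub-nucleosomal ladder below ~167 bp whose subpeaks repeat
with ~10 bp periodicity (nuclease nicks at exposed minor-groove sites on
the nucleosome surface), and a high-molecular-weight (HMW) chromatin
tail reaching tens of kilobases.  A :class:`PopulationSpec` describes a
mixture of these components; :func:`sample_fragment_lengths` draws
integer fragment lengths from it at 1 bp resolution.

Component families
------------------
``monoN`` / ``diN`` / ``triN``
    Discretized Laplace peaks: sharp cusped modes, as observed in 1-bp
    size profiles. ``location`` is the mode, ``scale`` the Laplace scale
    (bp); ``scale = 0`` degenerates to a point mass.
``subnuc``
    Sub-nucleosomal ladder on ``[subnuc_min, location]``: an exponential
    baseline rising toward the mononucleosome mode multiplied by a
    sawtooth of period ``sawtooth_period``.
``hmw``
    Log-normal tail; ``location`` is the median (bp) and ``scale`` the
    log standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from fragkin.errors import SpecificationError

COMPONENT_LABELS = ("subnuc", "monoN", "diN", "triN", "hmw")

__all__ = [
    "Component",
    "PopulationSpec",
    "sample_fragment_lengths",
    "healthy_population",
    "late_degradation_population",
    "net_supernatant_population",
    "ghmw_population",
]


@dataclass(frozen=True)
class Component:
    """One mixture component of a fragment-length population."""

    label: str
    weight: float
    location: float
    scale: float

    def __post_init__(self) -> None:
        if self.label not in COMPONENT_LABELS:
            raise SpecificationError(
                f"unknown component label {self.label!r}; expected one of {COMPONENT_LABELS}"
            )
        if self.weight < 0:
            raise SpecificationError(f"component weight must be >= 0, got {self.weight}")
        if self.location <= 0:
            raise SpecificationError(f"component location must be > 0, got {self.location}")
        if self.scale < 0:
            raise SpecificationError(f"component scale must be >= 0, got {self.scale}")


@dataclass(frozen=True)
class PopulationSpec:
    """Mixture of nucleosomal fragment-length components.

    Parameters
    ----------
    components
        Mixture components; weights must sum to one.
    sawtooth_period
        Spacing (bp) of the sub-nucleosomal subpeaks.
    sawtooth_amplitude
        Peak-to-baseline modulation depth of the sawtooth (0 disables it).
    sawtooth_phase
        Residue class (mod period) immediately *after* each subpeak; the
        default places subpeaks at ..., 147, 157 bp.
    subnuc_min
        Lower support bound (bp) of the sub-nucleosomal ladder.
    max_len
        Upper support bound (bp) of the whole population.
    """

    components: tuple[Component, ...]
    sawtooth_period: float = 10.0
    sawtooth_amplitude: float = 2.0
    sawtooth_phase: int = 8
    subnuc_min: int = 41
    max_len: int = 40_000

    def __post_init__(self) -> None:
        if not self.components:
            raise SpecificationError("PopulationSpec needs at least one component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise SpecificationError(f"component weights must sum to 1, got {total}")
        if self.sawtooth_period <= 0:
            raise SpecificationError("sawtooth_period must be > 0")
        if self.max_len < max(c.location for c in self.components):
            raise SpecificationError("max_len must cover the largest component location")
        if self.subnuc_min < 1:
            raise SpecificationError("subnuc_min must be >= 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def component_pmf(self, comp: Component) -> np.ndarray:
        """Probability mass over lengths 0..max_len (index = length in bp)."""
        L = np.arange(self.max_len + 1, dtype=float)
        p = np.zeros_like(L)
        if comp.label in ("monoN", "diN", "triN"):
            if comp.scale == 0:
                p[int(round(comp.location))] = 1.0
            else:
                p[1:] = np.exp(-np.abs(L[1:] - comp.location) / comp.scale)
        elif comp.label == "hmw":
            sigma = comp.scale if comp.scale > 0 else 1e-12
            mu = np.log(comp.location)
            logL = np.log(L[1:])
            p[1:] = np.exp(-0.5 * ((logL - mu) / sigma) ** 2) / L[1:]
        elif comp.label == "subnuc":
            lo = self.subnuc_min
            hi = min(int(round(comp.location)), self.max_len)
            if hi <= lo:
                raise SpecificationError("subnuc component upper edge must exceed subnuc_min")
            x = np.arange(lo, hi + 1, dtype=float)
            tau = comp.scale if comp.scale > 0 else 45.0
            base = np.exp((x - hi) / tau)
            period = self.sawtooth_period
            ramp = np.mod(x - self.sawtooth_phase, period) / max(period - 1.0, 1.0)
            p[lo : hi + 1] = base * (1.0 + self.sawtooth_amplitude * ramp)
        total = p.sum()
        if total <= 0:
            raise SpecificationError(f"component {comp.label} has empty support")
        return p / total

    def pmf(self) -> np.ndarray:
        """Mixture probability mass over lengths 0..max_len."""
        p = np.zeros(self.max_len + 1)
        for comp in self.components:
            if comp.weight > 0:
                p += comp.weight * self.component_pmf(comp)
        return p

    def mean_length(self, comp: Component) -> float:
        pmf = self.component_pmf(comp)
        return float(pmf @ np.arange(self.max_len + 1))

    def reweighted(self, weights: dict[str, float]) -> "PopulationSpec":
        """Return a copy with component weights replaced (normalized by label)."""
        comps = tuple(
            replace(c, weight=weights.get(c.label, c.weight)) for c in self.components
        )
        total = sum(c.weight for c in comps)
        if total <= 0:
            raise SpecificationError("reweighted spec has zero total weight")
        comps = tuple(replace(c, weight=c.weight / total) for c in comps)
        return replace(self, components=comps)


def sample_fragment_lengths(
    spec: PopulationSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` integer fragment lengths (bp) from a population mixture.

    Sampling is exact over the discretized per-component mass functions,
    so results are bit-reproducible given ``(spec, seed)``.
    """
    if n <= 0:
        raise SpecificationError(f"n must be > 0, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(n, spec.weights)
    out = np.empty(n, dtype=np.int64)
    pos = 0
    lengths_axis = np.arange(spec.max_len + 1)
    for comp, k in zip(spec.components, counts):
        if k == 0:
            continue
        pmf = spec.component_pmf(comp)
        cdf = np.cumsum(pmf)
        cdf[-1] = 1.0
        u = rng.random(k)
        out[pos : pos + k] = lengths_axis[np.searchsorted(cdf, u, side="right")]
        pos += k
    return out[rng.permutation(n)]


def _mix(components: list[tuple[str, float, float, float]], **kw) -> PopulationSpec:
    comps = tuple(Component(label, w, loc, sc) for label, w, loc, sc in components)
    return PopulationSpec(components=comps, **kw)


def healthy_population() -> PopulationSpec:
    """Default healthy-plasma cirDNA profile: mononucleosome-dominated.

    Mono-N mode at 167 bp with a faint sub-nucleosomal ladder, di-N near
    350 bp, tri-N near 560 bp and a small HMW tail.
    """
    return _mix(
        [
            ("subnuc", 0.03, 166, 45),
            ("monoN", 0.68, 167, 8),
            ("diN", 0.22, 350, 20),
            ("triN", 0.05, 560, 25),
            ("hmw", 0.02, 12_000, 0.6),
        ]
    )


def late_degradation_population() -> PopulationSpec:
    """Profile after prolonged serum incubation.

    Short fragments below the 167 bp mode accumulate (down to ~41 bp)
    with ~10 bp periodic subpeaks from nuclease nicking on the
    nucleosome surface; oligonucleosomal populations are depleted.
    """
    return _mix(
        [
            ("subnuc", 0.40, 166, 45),
            ("monoN", 0.52, 167, 8),
            ("diN", 0.06, 330, 20),
            ("triN", 0.01, 560, 25),
            ("hmw", 0.01, 5_000, 0.6),
        ],
        sawtooth_amplitude=3.0,
    )


def net_supernatant_population() -> PopulationSpec:
    """NET-rich supernatant of PMA-activated neutrophils (5 h).

    Nucleosomal ladder (mono/di/tri roughly 65/22/9 of the 20-1000 bp
    fragment counts, di-N mode at 365 bp, tri-N at 560 bp) riding on an
    HMW chromatin-fiber tail with mean size near 8.6 kb.
    """
    return _mix(
        [
            ("subnuc", 0.02, 166, 45),
            ("monoN", 0.562, 167, 8),
            ("diN", 0.197, 365, 20),
            ("triN", 0.081, 560, 25),
            ("hmw", 0.14, 7_200, 0.6),
        ]
    )


def ghmw_population() -> PopulationSpec:
    """Genomic HMW chromatin from cell lysate: 2-40 kb, peaking ~12 kb."""
    return _mix(
        [
            ("subnuc", 0.02, 166, 45),
            ("monoN", 0.02, 167, 8),
            ("diN", 0.01, 350, 20),
            ("triN", 0.01, 560, 25),
            ("hmw", 0.94, 12_000, 0.6),
        ]
    )
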