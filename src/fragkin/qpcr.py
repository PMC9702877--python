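"""Absolute qPCR quantification and DNA integrity indices.

Concentration is read off a serial-dilution standard curve
``Cq = intercept + slope * log10(concentration)``; amplification
efficiency follows from the slope as ``10^(-1/slope) - 1`` (a perfect
doubling per cycle gives slope -3.3219 and efficiency 1). Paired
short/long amplicons at the same locus (e.g. 73/246 bp on SRY,
67/320 bp on KRAS) give the DNA integrity index, DII = long-amplicon
concentration / short-amplicon concentration: long amplicons cannot sit
inside mononucleosomal fragments, so the DII falls as DNA degrades
toward mononucleosomes. The mitochondrial/nuclear ratio (MNR) compares
mitochondrial and nuclear cfDNA concentrations.

The fragment-length-aware amplifiability model used by the simulator is
also defined here: under a locus-centric view, a fragment of length L
covering a random genomic position is sampled with length-biased weight
L and still contains an intact A bp amplicon with probability
``max(0, (L - A + 1) / L)``, so the amplifiable fraction of a
population is ``sum_i w_i max(0, L_i - A + 1) / sum_i w_i L_i``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from fragkin.errors import AnalysisError, SpecificationError

__all__ = [
    "AmpliconAssay",
    "StandardCurve",
    "Volumes",
    "QuantResult",
    "SRY_ASSAY",
    "KRAS_ASSAY",
    "MT_ASSAY",
    "GENOME_MASS_PG",
    "fit_standard_curve",
    "quantify",
    "dii",
    "mnr",
    "amplifiable_fraction",
    "aggregate_cq",
    "read_cq_table",
]

#: haploid human genome mass in pg, for ng <-> genome-copy conversion
GENOME_MASS_PG = 3.3


@dataclass(frozen=True)
class AmpliconAssay:
    """A paired short/long amplicon qPCR design at one locus."""

    target: str
    short_len: int
    long_len: int
    compartment: str = "nuclear"

    def __post_init__(self) -> None:
        if not 0 < self.short_len < self.long_len:
            raise SpecificationError("need 0 < short_len < long_len")
        if self.compartment not in ("nuclear", "mitochondrial"):
            raise SpecificationError("compartment must be nuclear or mitochondrial")


# the chrY design quantifies male (NET-derived) DNA in female fluid
SRY_ASSAY = AmpliconAssay("SRY", 73, 246, "nuclear")
KRAS_ASSAY = AmpliconAssay("KRAS", 67, 320, "nuclear")
# mitochondrial design: long amplicon threshold >310 bp; the short length
# mirrors the nuclear short design (not printed in the assay table)
MT_ASSAY = AmpliconAssay("mt", 67, 311, "mitochondrial")


@dataclass(frozen=True)
class StandardCurve:
    """Cq-to-concentration calibration from serial dilutions.

    ``units`` documents the concentration scale the curve was fitted
    on: ``"ng_per_reaction"`` (template mass per reaction) or
    ``"ng_per_ul"`` (extract concentration).
    """

    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    units: str = "ng_per_reaction"

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise SpecificationError("standard-curve slope must be negative")
        if not 0.0 < self.efficiency <= 1.1:
            raise SpecificationError(
                f"implausible amplification efficiency {self.efficiency:.3f}"
            )

    def cq_of(self, concentration: float) -> float:
        if concentration <= 0:
            return math.nan
        return self.intercept + self.slope * math.log10(concentration)

    def concentration_of(self, cq: float) -> float:
        return 10.0 ** ((cq - self.intercept) / self.slope)


@dataclass(frozen=True)
class Volumes:
    """Extraction geometry linking extract and source-fluid concentrations."""

    fluid_ml: float = 0.5
    elution_ul: float = 80.0
    reaction_input_ul: float = 5.0

    def __post_init__(self) -> None:
        if min(self.fluid_ml, self.elution_ul, self.reaction_input_ul) <= 0:
            raise SpecificationError("all volumes must be positive")


@dataclass
class QuantResult:
    """Short/long amplicon concentrations (ng/mL fluid) and their DII."""

    conc_short: float
    conc_long: float
    dii: float  # NaN when undefined (conc_short == 0)
    volumes: Volumes


def fit_standard_curve(
    concentrations, cqs, units: str = "ng_per_reaction"
) -> StandardCurve:
    """Least-squares standard curve from serial-dilution observations.

    Requires at least 3 dilution points spanning at least 2 orders of
    magnitude. A non-monotone Cq-vs-dilution pattern raises a warning
    (pipetting or inhibition problem) but still fits.
    """
    conc = np.asarray(concentrations, dtype=float)
    cq = np.asarray(cqs, dtype=float)
    if conc.shape != cq.shape:
        raise SpecificationError("concentrations and cqs must have equal length")
    if conc.size < 3:
        raise SpecificationError("standard curve needs at least 3 dilution points")
    if (conc <= 0).any():
        raise SpecificationError("standard concentrations must be positive")
    logc = np.log10(conc)
    if logc.max() - logc.min() < 2.0:
        raise SpecificationError("dilution series must span at least 2 logs")
    order = np.argsort(logc)
    if np.any(np.diff(cq[order]) > 0):
        warnings.warn("Cq does not decrease monotonically with concentration", stacklevel=2)
    res = stats.linregress(logc, cq)
    efficiency = 10.0 ** (-1.0 / res.slope) - 1.0
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(efficiency),
        r_squared=float(res.rvalue**2),
        units=units,
    )


def quantify(
    cq: float, curve: StandardCurve, volumes: Volumes = Volumes()
) -> float:
    """Concentration in ng/mL of source fluid from a Cq value.

    The curve gives the per-reaction (or extract) quantity; rescaling by
    the extraction geometry (0.5 mL fluid -> 80 uL eluate by default,
    5 uL extract per reaction) converts to ng per mL of the original
    fluid. A "not detected" sentinel (NaN Cq) maps to concentration 0.
    """
    if cq is None or math.isnan(cq):
        return 0.0
    q = curve.concentration_of(cq)
    if curve.units == "ng_per_reaction":
        extract_ng_per_ul = q / volumes.reaction_input_ul
    elif curve.units == "ng_per_ul":
        extract_ng_per_ul = q
    else:
        raise SpecificationError(f"unknown curve units {curve.units!r}")
    return extract_ng_per_ul * volumes.elution_ul / volumes.fluid_ml


def dii(conc_long: float, conc_short: float) -> float:
    """DNA integrity index: long- over short-amplicon concentration.

    Undefined (NaN, with a warning) when the short-amplicon
    concentration is zero — a missing denominator is not integrity 0.
    """
    if conc_long < 0 or conc_short < 0:
        raise SpecificationError("concentrations must be non-negative")
    if conc_short == 0:
        warnings.warn("DII undefined: short-amplicon concentration is zero", stacklevel=2)
        return math.nan
    return conc_long / conc_short


def mnr(conc_mt: float, conc_n: float) -> float:
    """Mitochondrial-to-nuclear cfDNA concentration ratio."""
    if conc_mt < 0 or conc_n < 0:
        raise SpecificationError("concentrations must be non-negative")
    if conc_n == 0:
        warnings.warn("MNR undefined: nuclear concentration is zero", stacklevel=2)
        return math.nan
    return conc_mt / conc_n


def _population_weights(population) -> tuple[np.ndarray, np.ndarray]:
    """(lengths, weights) from a PopulationSpec, FragmentProfile or lengths."""
    # late imports keep qpcr importable without the other modules
    from fragkin.fragmentomics import FragmentProfile
    from fragkin.synthetic.populations import PopulationSpec

    if isinstance(population, PopulationSpec):
        pmf = population.pmf()
        lengths = np.arange(pmf.size, dtype=float)
        return lengths, pmf
    if isinstance(population, FragmentProfile):
        return population.lengths.astype(float), population.counts.astype(float)
    arr = np.asarray(population, dtype=float)
    if arr.size == 0:
        raise AnalysisError("empty fragment population")
    return arr, np.ones_like(arr)


def amplifiable_fraction(population, amplicon_len: int) -> float:
    """Fraction of template copies a given amplicon can amplify.

    ``sum_i w_i max(0, L_i - A + 1) / sum_i w_i L_i`` over the fragment
    population — equal to 1 at A = 1 and non-increasing in A; fragments
    shorter than the amplicon contribute nothing.
    """
    if amplicon_len < 1:
        raise SpecificationError("amplicon length must be >= 1")
    lengths, weights = _population_weights(population)
    denom = float(weights @ lengths)
    if denom <= 0:
        raise AnalysisError("population has zero total length mass")
    intact = np.maximum(0.0, lengths - amplicon_len + 1)
    return float(weights @ intact) / denom


def aggregate_cq(replicates, outlier_delta: float = 1.0) -> float:
    """Aggregate replicate Cq values: mean after outlier removal.

    Replicates further than ``outlier_delta`` cycles from the replicate
    median are dropped before averaging; an all-NaN set stays NaN.
    """
    arr = np.asarray(replicates, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return math.nan
    med = float(np.median(arr))
    kept = arr[np.abs(arr - med) <= outlier_delta]
    return float(kept.mean())


def read_cq_table(path) -> pd.DataFrame:
    """Read a replicate-level Cq table (sample, target, amplicon, replicate, Cq)."""
    df = pd.read_csv(path)
    required = {"sample", "target", "amplicon", "replicate", "Cq"}
    missing = required - set(df.columns)
    if missing:
        raise SpecificationError(f"Cq table missing columns: {sorted(missing)}")
    return df
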