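"""Forward qPCR model: fragment populations to Cq values.

For each amplicon the expected amplifiable concentration is the total
DNA concentration times the population's amplifiable fraction (see
:func:`fragkin.qpcr.amplifiable_fraction`); the Cq follows by
inverting the standard curve through the extraction geometry, plus
homoscedastic Gaussian cycle noise (default SD 0.15 cycles, typical
replicate scatter). A population with no fragment long enough for the
amplicon yields the "not detected" sentinel (NaN Cq).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from fragkin.errors import SpecificationError
from fragkin.qpcr import AmpliconAssay, StandardCurve, Volumes, amplifiable_fraction

__all__ = ["QPCRReadout", "simulate_qpcr", "reference_curve"]


@dataclass(frozen=True)
class QPCRReadout:
    """Simulated Cq pair for a short/long amplicon design (NaN = not detected)."""

    cq_short: float
    cq_long: float
    assay: AmpliconAssay

    @property
    def short_detected(self) -> bool:
        return not math.isnan(self.cq_short)

    @property
    def long_detected(self) -> bool:
        return not math.isnan(self.cq_long)


def reference_curve() -> StandardCurve:
    """A perfect-efficiency calibration on placental genomic DNA dilutions.

    Slope -log2(10) cycles per decade (doubling each cycle), Cq 21 at
    1 ng of template per reaction.
    """
    return StandardCurve(
        slope=-math.log2(10.0),
        intercept=21.0,
        efficiency=1.0,
        r_squared=1.0,
        units="ng_per_reaction",
    )


def simulate_qpcr(
    population,
    concentration: float,
    assay: AmpliconAssay,
    curve: StandardCurve | None = None,
    noise_sd: float = 0.15,
    seed: int | np.random.Generator = 0,
    volumes: Volumes = Volumes(),
) -> QPCRReadout:
    """Simulate short- and long-amplicon Cq values for a population.

    Parameters
    ----------
    population
        Fragment-length population (PopulationSpec, FragmentProfile or
        array of lengths).
    concentration
        Total DNA concentration in ng/mL of source fluid.
    """
    if concentration < 0:
        raise SpecificationError("concentration must be >= 0")
    if noise_sd < 0:
        raise SpecificationError("noise_sd must be >= 0")
    if curve is None:
        curve = reference_curve()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    cqs = []
    for amp_len in (assay.short_len, assay.long_len):
        frac = amplifiable_fraction(population, amp_len)
        conc_fluid = concentration * frac
        # fluid -> extract -> per-reaction template quantity
        extract_ng_per_ul = conc_fluid * volumes.fluid_ml / volumes.elution_ul
        if curve.units == "ng_per_reaction":
            q = extract_ng_per_ul * volumes.reaction_input_ul
        else:
            q = extract_ng_per_ul
        if q <= 0:
            cqs.append(math.nan)
            continue
        cq = curve.cq_of(q)
        if noise_sd > 0:
            cq += float(rng.normal(0.0, noise_sd))
        cqs.append(cq)
    return QPCRReadout(cq_short=cqs[0], cq_long=cqs[1], assay=assay)
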