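"""Blend composition arithmetic, capsule fill mass, drug content, uniformity.

Covers the bookkeeping between a powder blend recipe and the dose a capsule
must deliver: component mass fractions, fill mass from a target drug dose,
spectrophotometric concentration with LOD/LOQ gating, and content-uniformity
assessment against pharmacopeial and industry limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "BlendComposition",
    "CalibrationLine",
    "UniformityReport",
    "QUANTIFIABLE",
    "BELOW_LOQ",
    "BELOW_LOD",
    "mass_fractions",
    "fill_mass",
    "absorbance_to_conc",
    "assess_uniformity",
]

QUANTIFIABLE = "quantifiable"
BELOW_LOQ = "detected-below-LOQ"
BELOW_LOD = "below-LOD"


@dataclass(frozen=True)
class BlendComposition:
    """A powder blend: (component, mass in g) pairs plus which one is the drug."""

    components: tuple[tuple[str, float], ...]
    drug_component: str

    def __post_init__(self):
        if not self.components:
            raise InputError("a blend needs at least one component")
        names = [n for n, _ in self.components]
        if len(set(names)) != len(names):
            raise InputError("duplicate component names in blend")
        for name, mass in self.components:
            if mass <= 0:
                raise InputError(f"component '{name}' has non-positive mass {mass}")
        if self.drug_component not in names:
            raise InputError(f"drug component '{self.drug_component}' not in blend")

    @property
    def total_mass(self) -> float:
        return sum(m for _, m in self.components)

    @property
    def drug_fraction(self) -> float:
        drug = dict(self.components)[self.drug_component]
        return drug / self.total_mass


@dataclass(frozen=True)
class CalibrationLine:
    """Zero-intercept UV calibration: absorbance = slope * concentration."""

    slope: float          # mL/ug
    lod: float            # ug/mL
    loq: float            # ug/mL
    wavelength_nm: float

    def __post_init__(self):
        if self.slope <= 0:
            raise InputError("calibration slope must be > 0")
        if not self.lod < self.loq:
            raise InputError("LOD must be below LOQ")


@dataclass(frozen=True)
class UniformityReport:
    contents_pct: tuple[float, ...]
    mean_pct: float
    rsd_pct: float
    pass_pharmacopeia: bool  # every unit in 85-115% and RSD <= 6%
    pass_industry: bool      # every unit in 90-110%


def mass_fractions(blend: BlendComposition) -> dict[str, float]:
    """Mass fraction per component; fractions sum to 1."""
    total = blend.total_mass
    return {name: mass / total for name, mass in blend.components}


def fill_mass(dose_mg: float, drug_fraction: float) -> float:
    """Capsule fill mass (mg) that delivers ``dose_mg`` of drug."""
    if not 0 < drug_fraction <= 1:
        raise InputError("drug fraction must be in (0, 1]")
    if dose_mg <= 0:
        raise InputError("dose must be > 0")
    return dose_mg / drug_fraction


def absorbance_to_conc(a: float, cal: CalibrationLine) -> tuple[float, str]:
    """Concentration (ug/mL) and its quantifiability qualifier."""
    if a < 0:
        raise InputError("absorbance must be >= 0")
    c = a / cal.slope
    if c < cal.lod:
        qualifier = BELOW_LOD
    elif c < cal.loq:
        qualifier = BELOW_LOQ
    else:
        qualifier = QUANTIFIABLE
    return c, qualifier


def assess_uniformity(
    contents_pct: Sequence[float],
    pharmacopeia_limits: tuple[float, float] = (85.0, 115.0),
    pharmacopeia_rsd_max: float = 6.0,
    industry_limits: tuple[float, float] = (90.0, 110.0),
) -> UniformityReport:
    """Assess content uniformity of dosage units given as % of label claim.

    Sample (n-1) standard deviation is used for the RSD, per convention for
    10 dosage units.
    """
    values = np.asarray(contents_pct, dtype=float)
    if values.size < 2:
        raise InputError("at least 2 content values are required")
    if np.any(values < 0):
        raise InputError("contents must be >= 0")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    rsd = math.inf if mean == 0 else 100.0 * sd / mean
    lo, hi = pharmacopeia_limits
    pass_pharm = bool(np.all((values >= lo) & (values <= hi)) and rsd <= pharmacopeia_rsd_max)
    lo_i, hi_i = industry_limits
    pass_ind = bool(np.all((values >= lo_i) & (values <= hi_i)))
    return UniformityReport(
        contents_pct=tuple(float(v) for v in values),
        mean_pct=mean,
        rsd_pct=rsd,
        pass_pharmacopeia=pass_pharm,
        pass_industry=pass_ind,
    )
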