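"""Cascade-impactor data reduction: EF, FPF, MMAD and GSD.

An impactor run is the drug mass recovered from each sampling location
(device, capsule, induction port, mouthpiece, stages, back-up filter) at a
stated flow rate.  Reduction follows the classical log-probit route: the
cumulative percentage of sized mass below each stage's effective cut-off
diameter (ECD) is regressed as probit(cum/100) on ln(ECD); the mass median
aerodynamic diameter and geometric standard deviation come off that line,
and the fine-particle fractions are evaluated from it (or by piecewise
interpolation) and rescaled to the chosen denominator.

Units: masses in ug, diameters in um, flow in L/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDistributionError, InputError

__all__ = [
    "ACI_CUTOFFS_28_3_LPM",
    "ImpactorRun",
    "APSDResult",
    "emitted_fraction",
    "cumulative_undersize",
    "fit_log_probit",
    "fine_particle_fractions",
    "reduce_run",
    "runs_from_table",
]

#: Andersen Cascade Impactor effective cut-off diameters (um), stages 0-7,
#: at the 28.3 L/min calibration flow.  Held here as documented constants.
ACI_CUTOFFS_28_3_LPM: tuple[float, ...] = (9.0, 5.8, 4.7, 3.3, 2.1, 1.1, 0.7, 0.4)

FpfBasis = Literal["emitted", "recovered", "sized"]
FpfMethod = Literal["fit", "interp"]


@dataclass(frozen=True)
class ImpactorRun:
    """Drug mass per sampling location for one impactor run."""

    flow_rate_lpm: float
    device_mass: float
    capsule_mass: float
    induction_port_mass: float
    mouthpiece_mass: float
    stage_masses: tuple[float, ...]
    filter_mass: float
    stage_ecd_um: tuple[float, ...] = ACI_CUTOFFS_28_3_LPM
    run_id: str = ""

    def __post_init__(self):
        if self.flow_rate_lpm <= 0:
            raise InputError("flow rate must be > 0")
        masses = (
            self.device_mass,
            self.capsule_mass,
            self.induction_port_mass,
            self.mouthpiece_mass,
            self.filter_mass,
            *self.stage_masses,
        )
        if any(m < 0 for m in masses):
            raise InputError("masses must be >= 0")
        if len(self.stage_masses) != len(self.stage_ecd_um):
            raise InputError("one cut-off diameter per stage is required")
        ecd = self.stage_ecd_um
        if any(ecd[i] <= ecd[i + 1] for i in range(len(ecd) - 1)):
            raise InputError("stage cut-offs must be strictly decreasing")

    @property
    def total_recovered(self) -> float:
        return (
            self.device_mass
            + self.capsule_mass
            + self.induction_port_mass
            + self.mouthpiece_mass
            + sum(self.stage_masses)
            + self.filter_mass
        )

    @property
    def emitted_mass(self) -> float:
        """Everything that left the device and capsule."""
        return self.total_recovered - self.device_mass - self.capsule_mass

    @property
    def sized_mass(self) -> float:
        """Mass on the size-classifying locations: stages plus filter."""
        return sum(self.stage_masses) + self.filter_mass


@dataclass(frozen=True)
class APSDResult:
    """Reduced aerodynamic metrics of one run."""

    ef_pct: float
    fpf5_pct: float
    fpf3_pct: float
    mmad_um: float
    gsd: float
    r_squared: float
    fpf_basis: str = "emitted"


def emitted_fraction(run: ImpactorRun) -> float:
    """Percent of recovered drug found outside the device and capsule."""
    total = run.total_recovered
    if total <= 0:
        raise InputError("total recovered mass is zero")
    return 100.0 * run.emitted_mass / total


def cumulative_undersize(run: ImpactorRun) -> list[tuple[float, float]]:
    """(ECD, cumulative % of sized mass below that ECD), ascending in ECD.

    The mass below a stage's cut-off is everything collected on stages with
    smaller cut-offs plus the back-up filter.
    """
    sized = run.sized_mass
    if sized <= 0:
        raise InputError("sized mass (stages + filter) is zero")
    points = []
    for i, ecd in enumerate(run.stage_ecd_um):
        below = sum(run.stage_masses[i + 1 :]) + run.filter_mass
        points.append((ecd, 100.0 * below / sized))
    return sorted(points)


def fit_log_probit(
    cum: Sequence[tuple[float, float]],
) -> tuple[float, float, float]:
    """OLS of probit(cum/100) on ln(ECD) -> (mmad_um, gsd, r_squared).

    Points at exactly 0% or 100% (probit infinite) are excluded.  The line
    probit = slope*ln(d) + intercept gives MMAD = exp(-intercept/slope) and
    GSD = exp(1/slope).
    """
    usable = [(d, c) for d, c in cum if 0.0 < c < 100.0 and d > 0]
    if len(usable) < 2:
        raise DegenerateDistributionError(
            "need at least 2 cumulative points strictly between 0% and 100%"
        )
    x = np.log([d for d, _ in usable])
    y = stats.norm.ppf([c / 100.0 for _, c in usable])
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise DegenerateDistributionError("non-increasing cumulative undersize")
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    mmad = math.exp(-intercept / slope)
    gsd = math.exp(1.0 / slope)
    return mmad, gsd, r_squared


def _basis_mass(run: ImpactorRun, basis: FpfBasis) -> float:
    if basis == "emitted":
        return run.emitted_mass
    if basis == "recovered":
        return run.total_recovered
    if basis == "sized":
        return run.sized_mass
    raise InputError(f"unknown FPF basis '{basis}'")


def _undersize_at(
    d_um: float,
    fit: tuple[float, float, float] | None,
    cum: Sequence[tuple[float, float]],
    method: FpfMethod,
) -> float:
    """Fraction (0-1) of sized mass below ``d_um``."""
    if method == "fit":
        if fit is None:
            raise InputError("a log-probit fit is required for method='fit'")
        mmad, gsd, _ = fit
        if gsd <= 1.0:
            return float(d_um > mmad) if d_um != mmad else 0.5
        return float(stats.norm.cdf(math.log(d_um / mmad) / math.log(gsd)))
    if method == "interp":
        pts = sorted(cum)
        eps = 1e-3
        x = np.log([d for d, _ in pts])
        y = stats.norm.ppf([min(max(c, eps), 100.0 - eps) / 100.0 for _, c in pts])
        probit = float(np.interp(math.log(d_um), x, y))
        return float(stats.norm.cdf(probit))
    raise InputError(f"unknown FPF method '{method}'")


def fine_particle_fractions(
    run: ImpactorRun,
    fit: tuple[float, float, float] | None = None,
    cum: Sequence[tuple[float, float]] | None = None,
    basis: FpfBasis = "emitted",
    method: FpfMethod = "fit",
    cutoffs_um: tuple[float, float] = (5.0, 3.0),
) -> tuple[float, float]:
    """FPF below 5 um and below 3 um, % of the chosen basis mass.

    The undersize fraction of the sized mass (from the fitted line, or by
    piecewise-linear interpolation in probit-log space) is rescaled by
    sized mass / basis mass.
    """
    if cum is None:
        cum = cumulative_undersize(run)
    base = _basis_mass(run, basis)
    if base <= 0:
        raise InputError(f"basis mass '{basis}' is zero")
    scale = 100.0 * run.sized_mass / base
    fpf5 = _undersize_at(cutoffs_um[0], fit, cum, method) * scale
    fpf3 = _undersize_at(cutoffs_um[1], fit, cum, method) * scale
    return fpf5, fpf3


def reduce_run(
    run: ImpactorRun,
    basis: FpfBasis = "emitted",
    method: FpfMethod = "fit",
) -> APSDResult:
    """Full reduction of one run to EF, FPF<5, FPF<3, MMAD, GSD, R^2."""
    cum = cumulative_undersize(run)
    fit = fit_log_probit(cum)
    fpf5, fpf3 = fine_particle_fractions(run, fit=fit, cum=cum, basis=basis, method=method)
    return APSDResult(
        ef_pct=emitted_fraction(run),
        fpf5_pct=fpf5,
        fpf3_pct=fpf3,
        mmad_um=fit[0],
        gsd=fit[1],
        r_squared=fit[2],
        fpf_basis=basis,
    )


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------

_LOCATIONS = ("device", "capsule", "induction_port", "mouthpiece", "filter")


def runs_from_table(
    table: pd.DataFrame,
    flow_rate_lpm: float = 28.3,
    stage_ecd_um: tuple[float, ...] = ACI_CUTOFFS_28_3_LPM,
) -> list[ImpactorRun]:
    """Parse long-format (run_id, location, mass_ug) rows into runs.

    Locations: device, capsule, induction_port, mouthpiece, stage0..stageN,
    filter.  Missing locations default to zero mass.
    """
    required = {"run_id", "location", "mass_ug"}
    if not required.issubset(table.columns):
        raise InputError(f"run table must have columns {sorted(required)}")
    runs = []
    for run_id, grp in table.groupby("run_id", sort=False):
        masses = dict(zip(grp["location"], grp["mass_ug"].astype(float)))
        known = set(_LOCATIONS) | {f"stage{i}" for i in range(len(stage_ecd_um))}
        unknown = set(masses) - known
        if unknown:
            raise InputError(f"run '{run_id}': unknown locations {sorted(unknown)}")
        stages = tuple(masses.get(f"stage{i}", 0.0) for i in range(len(stage_ecd_um)))
        runs.append(
            ImpactorRun(
                flow_rate_lpm=flow_rate_lpm,
                device_mass=masses.get("device", 0.0),
                capsule_mass=masses.get("capsule", 0.0),
                induction_port_mass=masses.get("induction_port", 0.0),
                mouthpiece_mass=masses.get("mouthpiece", 0.0),
                stage_masses=stages,
                filter_mass=masses.get("filter", 0.0),
                stage_ecd_um=tuple(stage_ecd_um),
                run_id=str(run_id),
            )
        )
    return runs
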