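"""Surface free energy from two-liquid contact angles and pair-interaction metrics.

The dispersive/polar decomposition of a solid's surface free energy is
recovered from contact angles measured with two probe liquids via the
harmonic-mean (Wu) system

    (1 + cos th) * gl = 4 * [ gsd*gld/(gsd+gld) + gsp*glp/(gsp+glp) ]

one equation per probe liquid, two unknowns (gsd, gsp).  From the solved
components the module derives the work of cohesion (2*gs), the harmonic-mean
work of adhesion of a pair, the Derjaguin sphere-sphere adhesion force, and
the spreading coefficient of one material over another.

Unit contract: energies and works in mN/m, particle diameters in um,
forces in mN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DegenerateInputError, InputError, NonPhysicalAngleError

__all__ = [
    "ProbeLiquid",
    "ContactAngleSet",
    "SurfaceEnergy",
    "InteractionPair",
    "WATER",
    "DIIODOMETHANE",
    "DEFAULT_LIQUIDS",
    "solve_wu",
    "forward_contact_angle",
    "wu_residual",
    "cohesion_work",
    "work_of_adhesion",
    "adhesion_force",
    "spreading_coefficient",
    "solve_table",
    "interaction_table",
]

#: Back-substitution tolerance for a solved component pair, mN/m.
RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class ProbeLiquid:
    """A probe liquid with known surface-tension components (mN/m)."""

    name: str
    gamma_d: float
    gamma_p: float
    gamma_total: float | None = None

    def __post_init__(self):
        if self.gamma_d <= 0:
            raise InputError(f"{self.name}: dispersive surface tension must be > 0")
        if self.gamma_p < 0:
            raise InputError(f"{self.name}: polar surface tension must be >= 0")
        total = self.gamma_d + self.gamma_p
        if self.gamma_total is None:
            object.__setattr__(self, "gamma_total", total)
        elif abs(self.gamma_total - total) > 1e-9:
            raise InputError(
                f"{self.name}: gamma_total {self.gamma_total} != gamma_d + gamma_p {total}"
            )


#: Default probe-liquid constants (mN/m); overridable wherever liquids are accepted.
WATER = ProbeLiquid("water", gamma_d=22.6, gamma_p=50.2)
DIIODOMETHANE = ProbeLiquid("diiodomethane", gamma_d=49.0, gamma_p=1.8)
DEFAULT_LIQUIDS: tuple[ProbeLiquid, ProbeLiquid] = (WATER, DIIODOMETHANE)


@dataclass(frozen=True)
class ContactAngleSet:
    """Measured contact angles of one material, keyed by probe-liquid name."""

    material: str
    theta_by_liquid: Mapping[str, float]

    def __post_init__(self):
        for liquid, theta in self.theta_by_liquid.items():
            if not 0.0 <= theta < 180.0:
                raise InputError(
                    f"{self.material}/{liquid}: contact angle {theta} outside [0, 180)"
                )


@dataclass(frozen=True)
class SurfaceEnergy:
    """Solved surface-energy components of one material (mN/m)."""

    material: str
    gamma_sd: float
    gamma_sp: float

    def __post_init__(self):
        if self.gamma_sd <= 0:
            raise InputError(f"{self.material}: dispersive component must be > 0")
        if self.gamma_sp < 0:
            raise InputError(f"{self.material}: polar component must be >= 0")

    @property
    def gamma_s(self) -> float:
        return self.gamma_sd + self.gamma_sp

    @property
    def polarity_pct(self) -> float:
        return 100.0 * self.gamma_sp / self.gamma_s

    @property
    def cohesion_work(self) -> float:
        return 2.0 * self.gamma_s


def _harmonic_term(a: float, b: float) -> float:
    # 0/0 for a pair of zero polar components is a vanishing interaction
    return 0.0 if a + b == 0 else a * b / (a + b)


def _wu_rhs(gsd: float, gsp: float, liquid: ProbeLiquid) -> float:
    return 4.0 * (
        _harmonic_term(gsd, liquid.gamma_d) + _harmonic_term(gsp, liquid.gamma_p)
    )


def wu_residual(energy: SurfaceEnergy, liquid: ProbeLiquid, theta_deg: float) -> float:
    """Signed residual of the harmonic-mean equation for one liquid, mN/m."""
    lhs = (1.0 + math.cos(math.radians(theta_deg))) * liquid.gamma_total
    return _wu_rhs(energy.gamma_sd, energy.gamma_sp, liquid) - lhs


def forward_contact_angle(gamma_sd: float, gamma_sp: float, liquid: ProbeLiquid) -> float:
    """Contact angle (degrees) implied by known components for one probe liquid.

    Raises NonPhysicalAngleError when the components imply complete wetting
    (no finite angle solves the equation).
    """
    cos_theta = _wu_rhs(gamma_sd, gamma_sp, liquid) / liquid.gamma_total - 1.0
    if not -1.0 <= cos_theta <= 1.0:
        raise NonPhysicalAngleError(
            f"components ({gamma_sd}, {gamma_sp}) admit no contact angle on {liquid.name}"
        )
    return math.degrees(math.acos(cos_theta))


def _owens_wendt_guess(
    targets: np.ndarray, liquids: Sequence[ProbeLiquid]
) -> np.ndarray:
    """Geometric-mean closed-form initial guess for the Newton iteration.

    Solves 2(sqrt(gsd*gld) + sqrt(gsp*glp)) = target as a linear system in
    (sqrt(gsd), sqrt(gsp)).
    """
    a = np.array([[math.sqrt(l.gamma_d), math.sqrt(l.gamma_p)] for l in liquids])
    try:
        roots = np.linalg.solve(a, targets / 2.0)
    except np.linalg.LinAlgError:
        roots = np.array([1.0, 1.0])
    return np.maximum(roots, 0.1) ** 2


def _newton(
    x0: np.ndarray, targets: np.ndarray, liquids: Sequence[ProbeLiquid]
) -> np.ndarray | None:
    """Damped 2-D Newton with analytic Jacobian; None when not converged."""
    x = np.maximum(x0, 1e-9)

    def fvec(x):
        return np.array([_wu_rhs(x[0], x[1], l) - t for l, t in zip(liquids, targets)])

    f = fvec(x)
    for _ in range(80):
        if np.max(np.abs(f)) < 1e-11:
            return x
        jac = np.array(
            [
                [
                    4.0 * (l.gamma_d / (x[0] + l.gamma_d)) ** 2,
                    4.0 * (l.gamma_p / (x[1] + l.gamma_p)) ** 2 if l.gamma_p > 0 else 0.0,
                ]
                for l in liquids
            ]
        )
        try:
            step = np.linalg.solve(jac, f)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        for _ in range(40):
            cand = np.maximum(x - lam * step, 1e-12)
            fc = fvec(cand)
            if np.linalg.norm(fc) < np.linalg.norm(f):
                x, f = cand, fc
                break
            lam *= 0.5
        else:
            return None
    return x if np.max(np.abs(fvec(x))) < 1e-11 else None


def _nested_bisection(
    targets: np.ndarray, liquids: Sequence[ProbeLiquid]
) -> np.ndarray:
    """Bounded nested root bracketing on [1e-9, 500] mN/m.

    The right side of each equation is strictly increasing in both unknowns,
    so the inner solve (dispersive component from the more dispersive liquid)
    and the outer solve each bracket at most one root.
    """
    inner = int(np.argmax([l.gamma_d for l in liquids]))
    outer = 1 - inner
    lo, hi = 1e-9, 500.0

    def gsd_of(gsp: float) -> float:
        f = lambda gsd: _wu_rhs(gsd, gsp, liquids[inner]) - targets[inner]
        if f(lo) > 0 or f(hi) < 0:
            raise NonPhysicalAngleError("non-physical angle set: no dispersive root in bounds")
        return brentq(f, lo, hi, xtol=1e-13)

    def g(gsp: float) -> float:
        return _wu_rhs(gsd_of(gsp), gsp, liquids[outer]) - targets[outer]

    if g(lo) > 0 or g(hi) < 0:
        raise NonPhysicalAngleError("non-physical angle set: no polar root in bounds")
    gsp = brentq(g, lo, hi, xtol=1e-13)
    return np.array([gsd_of(gsp), gsp])


def solve_wu(
    angles: ContactAngleSet,
    liquids: Sequence[ProbeLiquid] = DEFAULT_LIQUIDS,
) -> SurfaceEnergy:
    """Invert a two-liquid contact-angle set to surface-energy components.

    Parameters
    ----------
    angles
        Contact angles of one material; must contain an angle for each
        probe liquid by name.
    liquids
        Exactly two probe liquids with distinct (gamma_d, gamma_p) directions.

    Returns
    -------
    SurfaceEnergy with both equation residuals below ``RESIDUAL_TOL``.
    """
    if len(liquids) != 2:
        raise InputError("exactly two probe liquids are required")
    if liquids[0].name == liquids[1].name:
        raise InputError("probe liquids must be distinct")
    det = liquids[0].gamma_d * liquids[1].gamma_p - liquids[1].gamma_d * liquids[0].gamma_p
    if abs(det) < 1e-9:
        raise InputError("probe liquids are colinear in (gamma_d, gamma_p)")
    try:
        thetas = [angles.theta_by_liquid[l.name] for l in liquids]
    except KeyError as exc:
        raise InputError(f"missing contact angle for liquid {exc}") from None

    targets = np.array(
        [
            (1.0 + math.cos(math.radians(theta))) * liquid.gamma_total
            for theta, liquid in zip(thetas, liquids)
        ]
    )
    x = _newton(_owens_wendt_guess(targets, liquids), targets, liquids)
    if x is None:
        x = _nested_bisection(targets, liquids)

    energy = SurfaceEnergy(angles.material, float(x[0]), float(max(x[1], 0.0)))
    for liquid, theta in zip(liquids, thetas):
        if abs(wu_residual(energy, liquid, theta)) > RESIDUAL_TOL:
            raise NonPhysicalAngleError(
                f"{angles.material}: no positive root reproduces the angle on {liquid.name}"
            )
    return energy


def cohesion_work(e: SurfaceEnergy) -> float:
    """Work of cohesion, mN/m: twice the total surface free energy."""
    return 2.0 * e.gamma_s


def work_of_adhesion(e1: SurfaceEnergy, e2: SurfaceEnergy) -> float:
    """Harmonic-mean work of adhesion between two materials, mN/m (symmetric)."""
    if e1.gamma_sd + e2.gamma_sd == 0:
        raise DegenerateInputError("both dispersive components are zero")
    return 4.0 * (
        _harmonic_term(e1.gamma_sd, e2.gamma_sd) + _harmonic_term(e1.gamma_sp, e2.gamma_sp)
    )


def adhesion_force(w_adh: float, d50_1: float, d50_2: float) -> float:
    """Derjaguin sphere-sphere adhesion force, mN.

    ``F = 2 pi (Ra Rb / (Ra + Rb)) W`` with radii D(0.5)/2 converted from um
    to metres; W in mN/m then yields the force directly in mN.
    """
    if d50_1 <= 0 or d50_2 <= 0:
        raise InputError("median diameters must be > 0")
    if w_adh <= 0:
        raise InputError("work of adhesion must be > 0")
    r1 = d50_1 / 2.0 * 1e-6
    r2 = d50_2 / 2.0 * 1e-6
    return 2.0 * math.pi * (r1 * r2 / (r1 + r2)) * w_adh


def spreading_coefficient(e1: SurfaceEnergy, e2: SurfaceEnergy) -> float:
    """Spreading coefficient of material 1 over material 2.

    Work of adhesion of the pair minus the work of cohesion of the spreading
    material (material 1).  Positive values favour film spreading.
    """
    return work_of_adhesion(e1, e2) - cohesion_work(e1)


@dataclass(frozen=True)
class InteractionPair:
    """Pair metrics for a spreading material (1) on a substrate (2).

    ``w_adh`` is always the harmonic-mean value computed from the two
    components.  When a published/externally measured work of adhesion is
    supplied via ``w_adh_override`` the force uses it (so printed force
    tables reproduce exactly) while ``s21`` stays tied to the computed value.
    """

    material_1: SurfaceEnergy
    material_2: SurfaceEnergy
    d50_1: float
    d50_2: float
    w_adh: float
    f_adh: float
    s21: float
    w_adh_override: float | None = None

    @classmethod
    def build(
        cls,
        e1: SurfaceEnergy,
        e2: SurfaceEnergy,
        d50_1: float,
        d50_2: float,
        w_adh_override: float | None = None,
    ) -> "InteractionPair":
        w = work_of_adhesion(e1, e2)
        w_used = w if w_adh_override is None else w_adh_override
        return cls(
            material_1=e1,
            material_2=e2,
            d50_1=d50_1,
            d50_2=d50_2,
            w_adh=w,
            f_adh=adhesion_force(w_used, d50_1, d50_2),
            s21=spreading_coefficient(e1, e2),
            w_adh_override=w_adh_override,
        )


# ---------------------------------------------------------------------------
# table-level drivers (CSV in, report tables out)
# ---------------------------------------------------------------------------

def solve_table(
    angles: pd.DataFrame,
    liquids: Sequence[ProbeLiquid] = DEFAULT_LIQUIDS,
) -> tuple[pd.DataFrame, dict[str, SurfaceEnergy]]:
    """Solve every material of a long-format angle table.

    ``angles`` columns: material, liquid, theta_deg.  Replicates are averaged
    per (material, liquid); their SD is reported alongside.
    """
    required = {"material", "liquid", "theta_deg"}
    if not required.issubset(angles.columns):
        raise InputError(f"angle table must have columns {sorted(required)}")
    rows, energies = [], {}
    for material, grp in angles.groupby("material", sort=False):
        means = grp.groupby("liquid")["theta_deg"].mean()
        sds = grp.groupby("liquid")["theta_deg"].std(ddof=1)
        e = solve_wu(ContactAngleSet(material, means.to_dict()), liquids)
        energies[material] = e
        row = {"material": material}
        for liquid in liquids:
            row[f"theta_{liquid.name}_deg"] = means[liquid.name]
            row[f"theta_{liquid.name}_sd_deg"] = sds.get(liquid.name, float("nan"))
        row.update(
            gamma_sd_mN_m=e.gamma_sd,
            gamma_sp_mN_m=e.gamma_sp,
            gamma_s_mN_m=e.gamma_s,
            polarity_pct=e.polarity_pct,
            cohesion_work_mN_m=e.cohesion_work,
        )
        rows.append(row)
    return pd.DataFrame(rows), energies


def interaction_table(
    pairs: pd.DataFrame,
    energies: Mapping[str, SurfaceEnergy],
    d50_um: Mapping[str, float],
) -> tuple[pd.DataFrame, list[InteractionPair]]:
    """Build the pair-metric table.

    ``pairs`` columns: material_1, material_2, optionally w_adh_override.
    """
    required = {"material_1", "material_2"}
    if not required.issubset(pairs.columns):
        raise InputError(f"pair table must have columns {sorted(required)}")
    rows, built = [], []
    for rec in pairs.to_dict("records"):
        m1, m2 = rec["material_1"], rec["material_2"]
        for m in (m1, m2):
            if m not in energies:
                raise InputError(f"no solved surface energy for material '{m}'")
            if m not in d50_um:
                raise InputError(f"no D(0.5) for material '{m}'")
        override = rec.get("w_adh_override")
        if override is not None and (isinstance(override, float) and math.isnan(override)):
            override = None
        pair = InteractionPair.build(
            energies[m1], energies[m2], d50_um[m1], d50_um[m2], w_adh_override=override
        )
        built.append(pair)
        rows.append(
            {
                "product": f"{m1} + {m2}",
                "w_adh_mN_m": pair.w_adh,
                "w_adh_used_mN_m": override if override is not None else pair.w_adh,
                "f_adh_mN": pair.f_adh,
                "s21": pair.s21,
            }
        )
    return pd.DataFrame(rows), built
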