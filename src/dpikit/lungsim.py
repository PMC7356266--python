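"""Stochastic whole-lung Monte Carlo aerosol deposition with breath-hold.

Particles are sampled mass-weighted from an aerodynamic size distribution,
filtered by an empirical extrathoracic (mouth-throat) capture efficiency,
then walked generation by generation through a 24-generation Weibel-type
airway scaffold whose tube dimensions are lognormally perturbed per particle
(standing in for cast-measurement variability).  In each tube the particle
survives or deposits by a Bernoulli trial on the combined probability of
three analytic tube mechanisms:

* inertial impaction in a bend (Stokes-number form),
* gravitational settling in an inclined tube,
* Brownian diffusion (Gormley-Kennedy laminar-tube form).

Penetration depth is set by the inhaled volume against the cumulative
airway + alveolar volume; the breath-hold applies zero-flow sedimentation
and diffusion in the particle's resting generation; exhalation retraces the
generations at the expiratory flow with the extrathoracic region treated as
pass-through.  Undeposited particles are exhaled.  Because the sample is
mass-weighted, count fractions are mass fractions.

Every random draw comes from one seeded generator in an order that does not
depend on the breathing profile, so runs that differ only in breath-hold
time are pathwise paired (monotonicity in hold time is exact per seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError
from .impactor import fit_log_probit

__all__ = [
    "BreathingProfile",
    "AirwayGeneration",
    "DepositionResult",
    "COPD_PROFILE_BH5",
    "COPD_PROFILE_BH10",
    "build_airway_tree",
    "sample_apsd",
    "sample_apsd_from_cumulative",
    "extrathoracic_efficiency",
    "generation_deposition_prob",
    "simulate",
    "plot_deposition",
]

# --- physical constants (SI) -----------------------------------------------
AIR_VISCOSITY = 1.90e-5          # Pa s at ~310 K
MEAN_FREE_PATH_M = 0.0712e-6     # air mean free path at body conditions
PARTICLE_DENSITY = 1000.0        # kg/m3; aerodynamic-equivalent convention
BOLTZMANN = 1.380649e-23
BODY_TEMP_K = 310.0
GRAVITY = 9.81

# --- model defaults ---------------------------------------------------------
DEFAULT_FRC_ML = 3300.0
ET_VOLUME_ML = 50.0              # mouth-throat dead space ahead of generation 0
DEFAULT_BRANCH_ANGLE_DEG = 35.0
DEFAULT_GEOMETRY_CV = 0.1
N_GENERATIONS = 24
ACINAR_START = 17                # generations 17..23 carry the alveolar volume

#: Empirical mouth-throat capture: eta = x/(1+x), x = a*(d_ae^2 * Q)^b with
#: d_ae in um and Q in L/min (oral-inhalation impaction-parameter fit).
ET_IMPACTION_COEF = 2.78e-4
ET_IMPACTION_EXP = 1.152

#: Weibel-type symmetric morphometry at ~4800 mL lung volume:
#: (length cm, diameter cm) per generation 0..23.
_WEIBEL_A: tuple[tuple[float, float], ...] = (
    (12.0, 1.80), (4.76, 1.22), (1.90, 0.83), (0.76, 0.56),
    (1.27, 0.45), (1.07, 0.35), (0.90, 0.28), (0.76, 0.23),
    (0.64, 0.186), (0.54, 0.154), (0.46, 0.130), (0.39, 0.109),
    (0.33, 0.095), (0.27, 0.082), (0.23, 0.074), (0.20, 0.066),
    (0.165, 0.060), (0.141, 0.054), (0.117, 0.050), (0.099, 0.047),
    (0.083, 0.045), (0.070, 0.043), (0.059, 0.041), (0.050, 0.041),
)
_WEIBEL_VOLUME_ML = 4800.0


@dataclass(frozen=True)
class BreathingProfile:
    """One breathing manoeuvre: inhale, optional hold, exhale."""

    inhaled_volume_l: float
    inhalation_time_s: float
    breath_hold_s: float
    exhalation_time_s: float

    def __post_init__(self):
        if self.inhaled_volume_l <= 0 or self.inhalation_time_s <= 0:
            raise InputError("inhaled volume and inhalation time must be > 0")
        if self.exhalation_time_s <= 0:
            raise InputError("exhalation time must be > 0")
        if self.breath_hold_s < 0:
            raise InputError("breath hold must be >= 0")

    @property
    def mean_inspiratory_flow_lpm(self) -> float:
        return self.inhaled_volume_l / self.inhalation_time_s * 60.0


#: COPD-patient breathing through a capsule DPI: 1.7 L over 3.2 s, 3 s exhale.
COPD_PROFILE_BH5 = BreathingProfile(1.7, 3.2, 5.0, 3.0)
COPD_PROFILE_BH10 = BreathingProfile(1.7, 3.2, 10.0, 3.0)


@dataclass(frozen=True)
class AirwayGeneration:
    """Mean geometry of one dichotomous airway generation."""

    index: int
    mean_length_cm: float
    mean_diameter_cm: float
    branching_angle_deg: float = DEFAULT_BRANCH_ANGLE_DEG
    gravity_angle_deg: float = 45.0

    def __post_init__(self):
        if not 0 <= self.index < N_GENERATIONS:
            raise InputError("generation index must be in 0..23")
        if self.mean_length_cm <= 0 or self.mean_diameter_cm <= 0:
            raise InputError("lengths and diameters must be > 0")

    @property
    def multiplicity(self) -> int:
        return 2 ** self.index


@dataclass(frozen=True)
class DepositionResult:
    """Regional deposition of one simulated manoeuvre, % of emitted mass."""

    et_pct: float
    lung_pct: float
    bronchial_pct: float
    acinar_pct: float
    exh_pct: float
    per_generation_pct: tuple[float, ...]
    n_particles: int
    seed: int | None


def build_airway_tree(
    frc_ml: float = DEFAULT_FRC_ML,
    branching_angle_deg: float = DEFAULT_BRANCH_ANGLE_DEG,
) -> list[AirwayGeneration]:
    """Symmetric 24-generation scaffold scaled isotropically to ``frc_ml``."""
    if frc_ml <= 0:
        raise InputError("functional residual capacity must be > 0")
    scale = (frc_ml / _WEIBEL_VOLUME_ML) ** (1.0 / 3.0)
    return [
        AirwayGeneration(i, length * scale, diameter * scale, branching_angle_deg)
        for i, (length, diameter) in enumerate(_WEIBEL_A)
    ]


# ---------------------------------------------------------------------------
# particle physics (vectorised over particle arrays; SI units internally)
# ---------------------------------------------------------------------------

def _slip_correction(d_m):
    kn = 2.0 * MEAN_FREE_PATH_M / d_m
    return 1.0 + kn * (1.257 + 0.4 * np.exp(-1.1 / kn))


def _settling_velocity(d_m):
    return PARTICLE_DENSITY * GRAVITY * d_m ** 2 * _slip_correction(d_m) / (18.0 * AIR_VISCOSITY)


def _diffusion_coefficient(d_m):
    return BOLTZMANN * BODY_TEMP_K * _slip_correction(d_m) / (3.0 * math.pi * AIR_VISCOSITY * d_m)


def extrathoracic_efficiency(
    d_ae_um,
    flow_lpm: float,
    coef: float = ET_IMPACTION_COEF,
    exponent: float = ET_IMPACTION_EXP,
):
    """Mouth-throat capture probability, monotone in d^2 Q; in [0, 1]."""
    d = np.asarray(d_ae_um, dtype=float)
    if np.any(d <= 0) or flow_lpm <= 0:
        raise InputError("diameter and flow must be > 0")
    x = coef * (d ** 2 * flow_lpm) ** exponent
    out = x / (1.0 + x)
    return float(out) if np.isscalar(d_ae_um) else out


def _eta_impaction(d_m, velocity, tube_diam, branch_angle_rad):
    stk = (
        PARTICLE_DENSITY * d_m ** 2 * _slip_correction(d_m) * velocity
        / (18.0 * AIR_VISCOSITY * tube_diam)
    )
    x = np.clip(branch_angle_rad * stk, 0.0, 1.0)
    acos = np.arccos(x)
    return 1.0 - (2.0 / math.pi) * acos - (1.0 / math.pi) * np.sin(2.0 * acos)


def _eta_sedimentation(d_m, velocity, tube_diam, tube_len, cos_gravity):
    t = tube_len / velocity
    return 1.0 - np.exp(
        -4.0 * _settling_velocity(d_m) * t * cos_gravity / (math.pi * tube_diam)
    )


def _eta_diffusion(d_m, velocity, tube_diam, tube_len):
    q = velocity * math.pi * tube_diam ** 2 / 4.0
    mu = _diffusion_coefficient(d_m) * tube_len / q
    small = 5.50 * np.cbrt(mu) ** 2 - 3.77 * mu
    large = 1.0 - (
        0.819 * np.exp(-11.5 * mu)
        + 0.0975 * np.exp(-70.1 * mu)
        + 0.0325 * np.exp(-179.0 * mu)
    )
    return np.clip(np.where(mu < 0.007, small, large), 0.0, 1.0)


def _eta_hold(d_m, tube_diam, cos_gravity, hold_s):
    """Zero-flow settling + first-mode tube diffusion over a pause."""
    sed = 1.0 - np.exp(-_settling_velocity(d_m) * hold_s * cos_gravity / tube_diam)
    diff = 1.0 - np.exp(
        -5.78 * _diffusion_coefficient(d_m) * hold_s / (tube_diam / 2.0) ** 2
    )
    return _combine(sed, diff)


def _combine(*etas):
    """Independent-mechanism complement product."""
    survive = 1.0
    for eta in etas:
        survive = survive * (1.0 - np.clip(eta, 0.0, 1.0))
    return 1.0 - survive


def generation_deposition_prob(
    d_ae_um: float,
    generation: AirwayGeneration,
    residence_time_s: float,
    velocity_cm_s: float,
    gravity_angle_deg: float | None = None,
    branching_angle_deg: float | None = None,
) -> float:
    """Deposition probability of one particle in one airway tube.

    With positive velocity, the tube length implied by
    ``velocity * residence_time`` is used for the flow-through impaction,
    settling and diffusion formulas.  With zero velocity (breath hold), the
    zero-flow settling and diffusion forms act for ``residence_time_s``.
    """
    if d_ae_um <= 0:
        raise InputError("aerodynamic diameter must be > 0")
    if residence_time_s < 0 or velocity_cm_s < 0:
        raise InputError("residence time and velocity must be >= 0")
    if residence_time_s == 0:
        return 0.0
    d_m = d_ae_um * 1e-6
    diam = generation.mean_diameter_cm * 1e-2
    phi = math.radians(
        generation.gravity_angle_deg if gravity_angle_deg is None else gravity_angle_deg
    )
    if velocity_cm_s == 0:
        return float(_eta_hold(d_m, diam, math.cos(phi), residence_time_s))
    u = velocity_cm_s * 1e-2
    length = u * residence_time_s
    theta = math.radians(
        generation.branching_angle_deg if branching_angle_deg is None else branching_angle_deg
    )
    eta = _combine(
        _eta_impaction(d_m, u, diam, theta),
        _eta_sedimentation(d_m, u, diam, length, math.cos(phi)),
        _eta_diffusion(d_m, u, diam, length),
    )
    return float(eta)


# ---------------------------------------------------------------------------
# APSD sampling
# ---------------------------------------------------------------------------

def sample_apsd(
    mmad_um: float,
    gsd: float,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Mass-weighted aerodynamic diameters (um) from a lognormal APSD.

    Because (MMAD, GSD) parameterise the *mass* distribution, equal-mass
    particles are plain lognormal draws; count fractions are mass fractions.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if mmad_um <= 0 or gsd < 1.0:
        raise InputError("need MMAD > 0 and GSD >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(n)
    return mmad_um * np.exp(math.log(gsd) * z)


def sample_apsd_from_cumulative(
    cum: Sequence[tuple[float, float]],
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Sample diameters from cumulative-undersize points via a log-probit fit."""
    mmad, gsd, _ = fit_log_probit(cum)
    return sample_apsd(mmad, gsd, n, seed)


# ---------------------------------------------------------------------------
# whole-lung Monte Carlo
# ---------------------------------------------------------------------------

def _generation_volumes_m3(tree: list[AirwayGeneration], frc_ml: float) -> np.ndarray:
    """Per-generation gas volume (ducts + attached alveoli), m^3.

    Duct volumes follow the scaled scaffold; the remaining lung volume is
    alveolar and is allocated to the acinar generations in proportion to
    their tube counts.
    """
    duct = np.array(
        [
            g.multiplicity * math.pi / 4.0 * (g.mean_diameter_cm * 1e-2) ** 2 * (g.mean_length_cm * 1e-2)
            for g in tree
        ]
    )
    total = frc_ml * 1e-6
    alveolar_total = max(total - duct.sum() - ET_VOLUME_ML * 1e-6, 0.0)
    weights = np.array(
        [g.multiplicity if g.index >= ACINAR_START else 0.0 for g in tree]
    )
    alveolar = alveolar_total * weights / weights.sum()
    return duct + alveolar


def simulate(
    apsd: tuple[float, float] | np.ndarray,
    profile: BreathingProfile,
    n: int = 100_000,
    seed: int | None = None,
    *,
    geometry_cv: float = DEFAULT_GEOMETRY_CV,
    frc_ml: float = DEFAULT_FRC_ML,
    branching_angle_deg: float = DEFAULT_BRANCH_ANGLE_DEG,
    et_coef: float = ET_IMPACTION_COEF,
    et_exponent: float = ET_IMPACTION_EXP,
) -> DepositionResult:
    """Run the Monte Carlo deposition model on the emitted aerosol.

    Parameters
    ----------
    apsd
        Either ``(mmad_um, gsd)`` of a lognormal mass distribution, or an
        explicit array of aerodynamic diameters in um (then its length
        overrides ``n``).
    profile
        Breathing manoeuvre; inspiratory/expiratory flows are taken constant
        at volume/time.
    n, seed
        Particle count (>= 100) and RNG seed; the seed is recorded in the
        result and makes the run bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    if isinstance(apsd, tuple) and len(apsd) == 2 and np.isscalar(apsd[0]):
        if n < 100:
            raise InputError("n must be >= 100")
        d_um = sample_apsd(float(apsd[0]), float(apsd[1]), n, rng)
    else:
        d_um = np.asarray(apsd, dtype=float)
        n = d_um.size
        if n < 100:
            raise InputError("n must be >= 100")
        if np.any(d_um <= 0):
            raise InputError("diameters must be > 0")
    if geometry_cv < 0:
        raise InputError("geometry CV must be >= 0")

    # -- fixed draw order, independent of the breathing profile, so runs
    #    differing only in breath-hold time are pathwise paired
    u_et = rng.random(n)
    u_vol = rng.random(n)
    sigma = math.sqrt(math.log(1.0 + geometry_cv ** 2))
    f_len = np.exp(sigma * rng.standard_normal((n, N_GENERATIONS)) - sigma ** 2 / 2.0)
    f_dia = np.exp(sigma * rng.standard_normal((n, N_GENERATIONS)) - sigma ** 2 / 2.0)
    cos_phi = np.cos(rng.uniform(0.0, math.pi / 2.0, (n, N_GENERATIONS)))
    u_inh = rng.random((n, N_GENERATIONS))
    u_hold = rng.random(n)
    u_exh = rng.random((n, N_GENERATIONS))

    tree = build_airway_tree(frc_ml, branching_angle_deg)
    length_m = np.array([g.mean_length_cm * 1e-2 for g in tree])
    diam_m = np.array([g.mean_diameter_cm * 1e-2 for g in tree])
    counts = np.array([g.multiplicity for g in tree], dtype=float)
    theta = math.radians(branching_angle_deg)

    d_m = d_um * 1e-6
    flow_in_lpm = profile.mean_inspiratory_flow_lpm
    q_in = profile.inhaled_volume_l * 1e-3 / profile.inhalation_time_s       # m3/s
    q_ex = profile.inhaled_volume_l * 1e-3 / profile.exhalation_time_s

    # extrathoracic filter on inhalation
    deposited_et = u_et < extrathoracic_efficiency(d_um, flow_in_lpm, et_coef, et_exponent)
    alive = ~deposited_et

    # penetration depth: generation where the particle's share of the inhaled
    # volume is exhausted against cumulative airway + alveolar volume
    cumvol = np.cumsum(_generation_volumes_m3(tree, frc_ml))
    v_target = np.maximum(u_vol * profile.inhaled_volume_l * 1e-3 - ET_VOLUME_ML * 1e-6, 0.0)
    g_rest = np.clip(np.searchsorted(cumvol, v_target, side="left"), 0, N_GENERATIONS - 1)

    gen_deposit = np.zeros(N_GENERATIONS, dtype=np.int64)

    def _transit(g: int, q_total: float, u_rand: np.ndarray) -> None:
        idx = np.nonzero(alive & (g_rest >= g))[0]
        if idx.size == 0:
            return
        lp = length_m[g] * f_len[idx, g]
        dp = diam_m[g] * f_dia[idx, g]
        u_gas = (q_total / counts[g]) / (math.pi / 4.0 * dp ** 2)
        eta = _combine(
            _eta_impaction(d_m[idx], u_gas, dp, theta),
            _eta_sedimentation(d_m[idx], u_gas, dp, lp, cos_phi[idx, g]),
            _eta_diffusion(d_m[idx], u_gas, dp, lp),
        )
        hit = u_rand[idx, g] < eta
        gen_deposit[g] += int(hit.sum())
        alive[idx[hit]] = False

    for g in range(N_GENERATIONS):                      # inhalation
        _transit(g, q_in, u_inh)

    if profile.breath_hold_s > 0:                       # breath hold at rest depth
        idx = np.nonzero(alive)[0]
        if idx.size:
            gr = g_rest[idx]
            dp = diam_m[gr] * f_dia[idx, gr]
            eta = _eta_hold(d_m[idx], dp, cos_phi[idx, gr], profile.breath_hold_s)
            hit = u_hold[idx] < eta
            np.add.at(gen_deposit, gr[hit], 1)
            alive[idx[hit]] = False

    for g in range(N_GENERATIONS - 1, -1, -1):          # exhalation (ET passes through)
        _transit(g, q_ex, u_exh)

    n_et = int(deposited_et.sum())
    n_exh = int(alive.sum())
    n_lung = int(gen_deposit.sum())
    assert n_et + n_exh + n_lung == n

    to_pct = 100.0 / n
    return DepositionResult(
        et_pct=n_et * to_pct,
        lung_pct=n_lung * to_pct,
        bronchial_pct=int(gen_deposit[:ACINAR_START].sum()) * to_pct,
        acinar_pct=int(gen_deposit[ACINAR_START:].sum()) * to_pct,
        exh_pct=n_exh * to_pct,
        per_generation_pct=tuple(gen_deposit * to_pct),
        n_particles=n,
        seed=seed,
    )


def plot_deposition(results: dict[str, DepositionResult], ax=None):
    """Stacked ET / LUNG / EXH bars, one per labelled result."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 + 1.2 * len(results), 4))
    labels = list(results)
    et = np.array([results[k].et_pct for k in labels])
    lung = np.array([results[k].lung_pct for k in labels])
    exh = np.array([results[k].exh_pct for k in labels])
    x = np.arange(len(labels))
    ax.bar(x, et, label="ET")
    ax.bar(x, lung, bottom=et, label="LUNG")
    ax.bar(x, exh, bottom=et + lung, label="EXH")
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=30, ha="right")
    ax.set_ylabel("deposited / exhaled mass (%)")
    ax.legend()
    return ax
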