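"""Synthetic input generators with the statistical structure the pipeline assumes.

Every generator is deterministic under a fixed seed and, at zero noise, is
exactly inverted by its downstream pipeline stage: forward-generated contact
angles solve back to the truth components, noise-free impactor runs reduce
to the truth (MMAD, GSD), and zero-spread uniformity samples pass every rule.

Default truth values are plausible for a micronised/spray-dried drug blended
on a coarse lactose carrier (with and without a magnesium stearate coat).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from . import energetics
from .errors import InputError
from .impactor import ACI_CUTOFFS_28_3_LPM, ImpactorRun

__all__ = [
    "SyntheticSpec",
    "gen_contact_angles",
    "gen_impactor_run",
    "gen_uniformity_samples",
    "angle_table",
    "impactor_table",
]


class MaterialTruth(BaseModel):
    """True surface-energy components and median size of one material."""

    model_config = ConfigDict(extra="forbid")
    gamma_sd: float = Field(gt=0)
    gamma_sp: float = Field(ge=0)
    d50_um: float = Field(gt=0)


class ApsdTruth(BaseModel):
    """True lognormal APSD and device/capsule retention of one formulation."""

    model_config = ConfigDict(extra="forbid")
    mmad_um: float = Field(gt=0)
    gsd: float = Field(ge=1.0)
    device_frac: float = Field(default=0.05, ge=0, lt=1)
    capsule_frac: float = Field(default=0.03, ge=0, lt=1)
    port_frac: float = Field(default=0.15, ge=0, lt=1)

    @model_validator(mode="after")
    def _fractions_leave_sized_mass(self):
        if self.device_frac + self.capsule_frac + self.port_frac >= 1.0:
            raise ValueError("retention fractions must leave sized mass")
        return self


class SyntheticSpec(BaseModel):
    """Truth parameters and noise scales for one synthetic dataset."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    materials: dict[str, MaterialTruth] = Field(
        default_factory=lambda: {
            "drug_micronised": MaterialTruth(gamma_sd=42.07, gamma_sp=33.18, d50_um=3.602),
            "drug_spray_dried": MaterialTruth(gamma_sd=39.93, gamma_sp=33.44, d50_um=2.109),
            "carrier": MaterialTruth(gamma_sd=45.58, gamma_sp=36.88, d50_um=215.0),
            "carrier_coated": MaterialTruth(gamma_sd=26.07, gamma_sp=19.22, d50_um=215.0),
            "coating_agent": MaterialTruth(gamma_sd=24.33, gamma_sp=2.64, d50_um=6.92),
        }
    )
    blends: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "drug_micronised+carrier": {"drug_micronised": 0.2, "carrier": 2.0},
            "drug_micronised+carrier_coated": {
                "drug_micronised": 0.2, "carrier": 1.956, "coating_agent": 0.044,
            },
            "drug_spray_dried+carrier": {"drug_spray_dried": 0.2, "carrier": 2.0},
            "drug_spray_dried+carrier_coated": {
                "drug_spray_dried": 0.2, "carrier": 1.956, "coating_agent": 0.044,
            },
        }
    )
    apsd: dict[str, ApsdTruth] = Field(
        default_factory=lambda: {
            "drug_micronised+carrier": ApsdTruth(mmad_um=7.18, gsd=1.8),
            "drug_micronised+carrier_coated": ApsdTruth(mmad_um=7.43, gsd=1.8),
            "drug_spray_dried+carrier": ApsdTruth(mmad_um=3.82, gsd=1.8),
            "drug_spray_dried+carrier_coated": ApsdTruth(mmad_um=3.11, gsd=1.8),
        }
    )
    dose_ug: float = Field(default=1300.0, gt=0)
    n_angle_replicates: int = Field(default=3, ge=1)
    angle_noise_sd_deg: float = Field(default=0.5, ge=0)
    impactor_cv: float = Field(default=0.05, ge=0)
    uniformity_sd_pct: float = Field(default=3.0, ge=0)
    uniformity_bias_pct: float = 0.0
    n_uniformity: int = Field(default=10, ge=2)


def gen_contact_angles(
    material: str,
    gamma_sd: float,
    gamma_sp: float,
    n_replicates: int = 3,
    noise_sd_deg: float = 0.5,
    seed: int | np.random.Generator | None = None,
    liquids: Sequence[energetics.ProbeLiquid] = energetics.DEFAULT_LIQUIDS,
) -> pd.DataFrame:
    """Replicate contact angles consistent with known components plus noise.

    Columns: material, liquid, theta_deg.  Raises when the truth admits no
    finite angle on one of the probe liquids (complete wetting).
    """
    if noise_sd_deg < 0:
        raise InputError("noise SD must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for liquid in liquids:
        theta = energetics.forward_contact_angle(gamma_sd, gamma_sp, liquid)
        noisy = theta + noise_sd_deg * rng.standard_normal(n_replicates)
        for value in np.clip(noisy, 0.0, 179.0):
            rows.append({"material": material, "liquid": liquid.name, "theta_deg": float(value)})
    return pd.DataFrame(rows)


def gen_impactor_run(
    mmad_um: float,
    gsd: float,
    total_mass_ug: float = 1300.0,
    device_frac: float = 0.05,
    capsule_frac: float = 0.03,
    port_frac: float = 0.15,
    cv: float = 0.0,
    seed: int | np.random.Generator | None = None,
    stage_ecd_um: tuple[float, ...] = ACI_CUTOFFS_28_3_LPM,
    flow_rate_lpm: float = 28.3,
    run_id: str = "",
) -> ImpactorRun:
    """An impactor run whose sized mass follows a lognormal APSD.

    Stage masses are the lognormal CDF differences between consecutive
    cut-offs (stage 0 additionally collects everything above its cut-off;
    the filter collects everything below the last), each multiplied by a
    unit-mean lognormal factor of coefficient of variation ``cv``.  Device,
    capsule and induction-port retention are fixed fractions of the total.
    """
    if mmad_um <= 0 or gsd < 1.0:
        raise InputError("need MMAD > 0 and GSD >= 1")
    if cv < 0:
        raise InputError("cv must be >= 0")
    if device_frac + capsule_frac + port_frac >= 1.0:
        raise InputError("retention fractions must leave sized mass")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sized_total = total_mass_ug * (1.0 - device_frac - capsule_frac - port_frac)
    if gsd == 1.0:
        cdf = (np.asarray(stage_ecd_um) > mmad_um).astype(float)
    else:
        cdf = stats.norm.cdf(np.log(np.asarray(stage_ecd_um) / mmad_um) / math.log(gsd))
    # cdf is undersize at each cut-off, descending cut-offs: stage i collects
    # the band between cut-off i-1 (or infinity) and cut-off i
    upper = np.concatenate(([1.0], cdf[:-1]))
    stage_frac = upper - cdf
    filter_frac = cdf[-1]
    fracs = np.concatenate((stage_frac, [filter_frac]))
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv ** 2))
        noise = np.exp(sigma * rng.standard_normal(fracs.size) - sigma ** 2 / 2.0)
        fracs = fracs * noise
    masses = sized_total * fracs
    return ImpactorRun(
        flow_rate_lpm=flow_rate_lpm,
        device_mass=total_mass_ug * device_frac,
        capsule_mass=total_mass_ug * capsule_frac,
        induction_port_mass=total_mass_ug * port_frac,
        mouthpiece_mass=0.0,
        stage_masses=tuple(float(m) for m in masses[:-1]),
        filter_mass=float(masses[-1]),
        stage_ecd_um=tuple(stage_ecd_um),
        run_id=run_id,
    )


def gen_uniformity_samples(
    label_claim_pct: float = 100.0,
    bias_pct: float = 0.0,
    sd_pct: float = 3.0,
    n: int = 10,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Gaussian dosage-unit contents as % of label claim."""
    if n < 2:
        raise InputError("n must be >= 2")
    if sd_pct < 0:
        raise InputError("sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return label_claim_pct + bias_pct + sd_pct * rng.standard_normal(n)


# ---------------------------------------------------------------------------
# whole-dataset helpers used by the pipeline / CLI
# ---------------------------------------------------------------------------

def angle_table(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    frames = [
        gen_contact_angles(
            name,
            truth.gamma_sd,
            truth.gamma_sp,
            n_replicates=spec.n_angle_replicates,
            noise_sd_deg=spec.angle_noise_sd_deg,
            seed=rng,
        )
        for name, truth in spec.materials.items()
    ]
    return pd.concat(frames, ignore_index=True)


def impactor_table(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Long-format (run_id, location, mass_ug) rows for every formulation."""
    rows = []
    for name, truth in spec.apsd.items():
        run = gen_impactor_run(
            truth.mmad_um,
            truth.gsd,
            total_mass_ug=spec.dose_ug,
            device_frac=truth.device_frac,
            capsule_frac=truth.capsule_frac,
            port_frac=truth.port_frac,
            cv=spec.impactor_cv,
            seed=rng,
            run_id=name,
        )
        rows.append({"run_id": name, "location": "device", "mass_ug": run.device_mass})
        rows.append({"run_id": name, "location": "capsule", "mass_ug": run.capsule_mass})
        rows.append({"run_id": name, "location": "induction_port", "mass_ug": run.induction_port_mass})
        rows.append({"run_id": name, "location": "mouthpiece", "mass_ug": run.mouthpiece_mass})
        for i, mass in enumerate(run.stage_masses):
            rows.append({"run_id": name, "location": f"stage{i}", "mass_ug": mass})
        rows.append({"run_id": name, "location": "filter", "mass_ug": run.filter_mass})
    return pd.DataFrame(rows)
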