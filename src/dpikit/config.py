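"""Schema-validated pipeline configuration (unknown keys rejected)."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .impactor import ACI_CUTOFFS_28_3_LPM
from .synthetic import SyntheticSpec

__all__ = [
    "ProbeLiquidConfig",
    "ImpactorConfig",
    "BreathingConfig",
    "SimulatorConfig",
    "PipelineConfig",
    "load_config",
]


class ProbeLiquidConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    gamma_d: float = Field(gt=0)
    gamma_p: float = Field(ge=0)


class ImpactorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    flow_rate_lpm: float = 28.3
    stage_ecd_um: list[float] = Field(default_factory=lambda: list(ACI_CUTOFFS_28_3_LPM))
    fpf_basis: str = "emitted"       # emitted | recovered | sized
    fpf_method: str = "fit"          # fit | interp


class BreathingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    inhaled_volume_l: float = 1.7
    inhalation_time_s: float = 3.2
    breath_hold_s: float = 5.0
    exhalation_time_s: float = 3.0


class SimulatorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_particles: int = Field(default=20_000, ge=100)
    frc_ml: float = Field(default=3300.0, gt=0)
    geometry_cv: float = Field(default=0.1, ge=0)
    branching_angle_deg: float = 35.0
    et_coef: float = 2.78e-4
    et_exponent: float = 1.152


class PipelineConfig(BaseModel):
    """Resolved configuration of one end-to-end pipeline run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 1
    output_precision: int = Field(default=6, ge=1, le=17)
    liquids: list[ProbeLiquidConfig] = Field(
        default_factory=lambda: [
            ProbeLiquidConfig(name="water", gamma_d=22.6, gamma_p=50.2),
            ProbeLiquidConfig(name="diiodomethane", gamma_d=49.0, gamma_p=1.8),
        ]
    )
    impactor: ImpactorConfig = Field(default_factory=ImpactorConfig)
    breathing: dict[str, BreathingConfig] = Field(
        default_factory=lambda: {
            "copd_bh5": BreathingConfig(breath_hold_s=5.0),
            "copd_bh10": BreathingConfig(breath_hold_s=10.0),
        }
    )
    simulator: SimulatorConfig = Field(default_factory=SimulatorConfig)
    synthetic: SyntheticSpec = Field(default_factory=SyntheticSpec)

    def dump_json(self, path: Path) -> None:
        path.write_text(json.dumps(self.model_dump(), indent=2, sort_keys=True) + "\n")


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    return PipelineConfig.model_validate(json.loads(Path(path).read_text()))
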