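"""End-to-end run: synthesise inputs, then energetics -> blend -> impactor -> lungsim.

Each stage writes plain CSV/JSON with unit-suffixed columns; the resolved
configuration is echoed beside the outputs and a log records versions and
seeds.  Identical config + seed reproduces every numeric output byte for
byte (single-threaded contract): per-stage seeds are spawned deterministically
from the master seed and no timestamps enter numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, blend, energetics, impactor, lungsim, synthetic
from .config import PipelineConfig
from .errors import DpikitError, PipelineStageError

__all__ = ["run_pipeline", "setup_logging"]

logger = logging.getLogger("dpikit")


def setup_logging(level: str = "INFO", log_file: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


def _round_df(df: pd.DataFrame, precision: int) -> pd.DataFrame:
    return df.round(precision)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute all stages; returns the paths written, keyed by artifact name."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(log_file=out / "run.log")
    logger.info("dpikit %s | numpy %s | master seed %d", __version__, np.__version__, config.seed)

    paths: dict[str, Path] = {}
    config.dump_json(out / "config.json")
    paths["config"] = out / "config.json"
    prec = config.output_precision
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    spec = config.synthetic.model_copy(update={"seed": config.seed})

    # ---- synthetic inputs ---------------------------------------------------
    stage = "synth"
    try:
        rng = np.random.default_rng(seeds[0])
        angles = synthetic.angle_table(spec, rng)
        runs_table = synthetic.impactor_table(spec, rng)
        contents = synthetic.gen_uniformity_samples(
            bias_pct=spec.uniformity_bias_pct,
            sd_pct=spec.uniformity_sd_pct,
            n=spec.n_uniformity,
            seed=rng,
        )
        d50 = pd.DataFrame(
            [{"material": m, "d50_um": t.d50_um} for m, t in spec.materials.items()]
        )
        _round_df(angles, prec).to_csv(out / "angles.csv", index=False)
        _round_df(runs_table, prec).to_csv(out / "impactor_runs.csv", index=False)
        d50.to_csv(out / "d50.csv", index=False)
        pd.DataFrame({"content_pct": np.round(contents, prec)}).to_csv(
            out / "uniformity_samples.csv", index=False
        )
        paths.update(
            angles=out / "angles.csv",
            impactor_runs=out / "impactor_runs.csv",
            d50=out / "d50.csv",
            uniformity_samples=out / "uniformity_samples.csv",
        )
        logger.info("synth: %d angle rows, %d impactor rows", len(angles), len(runs_table))
    except (DpikitError, ValueError, KeyError) as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- surface energetics -------------------------------------------------
    stage = "energetics"
    try:
        liquids = tuple(
            energetics.ProbeLiquid(l.name, l.gamma_d, l.gamma_p) for l in config.liquids
        )
        energy_table, energies = energetics.solve_table(angles, liquids)
        d50_map = dict(zip(d50["material"], d50["d50_um"]))
        pairs = pd.DataFrame(
            [
                {"material_1": drug, "material_2": carrier}
                for blend_name in spec.blends
                for drug, carrier in [blend_name.split("+", 1)]
            ]
        )
        pair_table, _ = energetics.interaction_table(pairs, energies, d50_map)
        _round_df(energy_table, prec).to_csv(out / "surface_energy.csv", index=False)
        _round_df(pair_table, max(prec, 9)).to_csv(out / "interactions.csv", index=False)
        paths.update(surface_energy=out / "surface_energy.csv", interactions=out / "interactions.csv")
        logger.info("energetics: solved %d materials", len(energies))
    except (DpikitError, ValueError, KeyError) as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- blend design -------------------------------------------------------
    stage = "blend"
    try:
        blend_rows = []
        for name, comp in spec.blends.items():
            drug = name.split("+", 1)[0]
            b = blend.BlendComposition(tuple(comp.items()), drug_component=drug)
            blend_rows.append(
                {
                    "blend": name,
                    "drug_fraction": b.drug_fraction,
                    "fill_mass_mg": round(blend.fill_mass(spec.dose_ug / 1000.0, b.drug_fraction), 1),
                }
            )
        report = blend.assess_uniformity(contents)
        _round_df(pd.DataFrame(blend_rows), prec).to_csv(out / "blend_design.csv", index=False)
        _write_json(
            out / "uniformity.json",
            {
                "mean_pct": round(report.mean_pct, prec),
                "rsd_pct": round(report.rsd_pct, prec),
                "pass_pharmacopeia": report.pass_pharmacopeia,
                "pass_industry": report.pass_industry,
            },
        )
        paths.update(blend_design=out / "blend_design.csv", uniformity=out / "uniformity.json")
        logger.info("blend: %d blends, uniformity RSD %.2f%%", len(blend_rows), report.rsd_pct)
    except (DpikitError, ValueError, KeyError) as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- impactor reduction -------------------------------------------------
    stage = "impactor"
    try:
        runs = impactor.runs_from_table(
            runs_table,
            flow_rate_lpm=config.impactor.flow_rate_lpm,
            stage_ecd_um=tuple(config.impactor.stage_ecd_um),
        )
        apsd_rows = []
        reduced: dict[str, impactor.APSDResult] = {}
        for run in runs:
            res = impactor.reduce_run(
                run, basis=config.impactor.fpf_basis, method=config.impactor.fpf_method
            )
            reduced[run.run_id] = res
            apsd_rows.append(
                {
                    "run_id": run.run_id,
                    "fpf5_pct": res.fpf5_pct,
                    "fpf3_pct": res.fpf3_pct,
                    "mmad_um": res.mmad_um,
                    "gsd": res.gsd,
                    "ef_pct": res.ef_pct,
                    "r_squared": res.r_squared,
                }
            )
        _round_df(pd.DataFrame(apsd_rows), prec).to_csv(out / "apsd.csv", index=False)
        paths["apsd"] = out / "apsd.csv"
        logger.info("impactor: reduced %d runs", len(runs))
    except (DpikitError, ValueError, KeyError) as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- lung deposition ----------------------------------------------------
    stage = "lungsim"
    try:
        sim = config.simulator
        dep_rows, dep_json = [], {}
        sim_seed = int(seeds[3].generate_state(1)[0])
        for run_id, res in reduced.items():
            for prof_name, prof_cfg in config.breathing.items():
                profile = lungsim.BreathingProfile(
                    prof_cfg.inhaled_volume_l,
                    prof_cfg.inhalation_time_s,
                    prof_cfg.breath_hold_s,
                    prof_cfg.exhalation_time_s,
                )
                result = lungsim.simulate(
                    (res.mmad_um, res.gsd),
                    profile,
                    n=sim.n_particles,
                    seed=sim_seed,
                    geometry_cv=sim.geometry_cv,
                    frc_ml=sim.frc_ml,
                    branching_angle_deg=sim.branching_angle_deg,
                    et_coef=sim.et_coef,
                    et_exponent=sim.et_exponent,
                )
                key = f"{run_id}|{prof_name}"
                dep_json[key] = {
                    k: (round(v, prec) if isinstance(v, float) else v)
                    for k, v in dataclasses.asdict(result).items()
                    if k != "per_generation_pct"
                }
                dep_rows.extend(
                    {
                        "run_id": run_id,
                        "profile": prof_name,
                        "generation": g,
                        "deposit_pct": round(pct, prec),
                    }
                    for g, pct in enumerate(result.per_generation_pct)
                )
        _write_json(out / "deposition.json", dep_json)
        pd.DataFrame(dep_rows).to_csv(out / "deposition_per_generation.csv", index=False)
        paths.update(
            deposition=out / "deposition.json",
            deposition_per_generation=out / "deposition_per_generation.csv",
        )
        logger.info("lungsim: %d scenario runs", len(dep_json))
    except (DpikitError, ValueError, KeyError) as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    logger.info("pipeline complete: %d artifacts in %s", len(paths), out)
    return paths
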