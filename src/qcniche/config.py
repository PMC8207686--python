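"""Run configuration, validation, and the staged pipeline runner.

A run config (YAML) selects the model, parameters, and which stages to
execute; :func:`run_pipeline` writes per-stage CSV/JSON outputs plus a
manifest (seed, config hash, package version) that makes reruns
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .calibration import FoldChangeCalibration
from .contributions import (
    AttenuationFactors,
    DivisionData,
    OBSERVED_DIVISION_DATA,
    QCDivisionModel,
    sweep_qB,
)
from .panel import (
    ExplorationConfig,
    explore_parameter_space,
    genotype_panel,
    sweep_medium,
)
from .parameters import (
    ComplexParameterSet,
    ParameterSet,
    ValidationError,
    default_parameters,
    load_params,
    save_params,
)
from .synthetic import estimate_foldchanges_from_gfp, generate_gfp

__all__ = ["RunConfig", "load_config", "run_pipeline"]

log = logging.getLogger("qcniche")

STAGE_ORDER = ("calibrate", "panel", "explore", "sweep_medium", "contributions", "synth")


class ExplorationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_runs: int = 1000
    range_factor: float = 2.0


class CalibrationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_starts: int = 8
    maxiter: int = 600


class ContributionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    a: float = OBSERVED_DIVISION_DATA.a
    b: float = OBSERVED_DIVISION_DATA.b
    c: float = OBSERVED_DIVISION_DATA.c
    d: float = OBSERVED_DIVISION_DATA.d
    n_eff: int = 15
    qW_bravo: float = 0.8
    qB_wox5: float = 0.5
    qB_grid: Optional[list[float]] = None


class SynthSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    wt_mean: float = 100.0
    cv: float = 0.3
    n_roots: int = 30


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    model: str = "alleviation"
    parameters: Optional[dict] = None
    parameter_file: Optional[str] = None
    stages: list[str] = Field(default_factory=lambda: ["panel", "contributions"])
    medium_x: list[float] = Field(default_factory=lambda: [float(x) for x in range(1, 11)])
    exploration: ExplorationSection = Field(default_factory=ExplorationSection)
    calibration: CalibrationSection = Field(default_factory=CalibrationSection)
    contributions: ContributionSection = Field(default_factory=ContributionSection)
    synth: SynthSection = Field(default_factory=SynthSection)
    out_dir: str = "qcniche_run"
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("model")
    @classmethod
    def _check_model(cls, v: str) -> str:
        if v not in ("alleviation", "activation", "complex"):
            raise ValueError(f"model must be alleviation/activation/complex, got {v!r}")
        return v

    @field_validator("stages")
    @classmethod
    def _check_stages(cls, v: list[str]) -> list[str]:
        for s in v:
            if s not in STAGE_ORDER:
                raise ValueError(f"unknown stage {s!r}; expected one of {STAGE_ORDER}")
        return v

    def resolve_params(self) -> ParameterSet:
        if self.parameters is not None:
            cls = ComplexParameterSet if self.model == "complex" else ParameterSet
            return cls.from_dict(self.parameters)
        if self.parameter_file is not None:
            return load_params(self.parameter_file)
        return default_parameters(self.model)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; errors name the offending key."""
    path = Path(path)
    try:
        payload = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as e:
        raise ValidationError(f"{path}: YAML parse error: {e}") from e
    try:
        cfg = RunConfig(**payload)
        cfg.resolve_params()  # surface parameter invariant violations early
    except (ValueError, TypeError) as e:
        raise ValidationError(f"{path}: {e}") from e
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages in canonical order and write results.

    Every stage writes CSV/JSON under ``out_dir``; a manifest records the
    seed, config hash and package version.  A stage failure halts the run
    but still writes a partial-results manifest.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "config": cfg.model_dump(),
        "stages_completed": [],
        "status": "running",
    }
    params = cfg.resolve_params()
    stages = [s for s in STAGE_ORDER if s in cfg.stages]
    try:
        for stage in stages:
            t0 = time.perf_counter()
            if stage == "calibrate":
                cal = FoldChangeCalibration(cfg.model)
                res = cal.fit(
                    seed=cfg.seed,
                    n_starts=cfg.calibration.n_starts,
                    maxiter=cfg.calibration.maxiter,
                )
                params = res.params
                save_params(params, out / "calibrated_params.yaml")
                (out / "calibration_summary.txt").write_text(res.summary() + "\n")
            elif stage == "panel":
                table = genotype_panel(cfg.model, params, check_saturation=True)
                table.to_frame().to_csv(out / "panel.csv", index=False)
            elif stage == "explore":
                ecfg = ExplorationConfig(
                    n_runs=cfg.exploration.n_runs,
                    range_factor=cfg.exploration.range_factor,
                    seed=cfg.seed,
                )
                res = explore_parameter_space(cfg.model, params, ecfg)
                res.ensemble.to_csv(out / "exploration_ensemble.csv", index=False)
                res.summary.to_csv(out / "exploration_summary.csv", index=False)
                (out / "exploration_meta.json").write_text(
                    json.dumps({"n_failures": res.n_failures, "n_runs": ecfg.n_runs})
                )
            elif stage == "sweep_medium":
                df = sweep_medium(cfg.model, params, cfg.medium_x)
                df.to_csv(out / "medium_sweep.csv", index=False)
            elif stage == "contributions":
                c = cfg.contributions
                data = DivisionData(a=c.a, b=c.b, c=c.c, d=c.d, n_eff=c.n_eff)
                q = AttenuationFactors(qW_bravo=c.qW_bravo, qB_wox5=c.qB_wox5)
                res = QCDivisionModel(data, q).fit()
                e = res.estimate
                (out / "contributions.json").write_text(
                    json.dumps(
                        {
                            "F0": e.F0,
                            "T_B": e.T_B,
                            "T_W": e.T_W,
                            "T_BW": e.T_BW,
                            "delta_T_B": e.delta_T_B,
                            "delta_T_W": e.delta_T_W,
                            "delta_T_BW": e.delta_T_BW,
                        },
                        indent=2,
                    )
                )
                sweep_qB(data, qW=q.qW_bravo, qB_grid=c.qB_grid).to_csv(
                    out / "contribution_sweep.csv", index=False
                )
            elif stage == "synth":
                table = genotype_panel(cfg.model, params)
                samples = generate_gfp(
                    table,
                    wt_mean=cfg.synth.wt_mean,
                    cv=cfg.synth.cv,
                    n_roots=cfg.synth.n_roots,
                    seed=cfg.seed,
                )
                rows = [
                    {
                        "genotype": s.genotype,
                        "reporter": s.reporter,
                        "root_id": i,
                        "intensity": v,
                    }
                    for s in samples
                    for i, v in enumerate(s.intensities)
                ]
                import pandas as pd

                pd.DataFrame(rows).to_csv(out / "gfp_synthetic.csv", index=False)
                estimate_foldchanges_from_gfp(samples).to_csv(
                    out / "gfp_foldchanges.csv", index=False
                )
            manifest["stages_completed"].append(
                {"stage": stage, "seconds": round(time.perf_counter() - t0, 3)}
            )
            log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
        manifest["status"] = "ok"
    except Exception as e:  # halt, keep partial manifest
        manifest["status"] = "failed"
        manifest["error"] = f"{type(e).__name__}: {e}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
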