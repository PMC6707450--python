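"""Run configuration schema (YAML/JSON), validation, and reproducibility
metadata.

A run config has four blocks: ``model`` (either explicit rate constants or a
calibration request), ``experiment`` (one of simulate / steady_state /
variance_sweep / moran / qc_sweep with its own options), ``seed``, and
``scale`` ("desk" keeps ensemble sizes desk-scale; "full" multiplies them up
to the printed protocol sizes).  Unknown keys are rejected.  Every run writes
a manifest JSON echoing the fully resolved configuration, including derived
calibration values, so a manifest can be re-run bit-identically.

All rates are per day; times are days.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .model import ModelParams
from .calibration import calibrate_replication_control, calibrate_degradation_control

__all__ = ["RunConfig", "load_config", "resolve_model", "write_manifest"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ExplicitModel(_Strict):
    gamma: float = Field(ge=0)
    beta: float = Field(ge=0)
    mu: float = Field(ge=0)
    b: float = Field(ge=0)
    kappa: float
    delta: float = Field(default=1.0, ge=0)
    eps_f: float = Field(default=0.0, ge=0)
    eps_m: float = Field(default=0.0, ge=0)
    mu_f: float = Field(default=0.0, ge=0)
    control_mode: Literal["replication", "degradation"] = "replication"
    replication_topology: Literal[
        "singleton_to_fused", "singleton_to_singleton"
    ] = "singleton_to_fused"
    M: float = Field(default=1.0, gt=0)
    R: float = Field(default=1.0, gt=0)
    lam0: float = Field(default=0.0, ge=0)


class CalibratedModel(_Strict):
    calibrate: Literal["replication", "degradation"] = "replication"
    mu: float = Field(default=0.023, gt=0)
    lam0: float = Field(default=0.0115, gt=0)
    n_target: float = Field(default=1000.0, gt=0)
    fs_target: float = Field(default=0.5, gt=0, lt=1)
    beta_over_mu: float = Field(default=1000.0, gt=0)
    beta: float = Field(default=23.0, gt=0)
    b: float = Field(default=1e-4, gt=0)
    delta: float = Field(default=1.0, ge=0)
    eps_f: float = Field(default=0.0, ge=0)
    eps_m: float = Field(default=0.0, ge=0)
    M: float = Field(default=0.1, gt=0)
    R: float = Field(default=1.0, gt=0)


ModelBlock = Union[ExplicitModel, CalibratedModel]


class SimulateExperiment(_Strict):
    kind: Literal["simulate"] = "simulate"
    h0: float = Field(default=0.3, ge=0, le=1)
    t_max: float = Field(default=1000.0, gt=0)
    n_record: int = Field(default=21, ge=2)
    n_traj: int = Field(default=100, ge=2)


class SteadyStateExperiment(_Strict):
    kind: Literal["steady_state"] = "steady_state"
    h_grid: list[float] = Field(default_factory=lambda: [0.1 * i for i in range(1, 10)])


class VarianceSweepExperiment(_Strict):
    kind: Literal["variance_sweep"] = "variance_sweep"
    sweep_var: Literal["mu", "n_target", "delta", "ratio"] = "mu"
    values: list[float] = Field(default_factory=lambda: [0.01, 0.023, 0.07])
    h0: float = Field(default=0.3, gt=0, lt=1)
    n_traj: int = Field(default=300, ge=2)
    t_max: Optional[float] = Field(default=None, gt=0)  # None: auto horizon


class MoranExperiment(_Strict):
    kind: Literal["moran"] = "moran"
    n: int = Field(default=1000, ge=1)
    mu: float = Field(default=0.023, ge=0)
    fs: float = Field(default=1.0, ge=0, le=1)
    t_max: float = Field(default=1000.0, gt=0)
    n_record: int = Field(default=11, ge=2)
    n_reps: int = Field(default=100, ge=1)


class QCSweepExperiment(_Strict):
    kind: Literal["qc_sweep"] = "qc_sweep"
    eps_f: float = Field(default=0.0, ge=0)
    eps_m: float = Field(default=0.0, ge=0)
    ratio_grid: list[float] = Field(
        default_factory=lambda: [0.01, 0.1, 1.0, 10.0, 100.0])
    t_eval: float = Field(default=1000.0, gt=0)
    h0: float = Field(default=0.3, gt=0, lt=1)
    n_iter: int = Field(default=500, ge=2)


Experiment = Union[
    SimulateExperiment, SteadyStateExperiment, VarianceSweepExperiment,
    MoranExperiment, QCSweepExperiment,
]


class RunConfig(_Strict):
    model: ModelBlock
    experiment: Experiment = Field(discriminator="kind")
    seed: int = 0
    scale: Literal["desk", "full"] = "desk"
    output_format: Literal["csv"] = "csv"


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data)


def resolve_model(block: ModelBlock) -> ModelParams:
    """Turn a model block into concrete ModelParams (running calibration
    when requested)."""
    if isinstance(block, ExplicitModel):
        return ModelParams(**block.model_dump())
    kw = block.model_dump()
    kind = kw.pop("calibrate")
    eps_f, eps_m = kw.pop("eps_f"), kw.pop("eps_m")
    if kind == "replication":
        kw.pop("lam0")
        kw.pop("beta")
        params = calibrate_replication_control(**kw)
    else:
        kw.pop("mu")
        kw.pop("beta_over_mu")
        params = calibrate_degradation_control(**kw)
    return params.with_(eps_f=eps_f, eps_m=eps_m)


def write_manifest(outdir, config: RunConfig, params: ModelParams,
                   extra: dict | None = None) -> Path:
    """Write the reproducibility manifest: resolved config, derived rate
    constants, seed and package version."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "resolved_params": params.to_dict(),
        "seed": config.seed,
        "package_version": __version__,
    }
    if extra:
        manifest["derived"] = extra
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
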