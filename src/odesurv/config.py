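"""Run configuration schema, dataset I/O, and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .likelihood import PriorSpec, SurvivalDataset
from .mapping import PredictorSpec

__all__ = ["RunConfig", "load_config", "read_dataset", "write_manifest"]


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    system: str = "hazard_response"
    formulas: list[str] = Field(default_factory=list)
    free_initials: list[str] = Field(default_factory=list)
    fixed: dict[str, float] = Field(default_factory=dict)


class PriorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    intercept_variance: float = 10.0
    coef_mode: str = "iid"
    coef_variance: float = 10.0
    g: dict[str, float] = Field(default_factory=dict)
    h0_gamma: tuple[float, float] | None = None
    complexity_C: float = 0.0


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: str = "batched"
    step: float = 0.01
    rtol: float = 1e-6
    atol: float = 1e-9


class InferenceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_draws: int = 1000
    mcmc_iter: int = 55000
    burn_in: int = 5000
    thin: int = 50


class RunConfig(BaseModel):
    """Validated configuration of a fitting / selection run."""

    model_config = ConfigDict(extra="forbid")
    model: ModelConfig = ModelConfig()
    priors: PriorConfig = PriorConfig()
    solver: SolverConfig = SolverConfig()
    inference: InferenceConfig = InferenceConfig()
    seed: int = 0
    time_col: str = "time"
    status_col: str = "status"

    def predictor_spec(self) -> PredictorSpec:
        return PredictorSpec.from_formulas(
            self.model.system, self.model.formulas,
            free_initials=tuple(self.model.free_initials), fixed=self.model.fixed,
        )

    def prior_spec(self) -> PriorSpec:
        return PriorSpec(
            intercept_variance=self.priors.intercept_variance,
            coef_mode=self.priors.coef_mode,
            coef_variance=self.priors.coef_variance,
            g=self.priors.g,
            h0_gamma=self.priors.h0_gamma,
            complexity_C=self.priors.complexity_C,
        )

    def solver_opts(self) -> dict:
        return self.solver.model_dump()


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration (unknown keys rejected)."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    return RunConfig.model_validate(raw)


def read_dataset(
    path, time_col: str = "time", status_col: str = "status", covariate_cols=None,
) -> SurvivalDataset:
    """Read a delimited survival dataset with row-level validation.

    Rows with missing values, nonpositive times, or non-binary status are
    rejected with their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path)
    for col in (time_col, status_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    cols = list(covariate_cols) if covariate_cols is not None else [
        c for c in df.columns if c not in (time_col, status_col)
    ]
    sub = df[[time_col, status_col] + cols]
    def lines(mask):
        return [int(i) + 2 for i in np.flatnonzero(mask.to_numpy())]
    na = sub.isna().any(axis=1)
    if na.any():
        raise ValueError(f"missing values at lines {lines(na)}")
    t = pd.to_numeric(df[time_col], errors="coerce")
    bad_t = ~np.isfinite(t) | (t <= 0)
    if bad_t.any():
        raise ValueError(f"nonpositive or non-numeric times at lines {lines(bad_t)}")
    status = pd.to_numeric(df[status_col], errors="coerce")
    bad_s = ~status.isin([0, 1])
    if bad_s.any():
        raise ValueError(f"non-binary status at lines {lines(bad_s)}")
    return SurvivalDataset(t.to_numpy(), status.to_numpy().astype(int), df[cols].copy())


def write_manifest(out_dir, config: dict, seed: int, outputs=None) -> Path:
    """Write a JSON manifest (config hash, seed, package version, outputs)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    canon = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
        "outputs": list(outputs or []),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
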