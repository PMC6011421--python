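"""YAML run-configuration with strict validation (unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .exceptions import ConfigurationError

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    dimension: int = 1
    length_cm: float = Field(3.0, gt=0)
    density: float = Field(80.0, gt=0)
    z0: float = Field(0.02, gt=0)
    decimation: int = Field(1, ge=1)


class PhysicsConfig(_Strict):
    c: float = 1.0
    a: float | None = None
    sigma_i: float | None = None
    sigma_e: float | None = None


class SourceConfig(_Strict):
    kind: str = "ap"                      # {"ap", "delta", "random"}
    baseline: float = 0.0
    amplitude: float = 100.0
    upstroke_center: float = -0.5
    upstroke_width: float = Field(0.02, gt=0)
    repol_center: float = 0.5
    repol_width: float = Field(0.15, gt=0)
    mode: str = "radial"                  # 2-D only
    position: list[float] = [0.0]         # delta only


class NoiseConfig(_Strict):
    target: str = "observation"
    level_db: float = Field(default=np.inf, ge=0)
    mode: str = "generator"
    seed: int = 0


class MethodsConfig(_Strict):
    ids: list[str] = ["fot", "ftsvd", "ftv", "dsmsvr"]
    nu: float = 0.5
    C: float = 1.0
    gamma_dl: float = 0.0
    b_mode: str | float = "kkt"
    rescale_measure: bool = True

    @field_validator("nu")
    @classmethod
    def _nu_open_interval(cls, v):
        if not (0.0 < v < 1.0):
            raise ValueError("nu must be in (0, 1)")
        return v

    @field_validator("C")
    @classmethod
    def _c_positive(cls, v):
        if not v > 0:
            raise ValueError("C must be positive")
        return v


class TuningConfig(_Strict):
    tuner: str = "lcurve"                 # {"lcurve", "loo", "grid"}
    num_candidates: int = Field(15, ge=5)
    folds: int | None = 24
    shrink: float = Field(0.5, gt=0, lt=1)
    max_iter: int = Field(10, ge=1)
    tol: float = Field(1e-3, gt=0)


class ExperimentConfig(_Strict):
    levels_db: list[float] = [0, 10, 20, 30, 40, 50, 60, 70]
    reps: int = Field(20, ge=1)
    seed: int = 0


class RunConfig(_Strict):
    grid: GridConfig = GridConfig()
    physics: PhysicsConfig = PhysicsConfig()
    source: SourceConfig = SourceConfig()
    noise: NoiseConfig = NoiseConfig()
    methods: MethodsConfig = MethodsConfig()
    tuning: TuningConfig = TuningConfig()
    experiment: ExperimentConfig = ExperimentConfig()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; defaults are filled in."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigurationError(f"invalid configuration: {details}") from exc


def dump_config(config: RunConfig, path) -> None:
    """Write a configuration back to YAML (round-trips with load_config)."""
    data = config.model_dump()
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
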