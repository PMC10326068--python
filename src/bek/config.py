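"""Validated run configuration and JSON I/O."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .model import RateSet
from .states import BarbedState

__all__ = ["RunConfig", "CohortConfig", "ObservationConfig", "AnalysisConfig",
           "load_config", "save_config", "config_hash", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unreadable run configuration."""


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_filaments: int = Field(default=500, ge=0)
    window: float = Field(default=500.0, gt=0)
    initial_state: BarbedState = BarbedState.BFC


class ObservationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    frame_interval: float = Field(default=0.2, gt=0)
    noise_sd: float = Field(default=0.0, ge=0)
    bleach_rate: float = Field(default=0.0, ge=0)
    n_traces: int = Field(default=16, ge=0)
    channels: list[str] = Field(default_factory=lambda: ["twinfilin", "length"])


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bootstrap_reps: int = Field(default=1000, ge=2)
    ci_level: float = Field(default=0.65, gt=0, lt=1)
    threshold: float | str = "auto"
    # survival curves are fitted on a regular grid at this spacing
    # (None = evaluate at event times)
    fit_grid_dt: float | None = Field(default=5.0)


class RunConfig(BaseModel):
    """Everything needed for one reproducible simulate-fit-dwell run."""

    model_config = ConfigDict(extra="forbid")

    rates: RateSet = Field(default_factory=RateSet)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    observation: ObservationConfig = Field(default_factory=ObservationConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    seed: int
    output_dir: str = "results/run"


def load_config(path) -> RunConfig:
    """Read and validate a JSON run configuration.

    Unknown keys are rejected; validation errors name the offending field.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(payload)
    except ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {problems}") from exc


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(config.model_dump_json(indent=2))


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 of the canonical JSON form (provenance tag)."""
    canon = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
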