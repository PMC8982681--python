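"""Run configuration: a single structured YAML file with validated defaults.

An empty file (or no file) yields the all-defaults configuration matching the
study conditions: 7 m path with a 5 m mat zone, three round trips, 2 s
turnaround dwells, 0.5 m/s2 acceleration ramps, ten participants at pace
targets of 1.0 m/s (normal) and 0.6 m/s (slow).  Unknown keys are rejected
with an error naming the offending key.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .estimators import STFTConfig
from .sensors import CWRadarConfig, GaitRiteConfig, MocapConfig, ThermalConfig, UWBConfig
from .walker import WalkProtocol

__all__ = ["PaceSpec", "RunConfig", "ConfigError", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    """Configuration file failed validation."""


class PaceSpec(BaseModel):
    """One pace condition: label, target speed and between-participant SD."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    label: str
    target_speed: float = Field(gt=0)
    speed_sd: float = Field(ge=0)


def _default_paces() -> list[PaceSpec]:
    return [
        PaceSpec(label="normal", target_speed=1.0, speed_sd=0.12),
        PaceSpec(label="slow", target_speed=0.6, speed_sd=0.08),
    ]


class RunConfig(BaseModel):
    """Full experiment manifest: protocol, sensors, analysis and run block."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    protocol: WalkProtocol = Field(default_factory=WalkProtocol)
    profile_accel: float = Field(default=0.5, gt=0)
    master_sample_rate: float = Field(default=1000.0, gt=0)
    cw: CWRadarConfig = Field(default_factory=CWRadarConfig)
    uwb: UWBConfig = Field(default_factory=UWBConfig)
    thermal: ThermalConfig = Field(default_factory=ThermalConfig)
    mocap: MocapConfig = Field(default_factory=MocapConfig)
    gaitrite: GaitRiteConfig = Field(default_factory=GaitRiteConfig)
    stft: STFTConfig = Field(default_factory=STFTConfig)
    doppler_factor: float = Field(default=2.0, gt=0)
    uwb_track_threshold: float = Field(default=0.01, gt=0)
    n_participants: int = Field(default=10, ge=1)
    paces: list[PaceSpec] = Field(default_factory=_default_paces)
    modes: list[str] = Field(default_factory=lambda: ["primary", "secondary"])
    master_seed: int = Field(default=1234, ge=0)
    output_dir: str = "results"


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``None`` or an empty file yields the all-defaults configuration.

    Raises
    ------
    ConfigError
        On schema violations, naming the offending key (e.g. ``cw.f0``).
    """
    data = {}
    if path is not None:
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"top level of {path} must be a mapping")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the configuration as YAML; load(save(cfg)) round-trips."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the full configuration, for output provenance."""
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
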