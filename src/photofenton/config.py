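"""Validated run configuration (YAML) shared by all CLI commands.

A single plain-text dialect: geometry, radiation data paths, kinetic
parameters with their fixed set, design path, noise levels, seed and output
directory. Unknown keys are rejected; omitted blocks fall back to the bench
defaults (device geometry, fitted rate constants, instrument noise).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .kinetics import KineticParams, default_params
from .radiation import ReactorGeometry
from .synthetic import NoiseModel

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    """Configuration schema violation, naming the offending key."""


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    r_int: float = 3.5
    r_ext: float = 7.0
    h_irr: float = 13.0
    lamp_length: float = 58.98
    lamp_offset: Optional[float] = None
    v_irr: float = 1.5
    v_total: float = 15.0

    def build(self) -> ReactorGeometry:
        return ReactorGeometry(**self.model_dump())


class ParamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k1: float = 147.29
    k3: float = 3.16
    k4: float = 7.00e7
    k5: float = 3.58e9
    phi_bar: float = default_params().phi_bar
    fixed: list[str] = Field(default_factory=lambda: ["k4"])

    @field_validator("k1", "k3", "k4", "k5", "phi_bar")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    def build(self) -> KineticParams:
        return KineticParams(
            k1=self.k1, k3=self.k3, k4=self.k4, k5=self.k5, phi_bar=self.phi_bar
        )


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pct: float = 0.15
    h2o2: float = 1.43
    fe: float = 0.05
    toc: float = 0.23

    @field_validator("pct", "h2o2", "fe", "toc")
    @classmethod
    def _non_negative(cls, v: float, info) -> float:
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v

    def build(self) -> NoiseModel:
        return NoiseModel(pct=self.pct, h2o2=self.h2o2, fe=self.fe, toc=self.toc)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    spectrum: Optional[str] = None  # CSV path; None -> synthetic spectrum
    absorptivity: Optional[str] = None  # CSV path; None -> synthetic table
    params: ParamsConfig = Field(default_factory=ParamsConfig)
    design: Optional[str] = None  # CSV path; None -> canonical 18-run design
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    seed: Optional[int] = None
    outdir: str = "out"
    verbosity: int = 1

    def require_seed(self) -> int:
        if self.seed is None:
            raise ConfigError("seed: required for stochastic commands")
        return self.seed


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; missing blocks get bench defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        key = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"{key}: {first['msg']}") from exc
    for name in ("spectrum", "absorptivity", "design"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{name}: path {p!r} does not exist")
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration, for artifact manifests."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
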