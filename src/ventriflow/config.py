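"""Run configuration: YAML in, validated model, lossless round-trip."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .errors import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_Strict):
    lv: str = "healthy"            # {healthy, dilated}
    mv: str = "healthy"            # {healthy, P3like, P2like}
    severity: float = 0.0          # coaptation-defect amplitude in [0, 1]
    lv_n_theta: int = 48
    lv_n_s: int = 40
    mv_n_theta: int = 33
    mv_n_s: int = 13

    @field_validator("lv")
    @classmethod
    def _lv(cls, v):
        if v not in ("healthy", "dilated"):
            raise ValueError("lv preset must be 'healthy' or 'dilated'")
        return v

    @field_validator("mv")
    @classmethod
    def _mv(cls, v):
        if v not in ("healthy", "P3like", "P2like"):
            raise ValueError("mv preset must be healthy/P3like/P2like")
        return v

    @field_validator("severity")
    @classmethod
    def _sev(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        return v


class GridConfig(_Strict):
    nx: int = 32
    ny: int = 32
    nz: int = 48
    pad_xy: float = 0.45           # box margin around the LV (cm)
    pad_bottom: float = 0.6
    tube_height: float = 1.4       # tube surrogate length above the base (cm)
    z_mode: str = "wall_open"      # or "open_wall" (mirrored reading)

    @field_validator("nx", "ny", "nz")
    @classmethod
    def _pos(cls, v):
        if v <= 0:
            raise ValueError("grid counts must be positive")
        return v

    @field_validator("z_mode")
    @classmethod
    def _zm(cls, v):
        if v not in ("wall_open", "open_wall"):
            raise ValueError("z_mode must be wall_open or open_wall")
        return v


class TimeConfig(_Strict):
    cfl_max: float = 0.5
    dt_max: float = 2.0e-3         # s
    dt_fixed: float | None = None  # fixed step (bit-exact restarts)
    n_cycles: int = 1

    @field_validator("cfl_max", "dt_max")
    @classmethod
    def _pos(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @field_validator("n_cycles")
    @classmethod
    def _nn(cls, v):
        if v < 0:
            raise ValueError("n_cycles must be >= 0")
        return v


class PhysicsConfig(_Strict):
    nu: float = 0.04               # kinematic viscosity, cm^2/s
    kappa: float | None = None     # scalar diffusivity; defaults to nu
    period: float = 1.0            # heartbeat period, s

    @field_validator("nu", "period")
    @classmethod
    def _pos(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @field_validator("kappa")
    @classmethod
    def _nonneg(cls, v):
        if v is not None and v < 0:
            raise ValueError("kappa must be >= 0")
        return v


class OutputConfig(_Strict):
    directory: str = "runs/out"
    snapshot_every: int = 0        # VTK snapshot cadence in steps (0 = off)
    checkpoint_every: int = 0      # HDF5 checkpoint cadence (0 = off)
    series_csv: bool = True


class RunConfig(_Strict):
    geometry: GeometryConfig = GeometryConfig()
    grid: GridConfig = GridConfig()
    time: TimeConfig = TimeConfig()
    physics: PhysicsConfig = PhysicsConfig()
    output: OutputConfig = OutputConfig()
    seed: int = 0                  # reserved; the pipeline is deterministic

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def _config_from_dict(data: dict) -> RunConfig:
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        locs = "; ".join(".".join(str(p) for p in e["loc"]) + ": " + e["msg"]
                         for e in exc.errors())
        raise ConfigError(locs) from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file = defaults)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return _config_from_dict(data)


def apply_overrides(cfg: RunConfig, overrides: dict[str, str]) -> RunConfig:
    """Apply dotted-path overrides like ``geometry.severity=0.5``."""
    data = cfg.model_dump()
    for key, val in overrides.items():
        parts = key.split(".")
        node = data
        for p in parts[:-1]:
            if p not in node:
                raise ConfigError(f"unknown config section '{p}' in '{key}'")
            node = node[p]
        if parts[-1] not in node:
            raise ConfigError(f"unknown config key '{key}'")
        node[parts[-1]] = yaml.safe_load(val)
    return _config_from_dict(data)
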