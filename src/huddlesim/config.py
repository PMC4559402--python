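"""Simulation configuration: defaults, validation, YAML loading.

Defaults reproduce the standard study conditions: 12 pups of unit radius
in an arena of radius 10, 1000 thermometers per pup, 8000 recorded steps
after a 100-step temperature settle, dt = 0.05, v1 = 200, v2 = 0.3,
G = 6.32, T_p = 37 degC, sigma = 100, k1 = 1, k2 = 2.5 (= 2.5 * k1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .behaviour import KinematicParams, Variant
from .thermodynamics import ThermalParams

__all__ = ["SimConfig", "ConfigError", "load_config", "config_from_dict"]


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration input."""


@dataclass
class SimConfig:
    """Full specification of one simulation run."""

    variant: Variant = Variant.HOMEOTHERMOTAXIC
    n_pups: int = 12
    n_thermometers: int = 1000
    steps: int = 8000
    settle_steps: int = 100
    initial_body_temperature: float = 30.0
    pup_radius: float = 1.0
    arena_radius: float = 10.0
    boundary_enabled: bool = True
    seed: int = 0
    thermal: ThermalParams = field(default_factory=ThermalParams)
    kinematic: KinematicParams = field(default_factory=KinematicParams)

    def __post_init__(self) -> None:
        try:
            self.variant = Variant(self.variant)
        except ValueError:
            valid = ", ".join(v.value for v in Variant)
            raise ConfigError(
                f"unknown variant {self.variant!r}; valid variants are: {valid}"
            ) from None
        if self.n_pups < 1:
            raise ConfigError(f"n_pups must be >= 1, got {self.n_pups}")
        if self.steps < 0:
            raise ConfigError(f"steps must be >= 0, got {self.steps}")
        if self.settle_steps < 0:
            raise ConfigError(f"settle_steps must be >= 0, got {self.settle_steps}")
        if self.n_thermometers < 2 or self.n_thermometers % 2:
            raise ConfigError(
                f"n_thermometers must be even and >= 2, got {self.n_thermometers}"
            )
        if self.pup_radius <= 0:
            raise ConfigError("pup_radius must be positive")
        if self.arena_radius <= self.pup_radius:
            raise ConfigError("arena_radius must exceed pup_radius")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["variant"] = self.variant.value
        return d

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def _build(cls, section: str, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {section}: {sorted(unknown)}; valid keys: {sorted(known)}"
        )
    try:
        return cls(**data)
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(f"out-of-range value in {section}: {exc}") from exc


def config_from_dict(data: dict | None) -> SimConfig:
    """Build a validated SimConfig; unspecified fields take the defaults,
    unknown keys are rejected."""
    data = dict(data or {})
    thermal = data.pop("thermal", {})
    kinematic = data.pop("kinematic", {})
    if not isinstance(thermal, dict) or not isinstance(kinematic, dict):
        raise ConfigError("'thermal' and 'kinematic' must be mappings")
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) in config: {sorted(unknown)}; valid keys: {sorted(known)}"
        )
    data["thermal"] = _build(ThermalParams, "thermal", thermal)
    data["kinematic"] = _build(KinematicParams, "kinematic", kinematic)
    return _build(SimConfig, "config", data)


def load_config(path: str | Path) -> SimConfig:
    """Load a YAML config file mirroring SimConfig field names."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file must contain a mapping, got {type(data).__name__}")
    return config_from_dict(data)
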