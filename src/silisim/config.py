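"""Configuration file parsing and validation.

One human-editable dialect (YAML; JSON parses as a YAML subset) with a
strict schema: unknown keys are rejected by name, mode-required sections
have no silent defaults, and every numeric default equals the published
parameter value.  A config bundles the simulation settings with either an
embedded synthetic-environment recipe (``environment:``) or a reference to
an environment CSV (``environment_file:``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .envgen import EnvSpec
from .errors import ConfigError
from .growth import GrowthParams
from .sim import SimulationConfig
from .soil import AvailabilityParams, SoilState
from .uptake import UptakeParams


@dataclass(frozen=True)
class RunConfig:
    """A simulation config plus its environment source."""

    simulation: SimulationConfig
    env_spec: EnvSpec | None = None
    environment_file: str | None = None

    def __post_init__(self) -> None:
        if (self.env_spec is None) == (self.environment_file is None):
            raise ConfigError(
                "exactly one of 'environment' and 'environment_file' is required"
            )


def _require_mapping(obj: Any, context: str) -> dict:
    if obj is None:
        return {}
    if not isinstance(obj, Mapping):
        raise ConfigError(f"{context} must be a mapping, got {type(obj).__name__}")
    return dict(obj)


def _build(cls, raw: Mapping[str, Any], context: str, **extra):
    """Instantiate a parameter dataclass from a mapping, rejecting unknown keys."""
    raw = dict(raw)
    allowed = {f.name for f in fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}"
        )
    for key, value in raw.items():
        if isinstance(value, list):
            raw[key] = tuple(value)
    try:
        return cls(**raw, **extra)
    except TypeError as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    """Build a validated :class:`RunConfig` from a plain mapping."""
    data = _require_mapping(data, "config")
    allowed = {
        "mode",
        "si_water",
        "soil",
        "season_length",
        "dt",
        "mulch_offset",
        "growth",
        "uptake",
        "availability",
        "environment",
        "environment_file",
    }
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in config; allowed: {sorted(allowed)}"
        )
    if "mode" not in data:
        raise ConfigError("config requires 'mode' (soil or soilless)")

    growth = _build(GrowthParams, _require_mapping(data.get("growth"), "growth"), "growth")
    uptake_raw = _require_mapping(data.get("uptake"), "uptake")
    uptake_raw.setdefault("planting_density", growth.planting_density)
    if "organ_fractions" in uptake_raw:
        uptake_raw["organ_fractions"] = _require_mapping(
            uptake_raw["organ_fractions"], "uptake.organ_fractions"
        )
    uptake = _build(UptakeParams, uptake_raw, "uptake")
    availability = _build(
        AvailabilityParams,
        _require_mapping(data.get("availability"), "availability"),
        "availability",
    )

    soil = None
    if data.get("soil") is not None:
        soil = _build(SoilState, _require_mapping(data["soil"], "soil"), "soil")

    sim_kwargs: dict[str, Any] = {
        "mode": data["mode"],
        "soil": soil,
        "growth": growth,
        "uptake": uptake,
        "availability": availability,
    }
    for key in ("si_water", "season_length", "dt", "mulch_offset"):
        if key in data:
            sim_kwargs[key] = data[key]
    simulation = SimulationConfig(**sim_kwargs)

    env_spec = None
    if data.get("environment") is not None:
        env_raw = _require_mapping(data["environment"], "environment")
        env_raw.setdefault("dt", simulation.dt)
        env_spec = _build(EnvSpec, env_raw, "environment")
    return RunConfig(
        simulation=simulation,
        env_spec=env_spec,
        environment_file=data.get("environment_file"),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(data or {})


def config_to_dict(config: RunConfig) -> dict[str, Any]:
    """Round-trippable plain-dict form of a :class:`RunConfig`."""
    out = config.simulation.to_dict()
    if config.env_spec is not None:
        spec = config.env_spec
        out["environment"] = {
            f.name: getattr(spec, f.name) for f in fields(spec)
        }
    if config.environment_file is not None:
        out["environment_file"] = config.environment_file
    return out


def write_config(config: RunConfig, path: str | Path) -> None:
    """Serialize *config* so that ``load_config`` reproduces it."""
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
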