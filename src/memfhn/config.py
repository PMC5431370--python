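"""Configuration: one YAML document fully describing a simulation run.

A config resolves to a :class:`SimulationConfig` (model parameters, grid,
initial-condition recipe, forcing, sampling plan, seed, mode flags).  The
schema is strict: unknown keys are rejected with the offending field named,
and a resolved config round-trips losslessly through YAML.  A file may name
an experiment preset; explicit keys then override the preset's values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .forcing import ForcingSpec, NoisePatch, RadiationSource
from .media_grid import Band, GridSpec, InitialConditionRecipe, SamplingPlan
from .model_core import ModelParams

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
]


class ConfigError(ValueError):
    """Invalid or unparseable configuration, with the offending field named."""


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one run bit-for-bit."""

    params: ModelParams = field(default_factory=ModelParams)
    grid: GridSpec = field(default_factory=GridSpec)
    recipe: InitialConditionRecipe = field(default_factory=InitialConditionRecipe)
    forcing: ForcingSpec = field(default_factory=ForcingSpec)
    sampling: SamplingPlan = field(default_factory=SamplingPlan)
    seed: int = 0
    mode: str = "induction"

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return replace(self, **kwargs)

    def override(self, dotted: Mapping[str, Any]) -> "SimulationConfig":
        """Apply ``section.field`` overrides (e.g. ``{"params.k0": 0.9}``)."""
        cfg = self
        for key, value in dotted.items():
            head, _, tail = key.partition(".")
            if not tail:
                if head not in {"seed", "mode"}:
                    raise ConfigError(f"cannot override top-level key {head!r}")
                cfg = cfg.replace(**{head: value})
                continue
            section = getattr(cfg, head, None)
            if section is None or not is_dataclass(section):
                raise ConfigError(f"unknown config section {head!r} in {key!r}")
            if tail not in {f.name for f in fields(section)}:
                raise ConfigError(f"unknown field {tail!r} in section {head!r}")
            value = _convert_field(type(section), tail, value, key)
            cfg = cfg.replace(**{head: replace(section, **{tail: value})})
        return cfg


# --- dataclass <-> plain dict -------------------------------------------------

def _to_plain(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(x) for x in obj]
    return obj


def _build(cls: type, data: Any, where: str) -> Any:
    """Construct a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, Mapping):
        raise ConfigError(f"{where}: expected a mapping, got {type(data).__name__}")
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ConfigError(f"{where}: unknown field(s) {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, value in data.items():
        kwargs[name] = _convert_field(cls, name, value, f"{where}.{name}")
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _convert_field(cls: type, name: str, value: Any, where: str) -> Any:
    if cls is SimulationConfig:
        sub = {
            "params": ModelParams,
            "grid": GridSpec,
            "recipe": InitialConditionRecipe,
            "forcing": ForcingSpec,
            "sampling": SamplingPlan,
        }.get(name)
        if sub is not None:
            return _build(sub, value, where)
    if cls is InitialConditionRecipe:
        if name == "bands":
            return tuple(
                b if isinstance(b, Band) else _build_band(b, f"{where}[{i}]")
                for i, b in enumerate(value)
            )
        if name in ("background", "constant"):
            return _triple(value, where)
    if cls is ForcingSpec:
        if name == "radiation":
            return tuple(
                s if isinstance(s, RadiationSource)
                else _build(RadiationSource, s, f"{where}[{i}]")
                for i, s in enumerate(value)
            )
        if name == "noise":
            return tuple(
                s if isinstance(s, NoisePatch)
                else _build(NoisePatch, s, f"{where}[{i}]")
                for i, s in enumerate(value)
            )
    if cls is SamplingPlan:
        if name == "snapshot_times":
            return tuple(float(t) for t in value)
        if name == "nodes":
            return tuple(_node(n, f"{where}[{i}]") for i, n in enumerate(value))
    return value


def _build_band(data: Any, where: str) -> Band:
    band = _build(Band, data, where)
    return replace(band, rows=tuple(band.rows), cols=tuple(band.cols))


def _triple(value: Any, where: str) -> tuple[float, float, float]:
    seq = tuple(float(x) for x in value)
    if len(seq) != 3:
        raise ConfigError(f"{where}: expected 3 values (u, v, phi), got {len(seq)}")
    return seq


def _node(value: Any, where: str) -> tuple[int, int]:
    seq = tuple(int(x) for x in value)
    if len(seq) != 2:
        raise ConfigError(f"{where}: expected (row, col), got {value!r}")
    return seq


def config_to_dict(cfg: SimulationConfig) -> dict:
    return _to_plain(cfg)


def config_from_dict(data: Mapping[str, Any]) -> SimulationConfig:
    """Resolve a plain mapping (e.g. parsed YAML) into a SimulationConfig.

    Supports an optional top-level ``preset`` key naming an experiment
    preset whose config supplies the defaults; other keys override it
    section-wise (field-level merge within each section).
    """
    if not isinstance(data, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    data = dict(data)
    preset_name = data.pop("preset", None)
    if preset_name is None:
        return _build(SimulationConfig, data, "config")
    from .presets import get_preset  # local import to avoid a cycle

    base = get_preset(preset_name).config
    base_dict = config_to_dict(base)
    for key, value in data.items():
        if key not in base_dict:
            raise ConfigError(f"config: unknown field(s) ['{key}']")
        if isinstance(value, Mapping) and isinstance(base_dict[key], dict):
            merged = dict(base_dict[key])
            merged.update(value)
            base_dict[key] = merged
        else:
            base_dict[key] = value
    return _build(SimulationConfig, base_dict, "config")


def load_config(path: str | Path) -> SimulationConfig:
    """Parse and validate a YAML config file; all defaults resolved."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        data = {}
    return config_from_dict(data)


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    """Write the fully resolved config as YAML (round-trips losslessly)."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
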