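"""Layered TOML configuration for the pipeline.

Every module parameter lives in a section mirroring the module name.
Unknown keys are rejected and values are type-checked at load time;
precedence is CLI flag > config file > built-in default.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .sim import SimConfig


class ConfigError(ValueError):
    """Invalid configuration file or value."""


@dataclass(frozen=True)
class DiscoveryConfig:
    min_clip: int = 10
    max_clip: int = 50
    min_support: int = 2
    min_fraction: float = 0.8
    max_mismatch: int = 1
    sm_motif: str = "AATTTT"
    window: int = 120
    min_hairpin_pairs: int = 8


@dataclass(frozen=True)
class ReadsConfig:
    min_overlap: int = 8
    max_mismatch_per_10: int = 1
    min_a: int = 8
    min_len: int = 20


@dataclass(frozen=True)
class PeaksConfig:
    min_count: int = 3
    merge_dist: int = 5


@dataclass(frozen=True)
class RefineConfig:
    promote_window: int = 50
    min_internal_offset: int = 200
    min_gene_len: int = 50
    min_aa: int = 100


@dataclass(frozen=True)
class UtilsConfig:
    min_coverage: float = 0.9
    min_repeat: int = 100


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    reads: ReadsConfig = field(default_factory=ReadsConfig)
    peaks: PeaksConfig = field(default_factory=PeaksConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    utils: UtilsConfig = field(default_factory=UtilsConfig)


_SECTIONS = {
    "sim": SimConfig,
    "discovery": DiscoveryConfig,
    "reads": ReadsConfig,
    "peaks": PeaksConfig,
    "refine": RefineConfig,
    "utils": UtilsConfig,
}


def _coerce(value, annotation, key: str):
    # tuple ranges arrive from TOML as lists
    if annotation.startswith("tuple") and isinstance(value, (list, tuple)):
        return tuple(value)
    if annotation == "float" and isinstance(value, int) and not isinstance(value, bool):
        return float(value)
    return value


def _build_section(cls, data: dict, section: str):
    valid = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(f"unknown key [{section}].{key}")
        ann = str(valid[key].type)
        value = _coerce(value, ann, key)
        expected: tuple[type, ...] | None = None
        if ann == "int":
            expected = (int,)
        elif ann == "float":
            expected = (int, float)
        elif ann == "str":
            expected = (str,)
        elif ann.startswith("tuple"):
            expected = (tuple,)
        if expected is not None and (
            not isinstance(value, expected) or isinstance(value, bool)
        ):
            raise ConfigError(
                f"[{section}].{key}: expected {ann}, got {type(value).__name__}"
            )
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"[{section}]: {exc}") from exc


def config_from_dict(data: dict) -> PipelineConfig:
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section(s): {', '.join(sorted(unknown))}")
    sections = {
        name: _build_section(cls, data.get(name, {}), name)
        for name, cls in _SECTIONS.items()
    }
    return PipelineConfig(**sections)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a TOML config file; None gives the built-in defaults."""
    if path is None:
        return PipelineConfig()
    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    return config_from_dict(data)


def with_seed(config: PipelineConfig, seed: int) -> PipelineConfig:
    """Return a copy of the config with the simulation seed replaced."""
    return dataclasses.replace(
        config, sim=dataclasses.replace(config.sim, seed=seed)
    )
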