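"""Run configuration: YAML round trip, validation, defaults, hashing."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .graph import LymphGraph, build_default_graph
from .hmm import ObservationModel, TimeConfig
from .inference import SamplerConfig

__all__ = ["RunConfig", "load_config", "save_config", "config_hash", "setup_logging"]


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration values."""


_SCHEMA = {
    "graph": {"levels", "arcs"},
    "observation": {"sensitivity", "specificity"},
    "time": {"t_max", "p_early"},
    "sampler": {"walkers", "steps", "burn_in", "thin"},
    "seed": None,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for the whole pipeline."""

    graph: dict = field(
        default_factory=lambda: {
            "levels": ["I", "II", "III", "IV"],
            "arcs": [["I", "II"], ["II", "III"], ["III", "IV"]],
        }
    )
    observation: dict = field(
        default_factory=lambda: {"sensitivity": 0.81, "specificity": 0.63}
    )
    time: dict = field(default_factory=lambda: {"t_max": 10, "p_early": 0.3})
    sampler: dict = field(
        default_factory=lambda: {
            "walkers": None,
            "steps": 10_000,
            "burn_in": 2_000,
            "thin": 1,
        }
    )
    seed: int = 0

    def build_graph(self) -> LymphGraph:
        levels = self.graph["levels"]
        arcs = self.graph.get("arcs", [])
        if levels == ["I", "II", "III", "IV"] and [list(a) for a in arcs] == [
            ["I", "II"],
            ["II", "III"],
            ["III", "IV"],
        ]:
            return build_default_graph()
        tumor_arcs = tuple((v, f"b{i + 1}") for i, v in enumerate(levels))
        level_arcs = tuple((r, s, f"t{r}{s}") for r, s in arcs)
        return LymphGraph(tuple(levels), tumor_arcs, level_arcs)

    def build_observation(self) -> ObservationModel:
        return ObservationModel(**self.observation)

    def build_time(self) -> TimeConfig:
        return TimeConfig(**self.time)

    def build_sampler(self) -> SamplerConfig:
        return SamplerConfig(**self.sampler)

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_section(name: str, data: dict, allowed: set) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{name}': {sorted(unknown)}")


def _validate_probability(section: str, key: str, value) -> None:
    if not isinstance(value, (int, float)) or not 0.0 <= float(value) <= 1.0:
        raise ConfigError(f"'{section}.{key}' must be a probability in [0, 1], got {value!r}")


def _validated(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    defaults = RunConfig()
    merged = {}
    for section, allowed in _SCHEMA.items():
        if section == "seed":
            continue
        base = dict(getattr(defaults, section))
        override = raw.get(section, {})
        if not isinstance(override, dict):
            raise ConfigError(f"'{section}' must be a mapping")
        _validate_section(section, override, allowed)
        base.update(override)
        merged[section] = base
    for key in ("sensitivity", "specificity"):
        _validate_probability("observation", key, merged["observation"][key])
    _validate_probability("time", "p_early", merged["time"]["p_early"])
    if merged["time"]["t_max"] < 1:
        raise ConfigError("'time.t_max' must be >= 1")
    for key in ("steps", "burn_in", "thin"):
        v = merged["sampler"][key]
        if not isinstance(v, int) or v < 0:
            raise ConfigError(f"'sampler.{key}' must be a non-negative integer")
    seed = raw.get("seed", defaults.seed)
    if not isinstance(seed, int):
        raise ConfigError("'seed' must be an integer")
    cfg = RunConfig(seed=seed, **merged)
    # constructing the domain objects re-runs their own invariant checks
    cfg.build_graph()
    cfg.build_observation()
    cfg.build_time()
    cfg.build_sampler()
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; defaults fill unspecified keys."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text(encoding="utf-8")) or {}
    return _validated(raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8"
    )


def config_hash(config: RunConfig) -> str:
    """Short stable hash identifying a configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def setup_logging(verbose: bool = False) -> None:
    """Structured logs to stderr; data outputs stay on stdout/files."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
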