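"""Configuration loading, presets, and run manifests.

Configs are YAML mappings mirroring :class:`~grnevol.evolution.EvolutionConfig`
with nested ``dev``, ``genome`` and ``fitness`` sections.  An empty file (or
no file) yields the standard study parameters: 200 traits, population 1000,
density 0.02, cue noise 0.05, mutation 0.005, selection strength 20, step
penalty 1/20, 40 selected traits, 200 generations per epoch, 40 preparatory
epochs, convergence tolerance 1e-5 within 200 developmental steps.

The ``desk`` preset scales the schedule down for interactive use:
population 200, 50 generations per epoch, 3 preparatory and 3 production
epochs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from typing import Any

import numpy as np
import yaml

from .development import DevConfig
from .evolution import EvolutionConfig, FitnessParams
from .genome import GenomeSpec

__all__ = [
    "load_config",
    "config_from_dict",
    "config_to_dict",
    "study_config",
    "desk_config",
    "ConfigError",
    "RunManifest",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration fields."""


_SECTIONS = {"dev": DevConfig, "genome": GenomeSpec, "fitness": FitnessParams}


def study_config(**overrides) -> EvolutionConfig:
    """Full-scale defaults: the standard study parameters."""
    return config_from_dict(overrides)


def desk_config(**overrides) -> EvolutionConfig:
    """Scaled-down preset: population 200, 50 generations/epoch,
    3 preparatory epochs, 3 production epochs."""
    base: dict[str, Any] = {
        "pop_size": 200,
        "generations_per_epoch": 50,
        "n_prep_epochs": 3,
        "n_epochs": 3,
    }
    base.update(overrides)
    return config_from_dict(base)


def _build(cls, data: dict, where: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(
            f"unknown {where} field(s): {', '.join(sorted(unknown))}; "
            f"valid fields: {', '.join(sorted(fields))}"
        )
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where} configuration: {exc}") from exc


def config_from_dict(data: dict | None) -> EvolutionConfig:
    data = dict(data or {})
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        section = data.pop(name, None)
        if section is not None:
            if isinstance(section, cls):
                kwargs[name] = section
            elif isinstance(section, dict):
                kwargs[name] = _build(cls, section, name)
            else:
                raise ConfigError(f"section {name!r} must be a mapping")
    kwargs.update(data)
    return _build(EvolutionConfig, kwargs, "experiment")


def load_config(path) -> EvolutionConfig:
    """Read an experiment configuration from YAML; empty file = defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def config_to_dict(cfg: EvolutionConfig) -> dict:
    return dataclasses.asdict(cfg)


@dataclasses.dataclass
class RunManifest:
    """Everything needed to re-run an invocation bit-identically."""

    command: str
    config: dict
    master_seed: int
    substream_seeds: dict
    code_version: str
    environment_fingerprints: list[str]
    outputs: list[str]
    created: str = ""

    @classmethod
    def create(cls, command: str, cfg: EvolutionConfig,
               environments=(), outputs=()) -> "RunManifest":
        from . import __version__

        ss = np.random.SeedSequence(cfg.seed)
        prep_ss, prod_ss = ss.spawn(2)
        return cls(
            command=command,
            config=config_to_dict(cfg),
            master_seed=cfg.seed,
            substream_seeds={
                "prep": list(map(int, prep_ss.generate_state(4))),
                "production": list(map(int, prod_ss.generate_state(4))),
            },
            code_version=__version__,
            environment_fingerprints=[fingerprint_environment(e)
                                      for e in environments],
            outputs=list(outputs),
            created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


def fingerprint_environment(env: np.ndarray) -> str:
    return hashlib.sha256(np.asarray(env, dtype=np.int8).tobytes()).hexdigest()[:16]
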