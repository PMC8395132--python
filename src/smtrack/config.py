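"""Nested pipeline configuration with validation and YAML round trip.

Every stage parameter has a default; unknown keys are rejected before any
computation starts, and the exact configuration that produced a run is
serialized next to its outputs. A single global seed deterministically
derives independent per-stage substreams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .link import LinkConfig
from .trajsim import ColocConfig, MovieConfig, SimulationConfig


@dataclass(frozen=True)
class SimulateSection:
    n_trajectories: int = 200
    # population composition by generating process
    fraction_brownian: float = 0.6
    fraction_switching: float = 0.25
    fraction_confined: float = 0.15
    traj: SimulationConfig = field(default_factory=lambda: SimulationConfig(n_steps=120))


@dataclass(frozen=True)
class LocalizeSection:
    k_sigma: float = 5.0
    roi_half_width: int = 3
    pixel_size: float = 0.1


@dataclass(frozen=True)
class ClassifySection:
    window: int = 15
    n_per_class: int = 4000
    hidden_units: int = 32


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "smtrack_run"
    dt: float = 0.1
    simulate: SimulateSection = field(default_factory=SimulateSection)
    movie: MovieConfig = field(default_factory=MovieConfig)
    localize: LocalizeSection = field(default_factory=LocalizeSection)
    link: LinkConfig = field(default_factory=LinkConfig)
    classify: ClassifySection = field(default_factory=ClassifySection)
    coloc: ColocConfig = field(default_factory=ColocConfig)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream seed derived from the global seed."""
        ss = np.random.SeedSequence((self.seed, abs(hash_stable(stage)) % (2**31)))
        return int(ss.generate_state(1)[0] % (2**31))


def hash_stable(s: str) -> int:
    """Process-independent string hash (FNV-1a, 32 bit)."""
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


def _from_dict(cls, data: dict, path: str = ""):
    if not dataclasses.is_dataclass(cls):
        return data
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} at '{path or 'root'}'")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        ftype = f.type if not isinstance(f.type, str) else None
        default = f.default_factory() if f.default_factory is not dataclasses.MISSING else f.default
        target = type(default) if dataclasses.is_dataclass(default) else None
        if target is not None and isinstance(value, dict):
            kwargs[key] = _from_dict(target, value, f"{path}.{key}" if path else key)
        elif key == "shape" and isinstance(value, (list, tuple)):
            kwargs[key] = tuple(value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return _from_dict(PipelineConfig, data)


def save_config(config: PipelineConfig, path) -> None:
    """Serialize the configuration (written next to every run's outputs)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(config), fh, sort_keys=False)
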