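"""Experiment configuration: defaults, validation, file loading.

Configs are plain YAML/JSON mappings. Model coefficients appear as top-level
keys (``alpha0: 0.5``); experiment-level keys control the run (``dimension``,
``N``, ``n_steps``, ``record_every``, ``seeds``, ``box_side``) and parameter
sweeps (``sweep: {alpha0: [0.1, 0.5], beta0: [0.01, 1]}``). Unknown keys are
rejected so that typos fail loudly.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Iterator

import yaml

from .errors import ConfigError
from .params import ModelParams

__all__ = ["ExperimentConfig", "load_config"]

_PARAM_KEYS = tuple(f.name for f in dc_fields(ModelParams))
_EXPERIMENT_KEYS = (
    "dimension", "N", "n_steps", "record_every", "seeds", "sweep", "box_side",
)


@dataclass
class ExperimentConfig:
    """A fully validated experiment description with defaults applied."""

    dimension: int = 2
    N: int = 10
    n_steps: int = 2000
    record_every: int = 10
    seeds: tuple[int, ...] = (0,)
    sweep: dict[str, tuple[float, ...]] = field(default_factory=dict)
    box_side: float | None = None
    params: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise ConfigError("dimension must be 2 or 3")
        if self.N < 1:
            raise ConfigError("N must be >= 1")
        if self.n_steps < 1:
            raise ConfigError("n_steps must be >= 1")
        if self.record_every < 1:
            raise ConfigError("record_every must be >= 1")
        self.seeds = tuple(int(s) for s in self.seeds)
        if not self.seeds:
            raise ConfigError("seeds must be non-empty")
        clean: dict[str, tuple[float, ...]] = {}
        for axis, values in dict(self.sweep).items():
            if axis not in _PARAM_KEYS:
                raise ConfigError(f"sweep axis '{axis}' is not a model parameter")
            vals = tuple(float(v) for v in values)
            if not vals:
                raise ConfigError(f"sweep axis '{axis}' has no values")
            clean[axis] = vals
        self.sweep = clean
        if self.box_side is not None and self.box_side <= 0:
            raise ConfigError("box_side must be > 0")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "ExperimentConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        known = set(_EXPERIMENT_KEYS) | set(_PARAM_KEYS)
        for key in raw:
            if key not in known:
                raise ConfigError(f"unknown config key '{key}'")
        param_kwargs = {k: raw[k] for k in _PARAM_KEYS if k in raw}
        try:
            params = ModelParams(**param_kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        exp_kwargs = {k: raw[k] for k in _EXPERIMENT_KEYS if k in raw}
        return cls(params=params, **exp_kwargs)

    def sweep_cells(self) -> Iterator[dict[str, float]]:
        """All parameter-override combinations of the sweep axes, in order."""
        if not self.sweep:
            yield {}
            return
        axes = list(self.sweep)
        for combo in itertools.product(*(self.sweep[a] for a in axes)):
            yield dict(zip(axes, combo))

    def planned_runs(self) -> list[tuple[dict[str, float], int]]:
        """(cell overrides, seed) for every planned simulation."""
        return [(cell, seed) for cell in self.sweep_cells() for seed in self.seeds]


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML (or JSON) experiment config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    return ExperimentConfig.from_dict(raw)
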