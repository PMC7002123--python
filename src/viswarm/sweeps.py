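"""Seeded experiment drivers: parameter sweeps summarized as CSV tables."""
from __future__ import annotations

import logging
import time as _time
from pathlib import Path

import pandas as pd

from .config import ExperimentConfig
from .errors import ConfigError, IntegrationError
from .metrics import SUMMARY_COLUMNS, summarize
from .model2d import init_swarm, run
from .model3d import init_swarm_3d, run_3d
from .trajectory import Trajectory

__all__ = ["run_cell", "phase_sweep_2d", "lambda_sweep_3d", "write_summary"]

log = logging.getLogger("viswarm.sweeps")


def run_cell(
    config: ExperimentConfig, overrides: dict[str, float], seed: int
) -> Trajectory:
    """Simulate one sweep cell standalone; rows of a full sweep match this."""
    params = config.params.replace(**overrides) if overrides else config.params
    if config.dimension == 2:
        swarm = init_swarm(config.N, params, seed, config.box_side)
        return run(swarm, config.n_steps, config.record_every, seed=seed)
    swarm = init_swarm_3d(config.N, params, seed, config.box_side)
    return run_3d(swarm, config.n_steps, config.record_every, seed=seed)


def _sweep(config: ExperimentConfig) -> pd.DataFrame:
    rows = []
    for overrides, seed in config.planned_runs():
        params = config.params.replace(**overrides) if overrides else config.params
        t0 = _time.perf_counter()
        try:
            traj = run_cell(config, overrides, seed)
            row = summarize(traj).as_row(params, config.N, seed)
            row["error"] = ""
        except IntegrationError as exc:
            row = {c: float("nan") for c in SUMMARY_COLUMNS}
            row.update(
                N=config.N, seed=seed,
                **{k: getattr(params, k) for k in
                   ("alpha0", "beta0", "alpha1", "beta1", "lambda0", "lambda1")},
            )
            row["error"] = str(exc)
            log.warning("cell %s seed %d failed: %s", overrides, seed, exc)
        log.info(
            "cell %s seed %d done in %.2fs", overrides, seed,
            _time.perf_counter() - t0,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS) + ["error"])


def phase_sweep_2d(config: ExperimentConfig) -> pd.DataFrame:
    """Sweep the (alpha0, beta0) response-strength plane of the 2D model.

    One summary row per (cell, seed); failed cells are recorded with NaN
    observables and an error message, and the sweep continues.
    """
    if config.dimension != 2:
        raise ConfigError("phase_sweep_2d needs a 2D config")
    missing = {"alpha0", "beta0"} - set(config.sweep)
    if missing:
        raise ConfigError(f"phase_sweep_2d needs sweep axes alpha0 and beta0; missing {sorted(missing)}")
    return _sweep(config)


def lambda_sweep_3d(config: ExperimentConfig) -> pd.DataFrame:
    """Sweep the vertical edge-attraction coefficient lambda1 in 3D."""
    if config.dimension != 3:
        raise ConfigError("lambda_sweep_3d needs a 3D config")
    if "lambda1" not in config.sweep:
        raise ConfigError("lambda_sweep_3d needs a sweep axis lambda1")
    return _sweep(config)


def write_summary(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path
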