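"""Trajectory persistence: long-format CSV with a JSON metadata header.

The first line of a trajectory file is ``# viswarm-trajectory <json>``
carrying the run metadata (model parameters, seed, dimension, recording
stride, state columns); the rest is an ordinary CSV with one row per
(time, agent). Floats are written with shortest-round-trip repr, so a
write/read cycle reproduces every state bit for bit.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .trajectory import COLUMNS_2D, COLUMNS_3D, Trajectory

__all__ = ["write_trajectory", "read_trajectory"]

_MAGIC = "# viswarm-trajectory "


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as header-block + long CSV; returns the path."""
    if traj.n_snapshots == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    t_count, n, f = traj.states.shape
    header = {
        "columns": list(traj.columns),
        "dim": traj.dim,
        "n_agents": n,
        **{k: v for k, v in traj.metadata.items() if k != "columns"},
    }
    with open(path, "w") as fh:
        fh.write(_MAGIC + json.dumps(header, sort_keys=True) + "\n")
        fh.write("time,agent_id," + ",".join(traj.columns) + "\n")
        for ti in range(t_count):
            t_repr = repr(float(traj.times[ti]))
            for ai in range(n):
                vals = ",".join(repr(float(v)) for v in traj.states[ti, ai])
                fh.write(f"{t_repr},{ai},{vals}\n")
    return path


def read_trajectory(path: str | Path, expect_dim: int | None = None) -> Trajectory:
    """Read a trajectory file; optionally enforce the model dimension."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"trajectory file not found: {path}")
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_MAGIC):
            raise ConfigError(f"{path} is not a viswarm trajectory file")
        meta = json.loads(first[len(_MAGIC):])
        df = pd.read_csv(fh, float_precision="round_trip")
    columns = tuple(meta.pop("columns"))
    if columns not in (COLUMNS_2D, COLUMNS_3D):
        raise ConfigError(f"unrecognized state columns {columns}")
    dim = 2 if columns == COLUMNS_2D else 3
    if expect_dim is not None and expect_dim != dim:
        raise ConfigError(
            f"dimension mismatch: file {path} holds a {dim}D trajectory, "
            f"expected {expect_dim}D"
        )
    if df.empty:
        raise ValueError(f"trajectory file {path} holds no snapshots")
    df = df.sort_values(["time", "agent_id"], kind="stable")
    times = np.unique(df["time"].to_numpy())
    n = meta.pop("n_agents")
    if len(df) != len(times) * n:
        raise ConfigError(f"{path}: inconsistent snapshot shapes")
    states = df[list(columns)].to_numpy(float).reshape(len(times), n, len(columns))
    meta.pop("dim", None)
    return Trajectory(times, states, columns, meta)
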