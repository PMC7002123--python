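"""Time-indexed record of a simulated swarm."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

COLUMNS_2D = ("x", "y", "v", "psi")
COLUMNS_3D = ("x", "y", "z", "v_psi", "psi", "v_z")


@dataclass
class Trajectory:
    """Snapshots of all agent states at recorded times plus run metadata.

    ``states`` has shape (T, N, F) with F matching ``columns``
    (:data:`COLUMNS_2D` or :data:`COLUMNS_3D`); ``times`` is strictly
    increasing; ``metadata`` carries at least the model parameters, seed,
    model dimension and recording stride.
    """

    times: np.ndarray
    states: np.ndarray
    columns: tuple[str, ...]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.states.ndim != 3:
            raise ValueError("times must be 1D and states (T, N, F)")
        if len(self.times) != len(self.states):
            raise ValueError("times and states disagree on snapshot count")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape[2] != len(self.columns):
            raise ValueError("state width does not match columns")
        self.columns = tuple(self.columns)

    @property
    def dim(self) -> int:
        return 2 if self.columns == COLUMNS_2D else 3

    @property
    def n_agents(self) -> int:
        return self.states.shape[1]

    @property
    def n_snapshots(self) -> int:
        return self.states.shape[0]

    def column(self, name: str) -> np.ndarray:
        """(T, N) array of one state component across all snapshots."""
        return self.states[:, :, self.columns.index(name)]

    def positions(self, t_index: int) -> np.ndarray:
        """(N, dim) positions at one recorded snapshot."""
        return self.states[t_index, :, : (2 if self.dim == 2 else 3)]

    def window_indices(self, t_start: float, t_end: float) -> np.ndarray:
        """Indices of snapshots with t_start <= t <= t_end."""
        return np.flatnonzero((self.times >= t_start) & (self.times <= t_end))

    def second_half_window(self) -> tuple[float, float]:
        """Default post-transient analysis window: second half of the run."""
        t0, t1 = float(self.times[0]), float(self.times[-1])
        return (t0 + 0.5 * (t1 - t0), t1)
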