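"""Order parameters and diagnostics of simulated swarms.

The central observables are the polarization P = |mean unit velocity|
(1 for perfect alignment, ~1/sqrt(N) for random headings), nearest-neighbor
and minimum pairwise distances in BL (a minimum below 1 BL means bodies
overlap, i.e. a collision), the planar and vertical extents of the group,
and the instantaneous pair-response map (speed and turning response to a
single neighbor placed at a given front-back / left-right offset).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import MetricError
from .model2d import Swarm2D, visual_turn
from .model3d import Swarm3D
from .params import ModelParams
from .retina import (
    AgentState2D,
    field_edges,
    visual_field,
    weighted_area_integral,
    weighted_edge_sum,
)
from .trajectory import COLUMNS_2D, COLUMNS_3D, Trajectory

__all__ = [
    "RunSummary",
    "SUMMARY_COLUMNS",
    "polarization",
    "polarization_series",
    "nearest_neighbor_stats",
    "extents",
    "collision_flag",
    "neighbor_exchange_fraction",
    "neighbor_retention",
    "pair_response_map",
    "summarize",
]

SUMMARY_COLUMNS = (
    "N", "alpha0", "beta0", "alpha1", "beta1", "lambda0", "lambda1", "seed",
    "polarization", "mean_nnd", "min_dist", "extent_xy", "extent_z",
)


def _states_and_columns(snapshot) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(snapshot, Swarm2D):
        return snapshot.state_array(), COLUMNS_2D
    if isinstance(snapshot, Swarm3D):
        return snapshot.state_array(), COLUMNS_3D
    states, columns = snapshot
    return np.asarray(states, dtype=float), tuple(columns)


def _positions(states: np.ndarray, columns: tuple[str, ...]) -> np.ndarray:
    return states[:, : (3 if columns == COLUMNS_3D else 2)]


def _unit_velocities(states: np.ndarray, columns: tuple[str, ...]) -> np.ndarray:
    if columns == COLUMNS_2D:
        psi = states[:, columns.index("psi")]
        return np.stack([np.cos(psi), np.sin(psi)], axis=1)
    v_psi = states[:, columns.index("v_psi")]
    psi = states[:, columns.index("psi")]
    v_z = states[:, columns.index("v_z")]
    vel = np.stack([v_psi * np.cos(psi), v_psi * np.sin(psi), v_z], axis=1)
    speed = np.linalg.norm(vel, axis=1)
    out = np.zeros_like(vel)
    moving = speed > 0
    out[moving] = vel[moving] / speed[moving, None]
    return out


def polarization(snapshot) -> float:
    """|sum of unit velocity vectors| / N, in [0, 1].

    In 2D the unit vector is the heading; in 3D it is the normalized full
    velocity, so vertical motion degrades planar order. Agents with exactly
    zero velocity contribute a zero vector.
    """
    states, columns = _states_and_columns(snapshot)
    u = _unit_velocities(states, columns)
    return float(np.linalg.norm(np.sum(u, axis=0)) / len(u))


def polarization_series(traj: Trajectory, indices: Sequence[int] | None = None) -> np.ndarray:
    idx = range(traj.n_snapshots) if indices is None else indices
    return np.array([polarization((traj.states[t], traj.columns)) for t in idx])


def nearest_neighbor_stats(snapshot) -> tuple[float, float]:
    """(mean distance to closest other agent, global minimum pairwise distance)."""
    states, columns = _states_and_columns(snapshot)
    pos = _positions(states, columns)
    if len(pos) < 2:
        raise MetricError("nearest-neighbor statistics need at least 2 agents")
    dists = pdist(pos)
    n = len(pos)
    dm = np.full((n, n), np.inf)
    iu = np.triu_indices(n, 1)
    dm[iu] = dists
    dm.T[iu] = dists
    return float(np.mean(np.min(dm, axis=1))), float(np.min(dists))


def extents(snapshot) -> tuple[float, float]:
    """(max pairwise distance in the xy projection, max z - min z)."""
    states, columns = _states_and_columns(snapshot)
    pos = _positions(states, columns)
    if len(pos) < 2:
        raise MetricError("extents need at least 2 agents")
    extent_xy = float(np.max(pdist(pos[:, :2])))
    extent_z = float(np.ptp(pos[:, 2])) if pos.shape[1] == 3 else 0.0
    return extent_xy, extent_z


def _window_indices(traj: Trajectory, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        window = traj.second_half_window()
    idx = traj.window_indices(*window)
    if not len(idx):
        raise MetricError("analysis window contains no recorded snapshots")
    return idx


def collision_flag(
    traj: Trajectory, window: tuple[float, float] | None = None, BL: float | None = None
) -> bool:
    """True iff the minimum pairwise distance drops below BL in the window."""
    if traj.n_agents < 2:
        return False
    if BL is None:
        BL = traj.metadata.get("params", {}).get("BL", 1.0)
    for t in _window_indices(traj, window):
        pos = _positions(traj.states[t], traj.columns)
        if float(np.min(pdist(pos))) < BL:
            return True
    return False


def neighbor_exchange_fraction(
    traj: Trajectory, window: tuple[float, float] | None = None
) -> float:
    """Average fraction of agents whose nearest neighbor changes identity.

    Computed between consecutive recorded snapshots in the window; near 0
    for crystal-like groups with locked relative positions, order 1 for
    fluid swarms with ongoing neighbor exchange.
    """
    if traj.n_agents < 2:
        raise MetricError("neighbor exchange needs at least 2 agents")
    idx = _window_indices(traj, window)
    if len(idx) < 2:
        raise MetricError("neighbor exchange needs at least 2 snapshots in the window")
    n = traj.n_agents
    eye = np.eye(n, dtype=bool)

    def nn_ids(t: int) -> np.ndarray:
        pos = _positions(traj.states[t], traj.columns)
        dm = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        dm[eye] = np.inf
        return np.argmin(dm, axis=1)

    prev = nn_ids(idx[0])
    changed = []
    for t in idx[1:]:
        cur = nn_ids(t)
        changed.append(np.mean(cur != prev))
        prev = cur
    return float(np.mean(changed))


def neighbor_retention(
    traj: Trajectory, window: tuple[float, float] | None = None, k: int = 3
) -> float:
    """Fraction of each agent's k nearest neighbors retained across the window.

    Compares the k-nearest-neighbor sets at the first and last snapshots of
    the window and averages the overlap fraction over agents: near 1 for
    groups whose relative arrangement is locked, near the random-overlap
    level k/(N-1) for fluid groups.
    """
    if traj.n_agents < k + 1:
        raise MetricError(f"neighbor retention with k={k} needs at least {k + 1} agents")
    idx = _window_indices(traj, window)
    if len(idx) < 2:
        raise MetricError("neighbor retention needs at least 2 snapshots in the window")

    def knn(t: int) -> np.ndarray:
        pos = _positions(traj.states[t], traj.columns)
        dm = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        np.fill_diagonal(dm, np.inf)
        return np.argsort(dm, axis=1)[:, :k]

    first, last = knn(idx[0]), knn(idx[-1])
    overlaps = [
        len(set(first[i]) & set(last[i])) / k for i in range(traj.n_agents)
    ]
    return float(np.mean(overlaps))


def pair_response_map(
    params: ModelParams,
    d_fb: Sequence[float],
    d_lr: Sequence[float],
) -> pd.DataFrame:
    """Instantaneous visual response to a single neighbor on an offset grid.

    The focal agent sits at the origin heading +x; the neighbor is placed at
    front-back offset d_FB (along the heading) and left-right offset d_LR
    (positive = left). Columns: d_fb, d_lr, dv (speed response, relaxation
    excluded), dpsi (turning response). Short-range the subtended angle
    dominates (dv < 0 ahead: repulsion); far away the edge term dominates
    (dv > 0 ahead: attraction); the dv zero-crossing along d_lr = 0 is the
    pair equilibrium distance.
    """
    focal = AgentState2D(0.0, 0.0, params.v0, 0.0)
    rows = []
    for fb in d_fb:
        for lr in d_lr:
            if fb == 0.0 and lr == 0.0:
                rows.append((fb, lr, np.nan, np.nan))
                continue
            neighbor = AgentState2D(float(fb), float(lr), params.v0, 0.0)
            fld = visual_field(focal, [neighbor], params.BL)
            edges = field_edges(fld)
            dv = params.alpha0 * (
                -weighted_area_integral(fld, "cos")
                + params.alpha1 * weighted_edge_sum(edges, "cos")
            )
            dpsi = visual_turn(focal, fld, params)
            rows.append((fb, lr, dv, dpsi))
    return pd.DataFrame(rows, columns=["d_fb", "d_lr", "dv", "dpsi"])


@dataclass
class RunSummary:
    """Steady-state observables of one run over a post-transient window."""

    polarization: float
    polarization_series: np.ndarray
    mean_nnd: float
    min_pairwise_distance: float
    extent_xy: float
    extent_z: float
    window: tuple[float, float]

    def as_row(
        self, params: ModelParams, N: int, seed: int | None
    ) -> dict[str, float]:
        """One CSV row with the fixed summary column set."""
        return {
            "N": N,
            "alpha0": params.alpha0,
            "beta0": params.beta0,
            "alpha1": params.alpha1,
            "beta1": params.beta1,
            "lambda0": params.lambda0,
            "lambda1": params.lambda1,
            "seed": seed if seed is not None else -1,
            "polarization": self.polarization,
            "mean_nnd": self.mean_nnd,
            "min_dist": self.min_pairwise_distance,
            "extent_xy": self.extent_xy,
            "extent_z": self.extent_z,
        }


def summarize(traj: Trajectory, window: tuple[float, float] | None = None) -> RunSummary:
    """Aggregate a trajectory over a window (default: second half of the run).

    Polarization, mean nearest-neighbor distance and extents are time
    averages of instantaneous values; the minimum pairwise distance is the
    minimum over the whole window.
    """
    if window is None:
        window = traj.second_half_window()
    idx = _window_indices(traj, window)
    pol = polarization_series(traj, idx)
    nnd, mins, exy, ez = [], [], [], []
    for t in idx:
        snap = (traj.states[t], traj.columns)
        m, mn = nearest_neighbor_stats(snap)
        nnd.append(m)
        mins.append(mn)
        xy, z = extents(snap)
        exy.append(xy)
        ez.append(z)
    return RunSummary(
        polarization=float(np.mean(pol)),
        polarization_series=pol,
        mean_nnd=float(np.mean(nnd)),
        min_pairwise_distance=float(np.min(mins)),
        extent_xy=float(np.mean(exy)),
        extent_z=float(np.mean(ez)),
        window=(float(window[0]), float(window[1])),
    )
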