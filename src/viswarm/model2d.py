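"""2D equations of motion driven by the binary visual projection field.

Each agent relaxes toward its preferred speed and responds to its visual
field through two functionals per degree of freedom:

    dv/dt   = gamma (v0 - v) + alpha0 (-A_cos + alpha1 E_cos)
    dpsi/dt =                  beta0  (-A_sin + beta1  E_sin)

where A_k is the kernel-weighted angular area of the occupied retina and
E_k the kernel sum over its edges (see :mod:`viswarm.retina`). The subtended
angle repels (short range, decays with distance) while the edges attract
(long range); their balance sets the equilibrium spacing BL/(2*alpha1).
Integration is synchronous explicit Euler: all fields are computed from the
pre-step states, then every agent is updated at once. Speed is signed and
never clamped; the heading is never flipped by a negative speed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, IntegrationError
from .params import ModelParams
from .retina import (
    AgentState2D,
    ArcSet,
    TWO_PI,
    _merge_circular,
    field_edges,
    weighted_area_integral,
    weighted_edge_sum,
    wrap_angle,
)
from .trajectory import COLUMNS_2D, Trajectory

__all__ = ["Swarm2D", "visual_accel", "visual_turn", "step", "init_swarm", "run"]

_FULL_TOL = 1e-12


@dataclass
class Swarm2D:
    """All agent states at one instant, stored as parallel arrays.

    Agent identity is the array index and is stable across steps.
    """

    x: np.ndarray
    y: np.ndarray
    v: np.ndarray
    psi: np.ndarray
    params: ModelParams
    time: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        self.psi = wrap_angle(np.atleast_1d(np.asarray(self.psi, dtype=float)))
        n = len(self.x)
        if n < 1:
            raise ValueError("a swarm needs at least one agent")
        if not (len(self.y) == len(self.v) == len(self.psi) == n):
            raise ValueError("state arrays must have equal length")

    @property
    def n(self) -> int:
        return len(self.x)

    def agent(self, i: int) -> AgentState2D:
        return AgentState2D(self.x[i], self.y[i], self.v[i], self.psi[i])

    @property
    def agents(self) -> list[AgentState2D]:
        return [self.agent(i) for i in range(self.n)]

    def state_array(self) -> np.ndarray:
        """(N, 4) array in :data:`viswarm.trajectory.COLUMNS_2D` order."""
        return np.stack([self.x, self.y, self.v, self.psi], axis=1)

    @classmethod
    def from_state_array(
        cls, states: np.ndarray, params: ModelParams, time: float = 0.0
    ) -> "Swarm2D":
        s = np.asarray(states, dtype=float)
        return cls(s[:, 0], s[:, 1], s[:, 2], s[:, 3], params, time)

    def copy(self) -> "Swarm2D":
        return Swarm2D(
            self.x.copy(), self.y.copy(), self.v.copy(), self.psi.copy(),
            self.params, self.time,
        )


def visual_accel(focal: AgentState2D, field: ArcSet, params: ModelParams) -> float:
    """Rate of change of the focal agent's speed given its visual field."""
    edges = field_edges(field)
    a_cos = weighted_area_integral(field, "cos")
    e_cos = weighted_edge_sum(edges, "cos")
    return params.gamma * (params.v0 - focal.v) + params.alpha0 * (
        -a_cos + params.alpha1 * e_cos
    )


def visual_turn(focal: AgentState2D, field: ArcSet, params: ModelParams) -> float:
    """Rate of change of the focal agent's heading given its visual field."""
    edges = field_edges(field)
    a_sin = weighted_area_integral(field, "sin")
    e_sin = weighted_edge_sum(edges, "sin")
    return params.beta0 * (-a_sin + params.beta1 * e_sin)


def _swarm_functionals_numpy(
    x: np.ndarray, y: np.ndarray, psi: np.ndarray, BL: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Visual functionals (A_cos, A_sin, E_cos, E_sin) for every agent.

    Equivalent to building each agent's :class:`~viswarm.retina.ArcSet` and
    evaluating the four functionals, but batched: pairwise geometry is
    computed once and the per-agent circular union is done with sorted
    interval merging. An agent with a saturated retina has all functionals
    zero (its social response vanishes).
    """
    n = len(x)
    a_cos = np.zeros(n)
    a_sin = np.zeros(n)
    e_cos = np.zeros(n)
    e_sin = np.zeros(n)
    if n < 2:
        return a_cos, a_sin, e_cos, e_sin

    dx = x[None, :] - x[:, None]
    dy = y[None, :] - y[:, None]
    d = np.hypot(dx, dy)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0.0):
        i, j = np.argwhere((d == 0.0) & off)[0]
        raise DegenerateGeometryError(f"agents {i} and {j} are coincident")
    with np.errstate(divide="ignore"):
        half = np.arcsin(np.minimum(1.0, BL / (2.0 * d)))
    bearing = np.arctan2(dy, dx) - psi[:, None]

    for i in range(n):
        c = bearing[i][off[i]]
        w = half[i][off[i]]
        starts, ends = _merge_circular(c - w, c + w)
        if float(np.sum(ends - starts)) >= TWO_PI - _FULL_TOL:
            continue  # saturated vision: no social response
        a_cos[i] = np.sum(np.sin(ends) - np.sin(starts))
        a_sin[i] = np.sum(np.cos(starts) - np.cos(ends))
        e_cos[i] = np.sum(np.cos(starts)) + np.sum(np.cos(ends))
        e_sin[i] = np.sum(np.sin(starts)) + np.sum(np.sin(ends))
    return a_cos, a_sin, e_cos, e_sin


def _make_numba_kernel():
    """Compiled interval-union kernel; None if numba is unavailable."""
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional speedup
        return None

    @njit(cache=True, fastmath=False)
    def kernel(x, y, psi, BL):  # pragma: no cover - exercised via wrapper
        n = x.size
        two_pi = 2.0 * math.pi
        a_cos = np.zeros(n)
        a_sin = np.zeros(n)
        e_cos = np.zeros(n)
        e_sin = np.zeros(n)
        lo = np.empty(n - 1)
        ln = np.empty(n - 1)
        starts = np.empty(n - 1)
        ends = np.empty(n - 1)
        degenerate = -1
        for i in range(n):
            m = 0
            for j in range(n):
                if j == i:
                    continue
                dx = x[j] - x[i]
                dy = y[j] - y[i]
                d = math.hypot(dx, dy)
                if d == 0.0:
                    degenerate = i
                    return a_cos, a_sin, e_cos, e_sin, degenerate
                s = BL / (2.0 * d)
                if s > 1.0:
                    s = 1.0
                w = math.asin(s)
                b = math.atan2(dy, dx) - psi[i]
                lo[m] = (b - w) % two_pi
                ln[m] = 2.0 * w
                m += 1
            order = np.argsort(lo[:m])
            # linear merge of sorted intervals on [0, 3*pi)
            k = 0
            cur_s = lo[order[0]]
            cur_e = cur_s + ln[order[0]]
            for oi in range(1, m):
                s0 = lo[order[oi]]
                e0 = s0 + ln[order[oi]]
                if s0 > cur_e:
                    starts[k] = cur_s
                    ends[k] = cur_e
                    k += 1
                    cur_s = s0
                    cur_e = e0
                elif e0 > cur_e:
                    cur_e = e0
            starts[k] = cur_s
            ends[k] = cur_e
            k += 1
            # circular wrap: fold the last interval past 2*pi onto the front
            if ends[k - 1] > two_pi:
                s0 = starts[k - 1] - two_pi
                e0 = ends[k - 1] - two_pi
                k -= 1
                drop = 0
                while drop < k and starts[drop] <= e0:
                    if ends[drop] > e0:
                        e0 = ends[drop]
                    drop += 1
                kept = k - drop
                tmp_s = starts[drop:drop + kept].copy()
                tmp_e = ends[drop:drop + kept].copy()
                starts[0] = s0
                ends[0] = e0
                for t in range(kept):
                    starts[1 + t] = tmp_s[t]
                    ends[1 + t] = tmp_e[t]
                k = kept + 1
            total = 0.0
            for t in range(k):
                total += ends[t] - starts[t]
            if total >= two_pi - 1e-12:
                continue  # saturated vision
            for t in range(k):
                a_cos[i] += math.sin(ends[t]) - math.sin(starts[t])
                a_sin[i] += math.cos(starts[t]) - math.cos(ends[t])
                e_cos[i] += math.cos(starts[t]) + math.cos(ends[t])
                e_sin[i] += math.sin(starts[t]) + math.sin(ends[t])
        return a_cos, a_sin, e_cos, e_sin, degenerate

    return kernel


_NUMBA_KERNEL = _make_numba_kernel()
USE_NUMBA = _NUMBA_KERNEL is not None


def _swarm_functionals(
    x: np.ndarray, y: np.ndarray, psi: np.ndarray, BL: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Dispatch to the compiled kernel when available (same contract)."""
    if USE_NUMBA and len(x) >= 2:
        a_cos, a_sin, e_cos, e_sin, degenerate = _NUMBA_KERNEL(
            np.ascontiguousarray(x), np.ascontiguousarray(y),
            np.ascontiguousarray(psi), float(BL),
        )
        if degenerate >= 0:
            raise DegenerateGeometryError(
                f"agent {degenerate} coincides with another agent"
            )
        return a_cos, a_sin, e_cos, e_sin
    return _swarm_functionals_numpy(x, y, psi, BL)


def _check_finite(arr: np.ndarray, term: str, step_index: int | None) -> None:
    if not np.all(np.isfinite(arr)):
        agent = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise IntegrationError(agent=agent, term=term, step=step_index)


def step(swarm: Swarm2D, _step_index: int | None = None) -> Swarm2D:
    """One synchronous explicit-Euler update of the whole swarm."""
    p = swarm.params
    a_cos, a_sin, e_cos, e_sin = _swarm_functionals(
        swarm.x, swarm.y, swarm.psi, p.BL
    )
    dv = p.gamma * (p.v0 - swarm.v) + p.alpha0 * (-a_cos + p.alpha1 * e_cos)
    dpsi = p.beta0 * (-a_sin + p.beta1 * e_sin)
    _check_finite(dv, "speed", _step_index)
    _check_finite(dpsi, "heading", _step_index)

    v_new = swarm.v + p.dt * dv
    psi_new = wrap_angle(swarm.psi + p.dt * dpsi)
    x_new = swarm.x + p.dt * v_new * np.cos(psi_new)
    y_new = swarm.y + p.dt * v_new * np.sin(psi_new)
    _check_finite(x_new, "position", _step_index)
    _check_finite(y_new, "position", _step_index)
    return Swarm2D(x_new, y_new, v_new, psi_new, p, swarm.time + p.dt)


def init_swarm(
    N: int,
    params: ModelParams,
    seed: int,
    box_side: float | None = None,
) -> Swarm2D:
    """Random initial swarm: positions uniform in a square, headings uniform.

    The default box side is ceil(sqrt(N)) times the pair equilibrium distance
    BL/(2*alpha1), i.e. the swarm starts near its expected steady density
    (10 BL per agent row when alpha1 = 0). All speeds start at v0.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if box_side is None:
        l_eq = params.BL / (2.0 * params.alpha1) if params.alpha1 > 0 else 10.0 * params.BL
        box_side = math.ceil(math.sqrt(N)) * l_eq
    if box_side <= 0:
        raise ValueError("box_side must be > 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, box_side, size=N)
    y = rng.uniform(0.0, box_side, size=N)
    psi = rng.uniform(-math.pi, math.pi, size=N)
    v = np.full(N, params.v0)
    return Swarm2D(x, y, v, psi, params)


def run(
    swarm: Swarm2D, n_steps: int, record_every: int = 1, seed: int | None = None
) -> Trajectory:
    """Integrate `n_steps` steps, recording every `record_every` steps.

    The initial and final states are always recorded. Deterministic given
    the initial swarm (the dynamics itself has no noise).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    times = [swarm.time]
    states = [swarm.state_array()]
    current = swarm
    for k in range(1, n_steps + 1):
        current = step(current, _step_index=k)
        if k % record_every == 0 or k == n_steps:
            times.append(current.time)
            states.append(current.state_array())
    meta = {
        "params": vars(current.params).copy(),
        "seed": seed,
        "dim": 2,
        "record_every": record_every,
    }
    return Trajectory(np.array(times), np.stack(states), COLUMNS_2D, meta)
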