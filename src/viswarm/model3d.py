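"""Cylindrical 3D extension: spherical binary retina and coupled dynamics.

Agents are spheres that translate freely in z but never pitch: the velocity
is v_psi * e_psi + v_z * e_z, and the retina is anchored to the world frame
rotated only by the planar heading psi. The visual field V(phi, theta) lives
on a uniform (phi, theta) grid of cell centers; a neighbor at 3D distance d
occupies every cell whose center direction lies within the angular radius
arcsin(min(1, BL/(2 d))) of the neighbor's direction (a spherical cap), and
occlusion is again binary union.

Equations of motion (midpoint quadrature over the grid):

    dv_psi/dt = alpha0 (-A_cos + alpha1 E_cos) + gamma (v0 - v_psi)
    dpsi/dt   = beta0  (-A_sin + beta1  E_sin)
    dv_z/dt   = lambda0 (-A_vert + lambda1 E_vert)

with area kernels cos(theta) cos(phi), cos(theta) sin(phi), sin(theta), and
edge terms detected per theta-row along phi only (periodic), each edge
contributing its kernel value once — the row-wise analogue of the 2D
Dirac-comb rule; up-down (theta-direction) edges are deliberately ignored.
Note v_z has no relaxation term: vertical motion is driven by vision alone.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, NamedTuple

import numpy as np

from .errors import DegenerateGeometryError, IntegrationError
from .params import ModelParams
from .retina import wrap_angle
from .trajectory import COLUMNS_3D, Trajectory

__all__ = [
    "AgentState3D",
    "SphericalField",
    "Swarm3D",
    "render_spherical_field",
    "spherical_functionals",
    "derivatives_3d",
    "step_3d",
    "init_swarm_3d",
    "make_planar_flock",
    "run_3d",
]


@dataclass
class AgentState3D:
    """One 3D agent: position (BL), planar speed, planar heading, vertical speed."""

    x: float
    y: float
    z: float
    v_psi: float
    psi: float
    v_z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z", "v_psi", "psi", "v_z"):
            val = float(getattr(self, name))
            if not math.isfinite(val):
                raise ValueError("agent state fields must be finite")
            setattr(self, name, val)
        self.psi = wrap_angle(self.psi)


class RetinaGrid:
    """Uniform (phi, theta) retina grid with precomputed quadrature weights.

    phi cell centers are periodic on (-pi, pi]; theta cell centers span
    (-pi/2, pi/2) symmetrically about theta = 0, so a field that is
    symmetric under z-reflection yields exactly zero vertical response.
    """

    def __init__(self, n_phi: int, n_theta: int):
        if n_theta % 2:
            raise ValueError("retina_n_theta must be even (theta grid symmetric about 0)")
        self.n_phi = int(n_phi)
        self.n_theta = int(n_theta)
        self.d_phi = 2.0 * math.pi / self.n_phi
        self.d_theta = math.pi / self.n_theta
        self.phi = -math.pi + (np.arange(self.n_phi) + 0.5) * self.d_phi
        # build theta from the upper half and mirror it, so the lower
        # hemisphere weights are bit-identical: a theta-symmetric field then
        # yields an exactly zero vertical response
        half = (np.arange(self.n_theta // 2) + 0.5) * self.d_theta
        self.theta = np.concatenate([-half[::-1], half])
        cos_half = np.cos(half)
        sin_half = np.sin(half)
        cos_t = np.concatenate([cos_half[::-1], cos_half])[:, None]
        sin_t_abs = np.concatenate([sin_half[::-1], sin_half])[:, None]
        z_sign = np.concatenate(
            [-np.ones(self.n_theta // 2), np.ones(self.n_theta // 2)]
        )[:, None]
        cos_p = np.cos(self.phi)[None, :]
        sin_p = np.sin(self.phi)[None, :]
        # (C, 3) unit directions of cell centers in the retina frame
        self.dirs = np.stack(
            [
                (cos_t * cos_p).ravel(),
                (cos_t * sin_p).ravel(),
                np.broadcast_to(z_sign * sin_t_abs, (self.n_theta, self.n_phi)).ravel(),
            ],
            axis=1,
        )
        cell = self.d_phi * self.d_theta
        self.w_area_cos = cos_t * cos_p * cell
        self.w_area_sin = cos_t * sin_p * cell
        self.w_area_vert_half = sin_half[:, None] * cell  # upper-hemisphere rows
        # edges sit midway between adjacent phi cell centers (periodic)
        phi_edge = self.phi + 0.5 * self.d_phi
        self.cos_edge = np.cos(phi_edge)
        self.sin_edge = np.sin(phi_edge)
        self.row_w_cos = cos_t[:, 0] * self.d_theta
        self.row_w_vert_half = sin_half * self.d_theta


@lru_cache(maxsize=8)
def _grid(n_phi: int, n_theta: int) -> RetinaGrid:
    return RetinaGrid(n_phi, n_theta)


@dataclass
class SphericalField:
    """Binary occupancy on a retina grid; shape (n_theta, n_phi)."""

    occupancy: np.ndarray
    grid: RetinaGrid

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != (self.grid.n_theta, self.grid.n_phi):
            raise ValueError("occupancy shape does not match grid")
        self.occupancy = occ

    @property
    def solid_angle_fraction(self) -> float:
        """Fraction of the full sphere covered, via the cos(theta) Jacobian."""
        g = self.grid
        w = np.cos(g.theta)[:, None] * g.d_phi * g.d_theta
        return float(np.sum(self.occupancy * w) / (4.0 * math.pi))


class Functionals3D(NamedTuple):
    A_cos: float
    A_sin: float
    A_vert: float
    E_cos: float
    E_sin: float
    E_vert: float


def _neighbor_caps(
    focal_xyz: np.ndarray, focal_psi: float, others_xyz: np.ndarray, BL: float
) -> tuple[np.ndarray, np.ndarray]:
    """Unit directions (retina frame) and angular radii of neighbor caps."""
    rel = np.asarray(others_xyz - focal_xyz[None, :], dtype=float)
    d = np.linalg.norm(rel, axis=1)
    if np.any(d == 0.0):
        j = int(np.flatnonzero(d == 0.0)[0])
        raise DegenerateGeometryError(f"neighbor {j} coincides with the focal agent")
    c, s = math.cos(focal_psi), math.sin(focal_psi)
    u = np.empty_like(rel)
    u[:, 0] = rel[:, 0] * c + rel[:, 1] * s
    u[:, 1] = -rel[:, 0] * s + rel[:, 1] * c
    u[:, 2] = rel[:, 2]
    u /= d[:, None]
    radii = np.arcsin(np.minimum(1.0, BL / (2.0 * d)))
    return u, radii


def render_spherical_field(
    focal: AgentState3D, others: Iterable[AgentState3D], params: ModelParams
) -> SphericalField:
    """Binary visual field of `focal`: union of neighbors' spherical caps."""
    grid = _grid(params.retina_n_phi, params.retina_n_theta)
    others = list(others)
    if not others:
        return SphericalField(np.zeros((grid.n_theta, grid.n_phi), bool), grid)
    xyz = np.array([[o.x, o.y, o.z] for o in others])
    u, radii = _neighbor_caps(
        np.array([focal.x, focal.y, focal.z]), focal.psi, xyz, params.BL
    )
    occ = _render_occupancy(grid, u, radii)
    return SphericalField(occ, grid)


def _render_occupancy(grid: RetinaGrid, u: np.ndarray, radii: np.ndarray) -> np.ndarray:
    cosr = np.cos(radii)
    occ = np.any(grid.dirs @ u.T >= cosr[None, :], axis=1)
    return occ.reshape(grid.n_theta, grid.n_phi)


def _functionals_from_occupancy(occ: np.ndarray, grid: RetinaGrid) -> Functionals3D:
    v = occ.astype(float)
    a_cos = float(np.sum(v * grid.w_area_cos))
    a_sin = float(np.sum(v * grid.w_area_sin))
    # vertical terms as upper minus lower hemisphere with identical weights
    # and summation order: exact zero for theta-symmetric fields
    h = grid.n_theta // 2
    a_vert = float(
        np.sum(v[h:] * grid.w_area_vert_half) - np.sum(v[h - 1 :: -1] * grid.w_area_vert_half)
    )
    trans = occ != np.roll(occ, -1, axis=1)  # periodic left-right transitions
    row_cos = trans @ grid.cos_edge
    row_sin = trans @ grid.sin_edge
    e_cos = float(grid.row_w_cos @ row_cos)
    e_sin = float(grid.row_w_cos @ row_sin)
    # vertical edge term has unit phi-kernel: each edge counts once per row
    rc = trans.sum(axis=1).astype(float)
    e_vert = float(
        np.dot(rc[h:], grid.row_w_vert_half) - np.dot(rc[h - 1 :: -1], grid.row_w_vert_half)
    )
    return Functionals3D(a_cos, a_sin, a_vert, e_cos, e_sin, e_vert)


def spherical_functionals(field: SphericalField) -> Functionals3D:
    """Area and left-right edge functionals of a binary spherical field.

    Area terms use midpoint quadrature against cos(theta)cos(phi),
    cos(theta)sin(phi) and sin(theta); edge terms count each 0-1 transition
    along phi once at the inter-cell midpoint, weighted per theta-row by
    cos(theta) d_theta (planar terms) or sin(theta) d_theta (vertical term).
    """
    return _functionals_from_occupancy(field.occupancy, field.grid)


def derivatives_3d(
    focal: AgentState3D, functionals: Functionals3D, params: ModelParams
) -> tuple[float, float, float]:
    """Time derivatives (dv_psi, dpsi, dv_z) of one agent's velocity state."""
    p = params
    f = functionals
    dv_psi = p.alpha0 * (-f.A_cos + p.alpha1 * f.E_cos) + p.gamma * (p.v0 - focal.v_psi)
    dpsi = p.beta0 * (-f.A_sin + p.beta1 * f.E_sin)
    dv_z = p.lambda0 * (-f.A_vert + p.lambda1 * f.E_vert)
    return dv_psi, dpsi, dv_z


@dataclass
class Swarm3D:
    """All 3D agent states at one instant, stored as parallel arrays."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    v_psi: np.ndarray
    psi: np.ndarray
    v_z: np.ndarray
    params: ModelParams
    time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("x", "y", "z", "v_psi", "psi", "v_z"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        self.psi = wrap_angle(self.psi)
        n = len(self.x)
        if n < 1:
            raise ValueError("a swarm needs at least one agent")
        if any(len(getattr(self, f)) != n for f in ("y", "z", "v_psi", "psi", "v_z")):
            raise ValueError("state arrays must have equal length")

    @property
    def n(self) -> int:
        return len(self.x)

    def agent(self, i: int) -> AgentState3D:
        return AgentState3D(
            self.x[i], self.y[i], self.z[i], self.v_psi[i], self.psi[i], self.v_z[i]
        )

    @property
    def agents(self) -> list[AgentState3D]:
        return [self.agent(i) for i in range(self.n)]

    def state_array(self) -> np.ndarray:
        """(N, 6) array in :data:`viswarm.trajectory.COLUMNS_3D` order."""
        return np.stack([self.x, self.y, self.z, self.v_psi, self.psi, self.v_z], axis=1)

    @classmethod
    def from_state_array(
        cls, states: np.ndarray, params: ModelParams, time: float = 0.0
    ) -> "Swarm3D":
        s = np.asarray(states, dtype=float)
        return cls(s[:, 0], s[:, 1], s[:, 2], s[:, 3], s[:, 4], s[:, 5], params, time)

    def copy(self) -> "Swarm3D":
        return Swarm3D(
            self.x.copy(), self.y.copy(), self.z.copy(), self.v_psi.copy(),
            self.psi.copy(), self.v_z.copy(), self.params, self.time,
        )


def _check_finite(arr: np.ndarray, term: str, step_index: int | None) -> None:
    if not np.all(np.isfinite(arr)):
        agent = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise IntegrationError(agent=agent, term=term, step=step_index)


def step_3d(swarm: Swarm3D, _step_index: int | None = None) -> Swarm3D:
    """One synchronous explicit-Euler update of the whole 3D swarm."""
    p = swarm.params
    grid = _grid(p.retina_n_phi, p.retina_n_theta)
    n = swarm.n
    xyz = np.stack([swarm.x, swarm.y, swarm.z], axis=1)
    dv_psi = np.zeros(n)
    dpsi = np.zeros(n)
    dv_z = np.zeros(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        if n > 1:
            u, radii = _neighbor_caps(xyz[i], swarm.psi[i], xyz[mask], p.BL)
            occ = _render_occupancy(grid, u, radii)
            f = _functionals_from_occupancy(occ, grid)
        else:
            f = Functionals3D(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        mask[i] = True
        dv_psi[i] = p.alpha0 * (-f.A_cos + p.alpha1 * f.E_cos)
        dpsi[i] = p.beta0 * (-f.A_sin + p.beta1 * f.E_sin)
        dv_z[i] = p.lambda0 * (-f.A_vert + p.lambda1 * f.E_vert)
    dv_psi += p.gamma * (p.v0 - swarm.v_psi)
    _check_finite(dv_psi, "planar speed", _step_index)
    _check_finite(dpsi, "heading", _step_index)
    _check_finite(dv_z, "vertical speed", _step_index)

    v_psi_new = swarm.v_psi + p.dt * dv_psi
    psi_new = wrap_angle(swarm.psi + p.dt * dpsi)
    v_z_new = swarm.v_z + p.dt * dv_z
    x_new = swarm.x + p.dt * v_psi_new * np.cos(psi_new)
    y_new = swarm.y + p.dt * v_psi_new * np.sin(psi_new)
    z_new = swarm.z + p.dt * v_z_new
    _check_finite(x_new, "position", _step_index)
    _check_finite(y_new, "position", _step_index)
    _check_finite(z_new, "position", _step_index)
    return Swarm3D(
        x_new, y_new, z_new, v_psi_new, psi_new, v_z_new, p, swarm.time + p.dt
    )


def init_swarm_3d(
    N: int,
    params: ModelParams,
    seed: int,
    box_side: float | None = None,
    z_jitter: float = 1e-6,
) -> Swarm3D:
    """Random 3D swarm: xy uniform in a square, z uniform in a thinner slab.

    The z spread is box_side/2 total (a quarter of the box on each side of
    the plane) plus a tiny jitter that breaks exact z-symmetry: a swarm
    started exactly in one plane stays there forever, since no vertical
    direction can be preferred without a bias.
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
    z = rng.uniform(-box_side / 4.0, box_side / 4.0, size=N)
    z += rng.normal(0.0, z_jitter, size=N)
    psi = rng.uniform(-math.pi, math.pi, size=N)
    return Swarm3D(x, y, z, np.full(N, params.v0), psi, np.zeros(N), params)


def make_planar_flock(
    N: int,
    params: ModelParams,
    seed: int,
    heading_jitter: float = 0.1,
    z_spread: float = 0.5,
    spacing: float | None = None,
    settle_time: float = 300.0,
) -> Swarm3D:
    """Prepare a polarized, near-planar flock, settled with vertical response off.

    The study of the vertical (flattening) transition presupposes a group
    that is coordinated in the horizontal plane. Because the 3D visual
    interaction weakens with distance in both directions, a dilute group of
    randomly oriented agents tends to disperse before it can organize; this
    constructor therefore starts from a compact group with a common heading
    direction (small jitter), z confined to a thin slab of total thickness
    ``z_spread`` (BL), and lets the planar dynamics settle for
    ``settle_time`` with lambda0 = 0 (v_z stays exactly zero, so z is frozen
    during settling). The returned swarm carries the original `params`,
    vertical response included.

    ``spacing`` defaults to the 3D front-back pair equilibrium estimate
    pi*BL/(8*alpha1); the initial box side is ceil(sqrt(N)) * spacing.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if spacing is None:
        spacing = (
            math.pi * params.BL / (8.0 * params.alpha1)
            if params.alpha1 > 0 else 10.0 * params.BL
        )
    rng = np.random.default_rng(seed)
    box = math.ceil(math.sqrt(N)) * spacing
    x = rng.uniform(0.0, box, size=N)
    y = rng.uniform(0.0, box, size=N)
    z = rng.uniform(-z_spread / 2.0, z_spread / 2.0, size=N)
    psi = rng.normal(0.0, heading_jitter, size=N)
    settle_params = params.replace(lambda0=0.0)
    swarm = Swarm3D(x, y, z, np.full(N, params.v0), psi, np.zeros(N), settle_params)
    n_settle = int(round(settle_time / params.dt))
    if n_settle >= 1:
        settled = run_3d(swarm, n_settle, record_every=n_settle)
        swarm = Swarm3D.from_state_array(settled.states[-1], params)
    else:
        swarm = Swarm3D(x, y, z, np.full(N, params.v0), psi, np.zeros(N), params)
    return swarm


def run_3d(
    swarm: Swarm3D, n_steps: int, record_every: int = 1, seed: int | None = None
) -> Trajectory:
    """Integrate `n_steps` 3D steps, recording every `record_every` steps."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    times = [swarm.time]
    states = [swarm.state_array()]
    current = swarm
    for k in range(1, n_steps + 1):
        current = step_3d(current, _step_index=k)
        if k % record_every == 0 or k == n_steps:
            times.append(current.time)
            states.append(current.state_array())
    meta = {
        "params": vars(current.params).copy(),
        "seed": seed,
        "dim": 3,
        "record_every": record_every,
    }
    return Trajectory(np.array(times), np.stack(states), COLUMNS_3D, meta)
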