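"""Exact binary visual projection field of disk-shaped agents in 2D.

The retina of an agent is the circle of viewing directions phi in (-pi, pi],
measured from its heading (positive = left / counter-clockwise). Each
neighboring disk of diameter BL at center distance d subtends an arc of
half-width arcsin(BL / (2 d)) around its bearing; the binary visual field
V(phi) is 1 wherever any neighbor projects, so occlusion is simply set union
of arcs. This module computes that union exactly (no rasterization), its
edges, and the cosine/sine weighted functionals the equations of motion use:

    area integral  A_k = ∫ k(phi) V(phi) dphi        (k = cos or sin)
    edge sum       E_k = sum over field edges of k(phi_edge)

The edge functional interprets the squared angular derivative of the binary
field as a unit-weight Dirac comb: every edge of the occupied region
contributes k(phi_edge) exactly once, independent of any discretization.
This makes the edge-attraction coefficients dimensionless and yields the
far-field front-back equilibrium distance BL/(2*alpha1).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "AgentState2D",
    "ArcSet",
    "wrap_angle",
    "subtended_arc",
    "occlusion_union",
    "visual_field",
    "field_edges",
    "weighted_area_integral",
    "weighted_edge_sum",
]

TWO_PI = 2.0 * math.pi
# tolerance for "the retina is fully covered" and split-artifact detection
_FULL_TOL = 1e-12


def wrap_angle(phi):
    """Wrap angle(s) to (-pi, pi]."""
    w = np.mod(np.asarray(phi, dtype=float) + math.pi, TWO_PI) - math.pi
    w = np.where(w == -math.pi, math.pi, w)
    if np.ndim(phi) == 0:
        return float(w)
    return w


@dataclass
class AgentState2D:
    """State of one planar agent: position (BL), signed speed, heading."""

    x: float
    y: float
    v: float
    psi: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "v", "psi"):
            val = float(getattr(self, name))
            if not math.isfinite(val):
                raise ValueError("agent state fields must be finite")
            setattr(self, name, val)
        self.psi = wrap_angle(self.psi)

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


class ArcSet:
    """Union of disjoint angular intervals on the retina circle.

    Arcs are stored as an (k, 2) array of (lo, hi) pairs with
    -pi <= lo < hi <= pi, pairwise disjoint and sorted by lo. An arc that
    wraps across +-pi is split into two stored entries; the split boundary
    is bookkeeping, not a physical edge (see :func:`field_edges`).
    """

    __slots__ = ("arcs",)

    def __init__(self, arcs: np.ndarray | Sequence[tuple[float, float]]):
        a = np.asarray(arcs, dtype=float).reshape(-1, 2)
        if a.size:
            if np.any(a[:, 0] >= a[:, 1]):
                raise ValueError("each arc must satisfy lo < hi")
            if np.any(a[:, 0] < -math.pi - _FULL_TOL) or np.any(a[:, 1] > math.pi + _FULL_TOL):
                raise ValueError("arc endpoints must lie in [-pi, pi]")
            order = np.argsort(a[:, 0], kind="stable")
            a = a[order]
            if np.any(a[1:, 0] < a[:-1, 1] - _FULL_TOL):
                raise ValueError("arcs must be pairwise disjoint")
        self.arcs = a

    @classmethod
    def empty(cls) -> "ArcSet":
        return cls(np.empty((0, 2)))

    @classmethod
    def full(cls) -> "ArcSet":
        return cls(np.array([[-math.pi, math.pi]]))

    def __len__(self) -> int:
        return len(self.arcs)

    def __iter__(self):
        return iter(map(tuple, self.arcs))

    def __eq__(self, other) -> bool:
        return isinstance(other, ArcSet) and np.array_equal(self.arcs, other.arcs)

    def __repr__(self) -> str:
        body = ", ".join(f"[{lo:.4f}, {hi:.4f}]" for lo, hi in self.arcs)
        return f"ArcSet({body})"

    @property
    def measure(self) -> float:
        """Total angular measure of the occupied region (<= 2*pi)."""
        if not len(self.arcs):
            return 0.0
        return float(np.sum(self.arcs[:, 1] - self.arcs[:, 0]))

    @property
    def is_full(self) -> bool:
        return self.measure >= TWO_PI - _FULL_TOL

    def contains(self, phi: float) -> bool:
        phi = wrap_angle(phi)
        return bool(np.any((self.arcs[:, 0] <= phi) & (phi <= self.arcs[:, 1])))


def subtended_arc(
    focal: AgentState2D, neighbor: AgentState2D, BL: float = 1.0
) -> tuple[float, float]:
    """Arc subtended by a neighboring disk on the focal agent's retina.

    Returns ``(center, half_width)``: the bearing of the neighbor relative to
    the focal heading, in (-pi, pi], and half the subtended angle,
    arcsin(min(1, BL/(2 d))), in (0, pi/2]. Overlapping bodies (d < BL) are
    clamped to a half-plane projection (half_width = pi/2); the eye sits at
    the disk center, so the focal body itself never occludes.
    """
    dx = neighbor.x - focal.x
    dy = neighbor.y - focal.y
    d = math.hypot(dx, dy)
    if d == 0.0:
        raise DegenerateGeometryError("coincident agents have no defined projection")
    center = wrap_angle(math.atan2(dy, dx) - focal.psi)
    half_width = math.asin(min(1.0, BL / (2.0 * d)))
    return center, half_width


def _merge_circular(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge arcs (lo_i, hi_i) on the circle into disjoint intervals.

    Input intervals are given on the real line (hi > lo, length <= pi each);
    output is a pair (starts, ends) of disjoint intervals sorted by start, in
    a shifted coordinate where the first interval may begin below 0 if the
    union wraps across the 0/2*pi cut. Endpoint angles differ from retina
    angles only by multiples of 2*pi, so periodic kernels may be applied
    directly. Full coverage is signalled by total measure >= 2*pi.
    """
    length = hi - lo
    lo_m = np.mod(lo, TWO_PI)
    hi_m = lo_m + length
    order = np.argsort(lo_m, kind="stable")
    lo_s = lo_m[order]
    hi_s = hi_m[order]
    cummax = np.maximum.accumulate(hi_s)
    is_start = np.empty(lo_s.shape, dtype=bool)
    is_start[0] = True
    # strictly greater: touching arcs fuse and leave no interior edge
    is_start[1:] = lo_s[1:] > cummax[:-1]
    idx = np.flatnonzero(is_start)
    starts = lo_s[idx]
    ends = cummax[np.append(idx[1:] - 1, len(lo_s) - 1)]

    if ends[-1] > TWO_PI and len(starts) >= 1:
        # last interval wraps past the cut: bring it to the front and absorb
        s0, e0 = starts[-1] - TWO_PI, ends[-1] - TWO_PI
        starts, ends = starts[:-1], ends[:-1]
        k = 0
        while k < len(starts) and starts[k] <= e0:
            e0 = max(e0, ends[k])
            k += 1
        starts = np.concatenate(([s0], starts[k:]))
        ends = np.concatenate(([e0], ends[k:]))
    return starts, ends


def occlusion_union(arcs: Iterable[tuple[float, float]]) -> ArcSet:
    """Union of subtended arcs given as (center, half_width) pairs.

    Occlusion in a binary field retains no depth: a farther neighbor hidden
    behind a nearer one contributes nothing, which is exactly set union.
    """
    arcs = list(arcs)
    if not arcs:
        return ArcSet.empty()
    c = np.array([a[0] for a in arcs], dtype=float)
    w = np.array([a[1] for a in arcs], dtype=float)
    if np.any(w <= 0) or np.any(w > math.pi / 2 + _FULL_TOL):
        raise ValueError("half widths must lie in (0, pi/2]")
    starts, ends = _merge_circular(c - w, c + w)
    if float(np.sum(ends - starts)) >= TWO_PI - _FULL_TOL:
        return ArcSet.full()
    # normalize to (-pi, pi], splitting any arc that crosses the +-pi cut
    out: list[tuple[float, float]] = []
    for s, e in zip(starts, ends):
        s_w = wrap_angle(s)
        if s_w == math.pi:  # arc starting exactly at the cut
            s_w = -math.pi
        e_w = s_w + (e - s)
        if e_w > math.pi + _FULL_TOL:
            out.append((s_w, math.pi))
            out.append((-math.pi, e_w - TWO_PI))
        else:
            out.append((s_w, min(e_w, math.pi)))
    return ArcSet(out)


def visual_field(
    focal: AgentState2D, others: Iterable[AgentState2D], BL: float = 1.0
) -> ArcSet:
    """Binary visual projection field of `focal` given all other agents."""
    return occlusion_union(subtended_arc(focal, o, BL) for o in others)


def field_edges(field: ArcSet) -> list[float]:
    """Sorted boundary angles of the occupied region.

    A saturated retina has no edges; a pair of boundaries at exactly -pi and
    +pi produced by splitting a wrapping arc is a storage artifact, detected
    by continuity across the cut, and is not reported.
    """
    a = field.arcs
    if not len(a) or field.is_full:
        return []
    edges = a.ravel()
    wraps = (
        abs(a[0, 0] + math.pi) <= _FULL_TOL and abs(a[-1, 1] - math.pi) <= _FULL_TOL
    )
    if wraps:
        keep = np.ones(len(edges), dtype=bool)
        keep[0] = False
        keep[-1] = False
        edges = edges[keep]
    return sorted(float(e) for e in edges)


def weighted_area_integral(field: ArcSet, kernel: str) -> float:
    """Exact ∫ kernel(phi) V(phi) dphi over the retina.

    With V the indicator of the arc set, the integral reduces per arc to
    sin(hi) - sin(lo) for the cos kernel and cos(lo) - cos(hi) for sin.
    """
    if kernel not in ("cos", "sin"):
        raise ValueError(f"unknown kernel {kernel!r}; expected 'cos' or 'sin'")
    a = field.arcs
    if not len(a) or field.is_full:
        return 0.0
    if kernel == "cos":
        return float(np.sum(np.sin(a[:, 1]) - np.sin(a[:, 0])))
    return float(np.sum(np.cos(a[:, 0]) - np.cos(a[:, 1])))


def weighted_edge_sum(edges: Sequence[float], kernel: str) -> float:
    """Dirac-comb edge functional: sum of kernel(phi) over field edges."""
    e = np.asarray(edges, dtype=float)
    if not e.size:
        return 0.0
    if kernel == "cos":
        return float(np.sum(np.cos(e)))
    if kernel == "sin":
        return float(np.sum(np.sin(e)))
    raise ValueError(f"unknown kernel {kernel!r}; expected 'cos' or 'sin'")
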