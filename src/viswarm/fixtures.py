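"""Named deterministic agent configurations used by tests and examples."""
from __future__ import annotations

import math

import numpy as np

from .model2d import Swarm2D, init_swarm
from .model3d import Swarm3D, init_swarm_3d
from .params import ModelParams

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("pair_front_back", "pair_side", "line", "ring", "random_box")


def make_fixture(
    name: str, params: ModelParams | None = None, dim: int = 2, **kwargs
) -> Swarm2D | Swarm3D:
    """Build a canonical configuration by name.

    * ``pair_front_back(d)`` — two agents with a common heading (+x),
      separated by ``d`` along the heading;
    * ``pair_side(d)`` — two agents heading +x, separated by ``d`` sideways;
    * ``line(N, spacing)`` — N agents on the x axis heading +x;
    * ``ring(N, radius)`` — N agents on a circle, headings tangential
      (counter-clockwise);
    * ``random_box(N, seed, box_side=None)`` — seeded uniform box (the
      standard initial condition).

    All speeds start at the preferred speed v0; ``dim=3`` embeds the planar
    fixtures at z = 0 with zero vertical speed.
    """
    if params is None:
        params = ModelParams()
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")

    if name == "pair_front_back":
        d = float(kwargs.pop("d", 5.0))
        states = [(0.0, 0.0, 0.0), (d, 0.0, 0.0)]
    elif name == "pair_side":
        d = float(kwargs.pop("d", 5.0))
        states = [(0.0, 0.0, 0.0), (0.0, d, 0.0)]
    elif name == "line":
        n = int(kwargs.pop("N", 5))
        spacing = float(kwargs.pop("spacing", 2.0))
        states = [(i * spacing, 0.0, 0.0) for i in range(n)]
    elif name == "ring":
        n = int(kwargs.pop("N", 8))
        radius = float(kwargs.pop("radius", 10.0))
        states = []
        for i in range(n):
            ang = 2.0 * math.pi * i / n
            states.append(
                (radius * math.cos(ang), radius * math.sin(ang), ang + math.pi / 2)
            )
    elif name == "random_box":
        n = int(kwargs.pop("N", 10))
        seed = int(kwargs.pop("seed", 0))
        box_side = kwargs.pop("box_side", None)
        if kwargs:
            raise ValueError(f"unexpected arguments {sorted(kwargs)} for {name!r}")
        if dim == 2:
            return init_swarm(n, params, seed, box_side)
        return init_swarm_3d(n, params, seed, box_side)
    else:
        raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")

    if kwargs:
        raise ValueError(f"unexpected arguments {sorted(kwargs)} for {name!r}")
    x = np.array([s[0] for s in states])
    y = np.array([s[1] for s in states])
    psi = np.array([s[2] for s in states])
    v = np.full(len(states), params.v0)
    if dim == 2:
        return Swarm2D(x, y, v, psi, params)
    z = np.zeros(len(states))
    return Swarm3D(x, y, z, v, psi, np.zeros(len(states)), params)
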