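"""Model parameters for the vision-based swarm model.

Units: lengths in body lengths (BL, the agent diameter), speeds in BL per
time unit; the default time unit is BL / v0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace


@dataclass
class ModelParams:
    """All coefficients of the equations of motion plus integration settings.

    The visual response decomposes, for each degree of freedom, into a
    subtended-angle (area) term that repels and an edge term that attracts:

    * ``alpha0`` scales the speed response, ``alpha1`` weighs its edge term;
    * ``beta0`` scales the turning response, ``beta1`` weighs its edge term;
    * ``lambda0``/``lambda1`` do the same for vertical motion (3D only).

    ``alpha1``, ``beta1`` and ``lambda1`` are dimensionless; the front-back
    equilibrium distance of a pair is BL/(2*alpha1) in the far field, so
    e.g. alpha1 = 0.08 puts the preferred spacing at 6.25 BL.

    ``alpha2``/``beta2`` are hooks for responses to temporal change of the
    visual field; they default to 0 and are not used by the shipped dynamics.
    """

    gamma: float = 1.0          # speed relaxation rate (1/time)
    v0: float = 1.0             # preferred speed (BL/time)
    alpha0: float = 1.0         # speed response strength
    alpha1: float = 0.08        # edge-attraction weight in the speed response
    alpha2: float = 0.0         # temporal-derivative hook (unused)
    beta0: float = 1.0          # turning response strength
    beta1: float = 0.08         # edge-attraction weight in the turning response
    beta2: float = 0.0          # temporal-derivative hook (unused)
    lambda0: float = 0.0        # vertical response strength (3D)
    lambda1: float = 0.0        # edge-attraction weight, vertical response (3D)
    BL: float = 1.0             # body diameter; the length unit
    dt: float = 0.05            # integration time step
    retina_n_phi: int = 128     # 3D retina azimuthal resolution
    retina_n_theta: int = 64    # 3D retina elevation resolution

    def __post_init__(self) -> None:
        for name in ("gamma", "v0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("alpha1", "beta1", "lambda1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.BL <= 0:
            raise ValueError("BL must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.retina_n_phi < 8 or self.retina_n_theta < 8:
            raise ValueError("retina grid sizes must be >= 8")
        if self.retina_n_theta % 2:
            raise ValueError("retina_n_theta must be even (grid symmetric about the horizon)")
        for f in fields(self):
            if not math.isfinite(getattr(self, f.name)):
                raise ValueError(f"{f.name} must be finite")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields changed (re-validated)."""
        return replace(self, **changes)

    def equilibrium_distance(self) -> float:
        """Exact two-agent front-back equilibrium separation.

        Root of BL/(2 d) = sin(arctan(alpha1)); reduces to the far-field
        BL/(2*alpha1) as alpha1 -> 0.
        """
        if self.alpha1 <= 0:
            return math.inf
        return self.BL / (2.0 * math.sin(math.atan(self.alpha1)))
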