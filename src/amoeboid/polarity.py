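"""Bistable reaction-diffusion dynamics of the intracellular polarity component.

A single effective species c lumps the front markers (activated Ras,
PI3K, PIP3) that promote actin polymerization and protrusion.  It obeys

    dc/dt = k_a c (1 - c)(c - delta) - rho c
            + (1/phi) div(phi D grad c) + xi phi (1 - phi)

with a cubic bistable reaction (passive state c ~ 0, active state c ~ 1,
unstable threshold delta), linear degradation, diffusion confined to the
cell interior by the phase field, and Ornstein-Uhlenbeck forcing applied
in the cortical region through the factor phi(1-phi).  The threshold is
not constant: a global feedback

    delta = delta_o + M (int c phi dx - C_o)

raises it when the total amount of c exceeds the target C_o, so active
patches self-limit to a roughly constant coverage (about a quarter of the
cell area at the default C_o = 28 um^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import PHI_FLOOR, GridSpec, integrate_field, masked_diffusion_term

__all__ = [
    "BiochemParams",
    "bistable_threshold",
    "reaction_term",
    "biochemical_step",
    "bistable_front_speed",
]


@dataclass(frozen=True)
class BiochemParams:
    """Polarity kinetics constants.

    k_a      reaction rate of the bistable kinetics (1/s); the single
             knob that tunes cells from slow apolar (k_a ~ 2) to fast
             persistent (k_a ~ 5) motion
    delta_o  base bistability threshold (dimensionless)
    C_o      target total amount of c, integral of c*phi (um^2)
    M        feedback strength coupling the c budget to delta (1/um^2)
    rho      linear degradation rate (1/s)
    D        diffusivity of c inside the cell (um^2/s)
    """

    k_a: float = 3.0
    delta_o: float = 0.5
    C_o: float = 28.0
    M: float = 0.045
    rho: float = 0.1
    D: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.k_a <= 10.0:
            raise ValueError("k_a must lie in [0, 10]")
        if not 0.0 < self.delta_o < 1.0:
            raise ValueError("delta_o must lie in (0, 1)")
        for name in ("C_o", "M", "rho", "D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def bistable_threshold(c: np.ndarray, phi: np.ndarray, p: BiochemParams, grid: GridSpec) -> float:
    """Global-feedback threshold delta = delta_o + M (int c phi dx - C_o)."""
    return p.delta_o + p.M * (integrate_field(c * phi, grid) - p.C_o)


def reaction_term(c, delta: float, p: BiochemParams):
    """Cubic bistable kinetics k_a c (1 - c)(c - delta); roots at 0, delta, 1."""
    return p.k_a * c * (1.0 - c) * (c - delta)


def bistable_front_speed(k_a: float, D: float, delta: float) -> float:
    """Closed-form 1D front speed sqrt(k_a D / 2) (1 - 2 delta) of the cubic.

    Positive speed means the active state c = 1 invades; the front is
    stationary at delta = 1/2, which is how the global feedback parks
    patch boundaries.
    """
    return np.sqrt(k_a * D / 2.0) * (1.0 - 2.0 * delta)


def biochemical_step(
    c: np.ndarray,
    phi: np.ndarray,
    xi: np.ndarray,
    p: BiochemParams,
    grid: GridSpec,
    phi_floor: float = PHI_FLOOR,
) -> np.ndarray:
    """One explicit Euler step of the polarity equation.

    The threshold delta is evaluated from the pre-update (c, phi)
    snapshot.  No clipping is applied to c: for small negative
    excursions the cubic itself is restoring.
    """
    delta = bistable_threshold(c, phi, p, grid)
    rhs = (
        reaction_term(c, delta, p)
        - p.rho * c
        + masked_diffusion_term(c, phi, p.D, grid, phi_floor)
        + xi * phi * (1.0 - phi)
    )
    out = c + grid.dt * rhs
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("polarity field became non-finite")
    return out
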