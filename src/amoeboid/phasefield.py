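"""Phase-field description of the deformable cell boundary.

The cell shape is encoded by an auxiliary field phi that is 1 inside the
cell, 0 outside, with a smooth interface of width ~epsilon whose 0.5
level set represents the membrane.  Its overdamped evolution

    tau dphi/dt = gamma (lap(phi) - G'(phi)/eps^2)
                  - beta (int phi dx - A_o) |grad phi|
                  + alpha c |grad phi|

balances three forces: surface tension (Allen-Cahn relaxation with the
double-well G(phi) = 18 phi^2 (1-phi)^2), a global area constraint that
restores the cell area to A_o, and an active tension that pushes the
interface outward where the intracellular polarity component c is high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, grad_magnitude, integrate_field, laplacian

__all__ = [
    "PhaseFieldParams",
    "double_well",
    "double_well_prime",
    "surface_tension_term",
    "area_constraint_term",
    "active_tension_term",
    "phase_field_step",
    "surface_energy",
    "tanh_disk",
]


class InstabilityError(RuntimeError):
    """Raised when an explicit update produces non-finite or runaway values."""


@dataclass(frozen=True)
class PhaseFieldParams:
    """Membrane mechanics constants.

    tau     friction per unit area with the substrate (pN s / um^2)
    gamma   surface tension (pN)
    epsilon interface width (um)
    beta    strength of the global area constraint (pN / um^3)
    A_o     target (resting) cell area (um^2)
    alpha   active tension per unit of c (pN / um)
    """

    tau: float = 2.0
    gamma: float = 2.0
    epsilon: float = 0.75
    beta: float = 22.2
    A_o: float = 113.0
    alpha: float = 3.0

    def __post_init__(self) -> None:
        for name in ("tau", "gamma", "epsilon", "beta", "A_o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative (0 disables the active force)")


def double_well(phi):
    """Double-well potential G(phi) = 18 phi^2 (1 - phi)^2, minima at 0 and 1."""
    return 18.0 * phi**2 * (1.0 - phi) ** 2


def double_well_prime(phi):
    """G'(phi) = 36 phi (1 - phi) (1 - 2 phi)."""
    return 36.0 * phi * (1.0 - phi) * (1.0 - 2.0 * phi)


def surface_tension_term(phi: np.ndarray, p: PhaseFieldParams, grid: GridSpec) -> np.ndarray:
    """gamma * (lap(phi) - G'(phi)/eps^2): Allen-Cahn surface-tension force density."""
    return p.gamma * (laplacian(phi, grid) - double_well_prime(phi) / p.epsilon**2)


def area_constraint_term(phi: np.ndarray, p: PhaseFieldParams, grid: GridSpec) -> np.ndarray:
    """-beta (area - A_o) |grad phi|: restores the enclosed area toward A_o.

    Acts only on the interface (where |grad phi| > 0), shrinking the cell
    when its area exceeds A_o and inflating it otherwise.
    """
    area = integrate_field(phi, grid)
    return -p.beta * (area - p.A_o) * grad_magnitude(phi, grid)


def active_tension_term(
    phi: np.ndarray, c: np.ndarray, p: PhaseFieldParams, grid: GridSpec
) -> np.ndarray:
    """+alpha c |grad phi|: protrusive force where the polarity component is high."""
    return p.alpha * c * grad_magnitude(phi, grid)


def phase_field_step(
    phi: np.ndarray, c: np.ndarray, p: PhaseFieldParams, grid: GridSpec
) -> np.ndarray:
    """One explicit Euler step of the phase-field equation.

    No clipping is applied; the energy structure keeps phi in [0, 1] up to
    small overshoots.  Raises :class:`InstabilityError` if phi leaves
    [-1.1, 1.1] or becomes non-finite, which indicates a violated stability
    bound rather than a physical state.
    """
    rhs = (
        surface_tension_term(phi, p, grid)
        + area_constraint_term(phi, p, grid)
        + active_tension_term(phi, c, p, grid)
    )
    out = phi + (grid.dt / p.tau) * rhs
    if not np.all(np.isfinite(out)):
        raise InstabilityError("phase field became non-finite")
    if np.max(np.abs(out)) > 1.1:
        raise InstabilityError(f"phase field out of range (max |phi| = {np.max(np.abs(out)):.3f})")
    return out


def surface_energy(phi: np.ndarray, p: PhaseFieldParams, grid: GridSpec) -> float:
    """Surface energy H = gamma * eps * integral(|grad phi|^2 / 2 + G(phi)/eps^2).

    For the equilibrium tanh interface the two integrand terms
    equipartition and each contributes 1/(2 eps) per unit interface
    length, so with the leading eps factor H equals gamma * L exactly in
    the sharp-interface limit and H/gamma is a perimeter diagnostic (um).
    """
    fx = (np.roll(phi, -1, axis=1) - np.roll(phi, 1, axis=1)) / (2.0 * grid.dx)
    fy = (np.roll(phi, -1, axis=0) - np.roll(phi, 1, axis=0)) / (2.0 * grid.dx)
    density = 0.5 * (fx**2 + fy**2) + double_well(phi) / p.epsilon**2
    return p.gamma * p.epsilon * integrate_field(density, grid)


def tanh_disk(
    grid: GridSpec,
    area: float = 113.0,
    epsilon: float = 0.75,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Equilibrium disk profile phi(r) = (1 - tanh(3 (r - R)/eps))/2.

    This is the stationary radial interface of the double well G; R is
    chosen so the enclosed area is ``area``.  ``center`` is (x, y) in um
    and defaults to the box centre.
    """
    R = np.sqrt(area / np.pi)
    Lx, Ly = grid.box_size
    if center is None:
        center = (Lx / 2.0, Ly / 2.0)
    x = np.arange(grid.nx) * grid.dx
    y = np.arange(grid.ny) * grid.dx
    xx, yy = np.meshgrid(x, y)
    r = np.hypot(xx - center[0], yy - center[1])
    return 0.5 * (1.0 - np.tanh(3.0 * (r - R) / epsilon))
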