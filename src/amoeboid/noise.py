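"""Spatio-temporally correlated cortical noise.

Each lattice cell carries an independent Ornstein-Uhlenbeck process

    dxi/dt = -k_eta xi + eta(x, t)

driven by Gaussian white noise with <eta> = 0 and
<eta(x,t) eta(x',t')> = 2 sigma^2 delta(x - x') delta(t - t').  On the
lattice the spatial delta function is discretized as 1/dx^2 per cell, so
an Euler-Maruyama step reads

    xi <- xi (1 - k_eta dt) + sqrt(2 sigma^2 dt / dx^2) N(0, 1)

with stationary per-cell variance sigma^2 / (k_eta dx^2) (up to an
O(k_eta dt) discretization factor) and correlation time 1/k_eta.  Note
the absolute noise amplitude is anchored to the lattice spacing: the
defaults assume dx = 0.15 um, and coarser grids change the effective
forcing in any one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec

__all__ = ["NoiseParams", "white_noise_increment", "ou_step", "stationary_std"]


@dataclass(frozen=True)
class NoiseParams:
    """sigma: white-noise intensity (1/s^2); k_eta: OU relaxation rate (1/s)."""

    sigma: float = 0.15
    k_eta: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.k_eta <= 0:
            raise ValueError("k_eta must be strictly positive")


def stationary_std(p: NoiseParams, grid: GridSpec) -> float:
    """Stationary per-cell standard deviation sigma / sqrt(k_eta dx^2)."""
    return p.sigma / np.sqrt(p.k_eta * grid.dx**2)


def white_noise_increment(
    grid: GridSpec, p: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    """Sample the white-noise field eta: iid N(0, 2 sigma^2/(dx^2 dt)) per cell.

    Multiplying by dt in an Euler-Maruyama step gives an increment of
    standard deviation sqrt(2 sigma^2 dt / dx^2).
    """
    std = np.sqrt(2.0 * p.sigma**2 / (grid.dx**2 * grid.dt))
    return std * rng.standard_normal(grid.shape)


def ou_step(
    xi: np.ndarray, grid: GridSpec, p: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    """One Euler-Maruyama step of the per-cell OU processes."""
    out = xi * (1.0 - p.k_eta * grid.dt) + grid.dt * white_noise_increment(grid, p, rng)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("noise field became non-finite")
    return out
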