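"""Synthetic fixtures with known ground truth.

Analytic shapes (tanh disks and ellipses), rigidly moving and deforming
shape sequences, and persistent-random-walk trajectories, used to
validate the contour-tracking and trajectory-statistics pipelines
against closed-form answers.  Everything is generated at call time from
a seed; nothing is stored on disk.
"""

from __future__ import annotations

import numpy as np

from .engine import SimulationConfig, SnapshotSeries
from .grid import GridSpec
from .motility import prw_generator  # noqa: F401  (re-exported as a fixture)
from .phasefield import tanh_disk

__all__ = [
    "disk_field",
    "ellipse_field",
    "shape_series",
    "translating_disk_series",
    "expanding_disk_series",
    "rotating_ellipse_series",
    "prw_generator",
]


def disk_field(
    grid: GridSpec,
    radius: float = 6.0,
    epsilon: float = 0.75,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Tanh disk phi field of the given radius (um)."""
    return tanh_disk(grid, area=np.pi * radius**2, epsilon=epsilon, center=center)


def ellipse_field(
    grid: GridSpec,
    a: float = 6.0,
    b: float = 3.0,
    epsilon: float = 0.75,
    angle: float = 0.0,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Tanh-profile ellipse with semi-axes a, b (um), rotated by ``angle`` rad.

    The interface runs along the ellipse through a signed-distance-like
    level function; exact only in the limit epsilon -> 0, adequate for
    contour fixtures.
    """
    Lx, Ly = grid.box_size
    if center is None:
        center = (Lx / 2.0, Ly / 2.0)
    x = np.arange(grid.nx) * grid.dx - center[0]
    y = np.arange(grid.ny) * grid.dx - center[1]
    xx, yy = np.meshgrid(x, y)
    u = np.cos(angle) * xx + np.sin(angle) * yy
    v = -np.sin(angle) * xx + np.cos(angle) * yy
    # approximate signed distance via the scaled radial residual
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    dist = (rho - 1.0) * np.sqrt((a * b) / np.maximum(rho, 1e-12))
    return 0.5 * (1.0 - np.tanh(3.0 * dist / epsilon))


def bumpy_disk_field(
    grid: GridSpec,
    radius: float = 6.0,
    amp: float = 0.05,
    m: int = 3,
    angle: float = 0.0,
    epsilon: float = 0.75,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Disk with an m-fold radial modulation r(t) = R(1 + amp cos(m(t - angle))).

    The modulation gives the otherwise rotation-symmetric disk
    identifiable material features, which node-tracking tests need.
    """
    Lx, Ly = grid.box_size
    if center is None:
        center = (Lx / 2.0, Ly / 2.0)
    x = np.arange(grid.nx) * grid.dx - center[0]
    y = np.arange(grid.ny) * grid.dx - center[1]
    xx, yy = np.meshgrid(x, y)
    r = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)
    r_target = radius * (1.0 + amp * np.cos(m * (theta - angle)))
    return 0.5 * (1.0 - np.tanh(3.0 * (r - r_target) / epsilon))


def shape_series(
    frames: list[np.ndarray],
    grid: GridSpec,
    c_frames: list[np.ndarray] | None = None,
    dt: float = 1.0,
) -> SnapshotSeries:
    """Wrap a list of phi (and optionally c) frames as a SnapshotSeries."""
    n = len(frames)
    phi = np.stack([f.astype(np.float32) for f in frames])
    c = np.stack([f.astype(np.float32) for f in c_frames]) if c_frames is not None else None
    config = SimulationConfig(grid=grid, duration=n * dt, burn_in=0.0)
    zeros = np.zeros((n, 2))
    return SnapshotSeries(
        times=np.arange(n) * dt,
        com=zeros.copy(),
        offsets=zeros.copy(),
        area=np.zeros(n),
        amount=np.zeros(n),
        delta=np.zeros(n),
        phi=phi,
        c=c,
        config=config,
        seed=0,
    )


def translating_disk_series(
    grid: GridSpec,
    n_frames: int = 10,
    radius: float = 6.0,
    velocity: tuple[float, float] = (0.1, 0.0),
    epsilon: float = 0.75,
) -> SnapshotSeries:
    """Rigidly translating disk, ``velocity`` in um per frame."""
    Lx, Ly = grid.box_size
    frames = []
    for k in range(n_frames):
        cx = Lx / 2.0 + k * velocity[0]
        cy = Ly / 2.0 + k * velocity[1]
        frames.append(disk_field(grid, radius, epsilon, center=(cx, cy)))
    return shape_series(frames, grid)


def expanding_disk_series(
    grid: GridSpec,
    n_frames: int = 5,
    radius0: float = 5.0,
    growth: float = 0.1,
    epsilon: float = 0.75,
) -> SnapshotSeries:
    """Concentric disk growing by ``growth`` um of radius per frame."""
    frames = [disk_field(grid, radius0 + k * growth, epsilon) for k in range(n_frames)]
    return shape_series(frames, grid)


def rotating_ellipse_series(
    grid: GridSpec,
    n_frames: int = 100,
    a: float = 6.0,
    b: float = 3.0,
    omega: float = 0.02,
    epsilon: float = 0.75,
) -> SnapshotSeries:
    """Rigidly rotating ellipse, ``omega`` rad per frame; tests node tracking."""
    frames = [ellipse_field(grid, a, b, epsilon, angle=omega * k) for k in range(n_frames)]
    return shape_series(frames, grid)
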