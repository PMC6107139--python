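"""Coupled simulation of cell shape, polarity and noise.

Orchestrates the explicit time stepping of the phase field phi, the
polarity component c and the Ornstein-Uhlenbeck noise xi on a periodic
lattice, with the update ordering per time step:

    (1) global threshold delta from the pre-update (c, phi);
    (2) OU update of xi;
    (3) explicit Euler update of c (using the new xi, pre-update phi);
    (4) explicit Euler update of phi (using the pre-update c).

The cell is kept near the box centre by rolling all fields by an integer
number of pixels whenever the centroid strays beyond a threshold; the
accumulated offset makes unwrapped trajectories exact.  Snapshots are
recorded at 1 Hz by default, mirroring typical live-cell imaging frame
rates, so simulated and experimental statistics are directly comparable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _kernels
from .grid import PHI_FLOOR, GridSpec, integrate_field
from .noise import NoiseParams, ou_step, stationary_std
from .phasefield import InstabilityError, PhaseFieldParams, phase_field_step, tanh_disk
from .polarity import BiochemParams, biochemical_step

__all__ = [
    "SimulationConfig",
    "FieldState",
    "SnapshotSeries",
    "initialize",
    "step",
    "recenter_if_needed",
    "run_simulation",
]

# phi below this is treated as saturated-outside, above 1 minus it as
# saturated-inside, for the purpose of partitioning work in the fast path
BAND_THRESHOLD = 1e-6
BAND_DILATION = 3  # pixels of safety margin around the interface band
REFRESH_STEPS = 100  # steps between band refreshes (0.2 s at dt = 0.002)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one simulation run."""

    phase: PhaseFieldParams = field(default_factory=PhaseFieldParams)
    biochem: BiochemParams = field(default_factory=BiochemParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    grid: GridSpec = field(default_factory=GridSpec)
    duration: float = 500.0  # total simulated time (s)
    burn_in: float = 100.0  # discarded transient before snapshots start (s)
    snapshot_interval: float = 1.0  # s
    recenter_threshold: float = 2.0  # centroid excursion triggering a roll (um)
    seed: int = 0
    store_fields: bool = True  # keep phi/c frames (float32) in the snapshot series
    # "patch" starts at the budget balance point (quarter-disk of active
    # state, delta ~ delta_o); "zero" lets noise nucleate patches from an
    # empty cell, at the price of a violent global activation transient
    # (delta(0) = -0.76) that can transiently drive extreme shapes
    c_init: str = "patch"
    k_a_ramp: float = 0.0  # optional development schedule k_a(t) = k_a + ramp * t

    def __post_init__(self) -> None:
        if self.duration < self.burn_in or self.burn_in < 0:
            raise ValueError("need duration >= burn_in >= 0")
        if self.snapshot_interval <= 0:
            raise ValueError("snapshot_interval must be positive")
        n = self.snapshot_interval / self.grid.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("snapshot_interval must be a multiple of dt")
        if self.c_init not in ("zero", "patch"):
            raise ValueError("c_init must be 'zero' or 'patch'")
        diameter = 2.0 * np.sqrt(self.phase.A_o / np.pi)
        if min(self.grid.box_size) < 2.5 * diameter:
            raise ValueError(
                f"box {self.grid.box_size} smaller than 2.5 cell diameters ({2.5 * diameter:.1f} um)"
            )
        self.grid.check_stability(self.biochem.D)
        self.grid.check_stability(self.phase.gamma / self.phase.tau)


@dataclass
class FieldState:
    """The three lattice fields at one instant, plus trajectory bookkeeping."""

    phi: np.ndarray
    c: np.ndarray
    xi: np.ndarray
    time: float
    offset: np.ndarray  # cumulative recentering offset (x, y) in um
    rng: np.random.Generator


@dataclass
class SnapshotSeries:
    """1 Hz record of a run: centre of mass always, full fields optionally."""

    times: np.ndarray  # (n,) s
    com: np.ndarray  # (n, 2) unwrapped centre of mass (x, y) um
    offsets: np.ndarray  # (n, 2) cumulative recentering offset (x, y) um
    area: np.ndarray  # (n,) cell area integral(phi) um^2
    amount: np.ndarray  # (n,) c budget integral(c phi) um^2
    delta: np.ndarray  # (n,) bistability threshold
    phi: np.ndarray | None  # (n, ny, nx) float32, or None
    c: np.ndarray | None
    config: SimulationConfig
    seed: int

    @property
    def n_frames(self) -> int:
        return len(self.times)


def _centroid_in_box(phi: np.ndarray, grid: GridSpec) -> np.ndarray:
    """phi-weighted centroid (x, y) in um, assuming the cell does not wrap."""
    total = phi.sum()
    rows, cols = np.nonzero(phi > BAND_THRESHOLD)
    w = phi[rows, cols]
    cx = float((w * cols).sum() / total) * grid.dx
    cy = float((w * rows).sum() / total) * grid.dx
    return np.array([cx, cy])


def initialize(config: SimulationConfig) -> FieldState:
    """Equilibrium tanh disk for phi, c zero or a seeded patch, stationary xi."""
    grid = config.grid
    rng = np.random.default_rng(config.seed)
    phi = tanh_disk(grid, area=config.phase.A_o, epsilon=config.phase.epsilon)
    if config.c_init == "patch":
        # quarter-disk wedge of active state inside the cell
        Lx, Ly = grid.box_size
        x = np.arange(grid.nx) * grid.dx - Lx / 2.0
        y = np.arange(grid.ny) * grid.dx - Ly / 2.0
        xx, yy = np.meshgrid(x, y)
        c = np.where((phi > 0.5) & (xx >= 0) & (yy >= 0), 1.0, 0.0)
    else:
        c = np.zeros(grid.shape)
    xi = stationary_std(config.noise, grid) * rng.standard_normal(grid.shape)
    if config.noise.sigma == 0.0:
        xi[:] = 0.0
    return FieldState(phi=phi, c=c, xi=xi, time=0.0, offset=np.zeros(2), rng=rng)


def step(state: FieldState, config: SimulationConfig) -> FieldState:
    """Reference single step composed from the per-module operators.

    Used for validation and small problems; the production path is the
    fused kernel in :mod:`amoeboid._kernels`, which implements identical
    update rules.
    """
    grid = config.grid
    biochem = config.biochem
    if config.k_a_ramp != 0.0:
        biochem = dataclasses.replace(biochem, k_a=biochem.k_a + config.k_a_ramp * state.time)
    xi_new = ou_step(state.xi, grid, config.noise, state.rng)
    c_new = biochemical_step(state.c, state.phi, xi_new, biochem, grid)
    phi_new = phase_field_step(state.phi, state.c, config.phase, grid)
    return FieldState(
        phi=phi_new,
        c=c_new,
        xi=xi_new,
        time=state.time + grid.dt,
        offset=state.offset,
        rng=state.rng,
    )


def recenter_if_needed(state: FieldState, config: SimulationConfig) -> FieldState:
    """Roll all fields by whole pixels to re-centre the cell, updating the offset.

    The unwrapped centroid (in-box centroid + offset) is invariant to
    machine precision.
    """
    grid = config.grid
    com = _centroid_in_box(state.phi, grid)
    centre = np.array(grid.box_size) / 2.0
    if np.max(np.abs(com - centre)) <= config.recenter_threshold:
        return state
    shift_px = np.round((com - centre) / grid.dx).astype(int)  # (x, y)
    # rolling content by -shift moves the centroid onto the centre
    for arr in (state.phi, state.c, state.xi):
        arr[:] = np.roll(np.roll(arr, -shift_px[1], axis=0), -shift_px[0], axis=1)
    state.offset = state.offset + shift_px * grid.dx
    return state


def _band_partition(phi: np.ndarray):
    """Index lists for the interface band and the saturated interior core."""
    interface = (phi > BAND_THRESHOLD) & (phi < 1.0 - BAND_THRESHOLD)
    band = ndimage.binary_dilation(interface, iterations=BAND_DILATION)
    core = (phi >= 1.0 - BAND_THRESHOLD) & ~band
    bi, bj = np.nonzero(band)
    ci, cj = np.nonzero(core)
    return (
        bi.astype(np.int64),
        bj.astype(np.int64),
        ci.astype(np.int64),
        cj.astype(np.int64),
        band,
        core,
    )


def _check_health(phi: np.ndarray, c: np.ndarray, time: float) -> None:
    if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(c))):
        raise InstabilityError(f"non-finite field values at t = {time:.3f} s")
    m = float(np.max(np.abs(phi)))
    if m > 1.1:
        raise InstabilityError(f"phase field out of range (|phi| = {m:.3f}) at t = {time:.3f} s")


def _check_box_margin(phi: np.ndarray, grid: GridSpec, epsilon: float, time: float) -> None:
    """Error out before the (recentred) cell wraps the periodic box.

    Called after recentering: if the membrane comes within three
    interface widths of the box edge the periodic images are about to
    interact and centroid bookkeeping would silently corrupt, so this is
    treated as the cell having outgrown the box.
    """
    margin = int(np.ceil(3.0 * epsilon / grid.dx))
    rows, cols = np.nonzero(phi > 0.5)
    if (
        rows.min() < margin
        or cols.min() < margin
        or rows.max() >= grid.ny - margin
        or cols.max() >= grid.nx - margin
    ):
        raise InstabilityError(
            f"cell reached the box margin at t = {time:.3f} s; "
            "enlarge the box or reduce the run length"
        )


def run_simulation(
    config: SimulationConfig,
    method: str = "compiled",
    progress: bool = False,
) -> SnapshotSeries:
    """Integrate the coupled model and return the 1 Hz snapshot series.

    ``method="compiled"`` uses the fused banded kernel (the default);
    ``method="reference"`` composes the per-module numpy operators and is
    only practical for short runs on small grids.  Results for matched
    noise draws agree to round-off; with noise on, the two paths consume
    random numbers in different orders and so realize different (equally
    distributed) trajectories.
    """
    if method not in ("compiled", "reference"):
        raise ValueError("method must be 'compiled' or 'reference'")
    grid = config.grid
    state = initialize(config)
    n_snap_steps = int(round(config.snapshot_interval / grid.dt))
    n_total = int(round(config.duration / grid.dt))

    times, coms, offsets, areas, amounts, deltas = [], [], [], [], [], []
    phis, cs = [], []

    def record(area: float, amount: float, delta: float) -> None:
        com = _centroid_in_box(state.phi, grid) + state.offset
        times.append(state.time)
        coms.append(com)
        offsets.append(state.offset.copy())
        areas.append(area)
        amounts.append(amount)
        deltas.append(delta)
        if config.store_fields:
            phis.append(state.phi.astype(np.float32))
            cs.append(state.c.astype(np.float32))

    step_count = 0
    next_log = 100.0
    while step_count < n_total:
        n_this = min(n_snap_steps, n_total - step_count)
        if method == "compiled":
            _advance_compiled(state, config, n_this)
        else:
            for _ in range(n_this):
                state = step(state, config)
        step_count += n_this
        _check_health(state.phi, state.c, state.time)
        recenter_if_needed(state, config)
        _check_box_margin(state.phi, grid, config.phase.epsilon, state.time)
        if state.time > config.burn_in + 1e-9 and step_count >= n_snap_steps:
            area = integrate_field(state.phi, grid)
            amount = integrate_field(state.c * state.phi, grid)
            delta = config.biochem.delta_o + config.biochem.M * (amount - config.biochem.C_o)
            record(area, amount, delta)
        if progress and state.time >= next_log:
            com = _centroid_in_box(state.phi, grid) + state.offset
            amount = integrate_field(state.c * state.phi, grid)
            delta = config.biochem.delta_o + config.biochem.M * (amount - config.biochem.C_o)
            print(
                f"t={state.time:7.1f} s  area={integrate_field(state.phi, grid):7.2f}  "
                f"amount={amount:6.2f}  delta={delta:6.3f}  "
                f"com=({com[0]:7.2f},{com[1]:7.2f})"
            )
            next_log += 100.0

    return SnapshotSeries(
        times=np.array(times),
        com=np.array(coms).reshape(-1, 2),
        offsets=np.array(offsets).reshape(-1, 2),
        area=np.array(areas),
        amount=np.array(amounts),
        delta=np.array(deltas),
        phi=np.array(phis) if config.store_fields and phis else None,
        c=np.array(cs) if config.store_fields and cs else None,
        config=config,
        seed=config.seed,
    )


def _advance_compiled(state: FieldState, config: SimulationConfig, n_steps: int) -> None:
    """Advance ``n_steps`` with the fused kernel, refreshing the band partition."""
    grid = config.grid
    p, b, nz = config.phase, config.biochem, config.noise
    a_ou = 1.0 - nz.k_eta * grid.dt
    s_ou = np.sqrt(2.0 * nz.sigma**2 * grid.dt / grid.dx**2)
    done = 0
    while done < n_steps:
        n_chunk = min(REFRESH_STEPS, n_steps - done)
        bi, bj, ci, cj, band, core = _band_partition(state.phi)
        updated = band | core
        sum_phi_const = float(state.phi[~band].sum())
        sum_cphi_const = float((state.c[~updated] * state.phi[~updated]).sum())
        normals = state.rng.standard_normal((n_chunk, bi.size))
        # ramped k_a is held constant within a chunk; evaluating it at the
        # chunk midpoint keeps the error second order in the chunk length
        k_a = b.k_a + config.k_a_ramp * (state.time + 0.5 * n_chunk * grid.dt)
        _kernels.run_chunk(
            state.phi,
            state.c,
            state.xi,
            bi,
            bj,
            ci,
            cj,
            normals,
            grid.dx,
            grid.dt,
            p.tau,
            p.gamma,
            p.epsilon**2,
            p.beta,
            p.A_o,
            p.alpha,
            k_a,
            b.delta_o,
            b.C_o,
            b.M,
            b.rho,
            b.D,
            PHI_FLOOR,
            a_ou,
            s_ou,
            sum_phi_const,
            sum_cphi_const,
        )
        done += n_chunk
        state.time += n_chunk * grid.dt
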