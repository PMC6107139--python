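"""Centre-of-mass trajectory statistics.

Implements the standard motility observables at 1 Hz sampling:
instantaneous speed and its autocorrelation time tau_a (first decay of
the normalized speed ACF to 0.5), the time-averaged mean-squared
displacement with a persistent-random-walk fit

    MSD(T) = 4 D_a (T - tau_P (1 - exp(-T / tau_P)))

(Fuerth's formula, ballistic at short lags and diffusive at long lags),
and velocity-component histograms with their Gaussian fits and excess
kurtosis.  A persistent-random-walk generator (2D Ornstein-Uhlenbeck
velocity process) whose ensemble MSD is exactly Fuerth's formula serves
as the known-parameter control for the fitting pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from statsmodels.tsa.stattools import acf as _acf

from .engine import SnapshotSeries

__all__ = [
    "Trajectory",
    "SpeedSeries",
    "FurthFit",
    "VelocityDistribution",
    "furth_msd",
    "com_trajectory",
    "instantaneous_speed",
    "speed_autocorrelation",
    "mean_squared_displacement",
    "furth_fit",
    "prw_generator",
    "velocity_histogram",
]


@dataclass
class Trajectory:
    """Uniformly sampled, unwrapped 2D centre-of-mass positions (um)."""

    times: np.ndarray  # (n,) s
    positions: np.ndarray  # (n, 2) um

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("times must be strictly increasing and uniformly sampled")

    @property
    def sample_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class SpeedSeries:
    """Instantaneous speeds ||r(t + dt) - r(t)|| / dt at the sampling interval."""

    times: np.ndarray
    speeds: np.ndarray

    def mean(self) -> float:
        return float(np.mean(self.speeds))


@dataclass
class FurthFit:
    """Persistent-random-walk parameters fitted to an MSD curve."""

    D_a: float  # diffusion coefficient (um^2/s)
    tau_P: float  # persistence time (s)
    covariance: np.ndarray  # 2x2 from the least-squares fit
    lags: np.ndarray  # lag times used (s)


@dataclass
class VelocityDistribution:
    """Histogrammed velocity components with Gaussian fit diagnostics."""

    bin_edges: np.ndarray
    counts_x: np.ndarray
    counts_y: np.ndarray
    mu: float  # ML Gaussian fit to v_x
    sigma: float
    excess_kurtosis_x: float
    excess_kurtosis_y: float
    ks_pvalue_xy: float  # two-sample KS of v_x vs v_y
    center_excess: float  # relative excess of P(|v_x| < sigma/2) over the fit
    tail_excess: float  # relative excess of P(|v_x| > 2 sigma) over the fit
    samples_x: np.ndarray
    samples_y: np.ndarray


def furth_msd(T, D_a: float, tau_P: float):
    """Fuerth's formula MSD(T) = 4 D_a (T - tau_P (1 - exp(-T/tau_P)))."""
    T = np.asarray(T, dtype=float)
    return 4.0 * D_a * (T - tau_P * (1.0 - np.exp(-T / tau_P)))


def com_trajectory(snapshots: SnapshotSeries) -> Trajectory:
    """Unwrapped phi-weighted centroid trajectory of a simulation run."""
    return Trajectory(times=snapshots.times.copy(), positions=snapshots.com.copy())


def instantaneous_speed(traj: Trajectory) -> SpeedSeries:
    """Frame-to-frame speed; no smoothing is applied."""
    if len(traj.times) < 2:
        raise ValueError("need at least two samples")
    d = np.diff(traj.positions, axis=0)
    dt = traj.sample_interval
    return SpeedSeries(times=traj.times[:-1], speeds=np.hypot(d[:, 0], d[:, 1]) / dt)


def speed_autocorrelation(
    speeds: SpeedSeries, max_lag: int | None = None
) -> tuple[np.ndarray, float]:
    """Normalized speed ACF and the characteristic time tau_a.

    tau_a is the lag (in time units) at which the mean-subtracted,
    variance-normalized autocorrelation first decays to 0.5, linearly
    interpolated between integer lags.  Raises if the ACF never reaches
    0.5 within the lag window.
    """
    v = speeds.speeds
    if len(v) < 50:
        raise ValueError("need at least 50 speed samples")
    if max_lag is None:
        max_lag = len(v) // 2
    rho = _acf(v, nlags=max_lag, fft=True)
    below = np.nonzero(rho <= 0.5)[0]
    if len(below) == 0:
        raise ValueError("speed ACF does not decay to 0.5 within the lag window")
    k = int(below[0])
    if k == 0:
        raise ValueError("speed ACF below 0.5 at lag zero; series is degenerate")
    # linear interpolation between lags k-1 and k
    frac = (rho[k - 1] - 0.5) / (rho[k - 1] - rho[k])
    dt = float(speeds.times[1] - speeds.times[0]) if len(speeds.times) > 1 else 1.0
    return rho, (k - 1 + frac) * dt


def mean_squared_displacement(
    traj: Trajectory, max_lag: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD; returns (lag_times, msd) with MSD(0) = 0.

    Lags run to a quarter of the trajectory length by default, keeping
    each estimate an average over at least 3/4 of the samples.
    """
    n = len(traj.times)
    if n < 10:
        raise ValueError("need at least 10 samples")
    if max_lag is None:
        max_lag = n // 4
    max_lag = min(max_lag, n - 1)
    r = traj.positions
    msd = np.zeros(max_lag + 1)
    for k in range(1, max_lag + 1):
        d = r[k:] - r[:-k]
        msd[k] = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
    lags = np.arange(max_lag + 1) * traj.sample_interval
    return lags, msd


def furth_fit(lags: np.ndarray, msd: np.ndarray) -> FurthFit:
    """Unweighted nonlinear least squares of Fuerth's formula to an MSD curve.

    Initial guesses come from the diffusive large-lag asymptote
    MSD ~ 4 D_a T - 4 D_a tau_P (slope and intercept of the upper half
    of the lag range).  Raises on non-convergence or parameters pinned
    at the positivity boundary.
    """
    lags = np.asarray(lags, dtype=float)
    msd = np.asarray(msd, dtype=float)
    mask = lags > 0
    if mask.sum() < 10:
        raise ValueError("need at least 10 nonzero lags")
    x, y = lags[mask], msd[mask]
    tail = x >= 0.5 * x.max()
    slope, intercept = np.polyfit(x[tail], y[tail], 1)
    D0 = max(slope / 4.0, 1e-6)
    tau0 = min(max(-intercept / (4.0 * D0), 1e-2), x.max())
    try:
        popt, pcov = optimize.curve_fit(
            furth_msd, x, y, p0=(D0, tau0), bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000
        )
    except RuntimeError as err:
        raise RuntimeError(f"Fuerth fit did not converge: {err}") from err
    if popt[0] < 1e-10 or popt[1] < 1e-10:
        raise RuntimeError("Fuerth fit pinned at the positivity boundary")
    return FurthFit(D_a=float(popt[0]), tau_P=float(popt[1]), covariance=pcov, lags=x)


def prw_generator(
    D_a: float,
    tau_P: float,
    duration: float,
    seed: int | np.random.Generator = 0,
    sample_interval: float = 1.0,
    n_substeps: int = 20,
) -> Trajectory:
    """Persistent random walk with known D_a and tau_P, sampled at 1 Hz.

    The velocity is a 2D Ornstein-Uhlenbeck process with relaxation time
    tau_P and per-component stationary variance D_a / tau_P, whose exact
    ensemble MSD is Fuerth's formula.  Integration uses Euler-Maruyama
    substeps well below tau_P.
    """
    if D_a <= 0 or tau_P <= 0:
        raise ValueError("D_a and tau_P must be positive")
    from scipy.signal import lfilter

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = sample_interval / n_substeps
    n_samples = int(round(duration / sample_interval))
    n_steps = n_samples * n_substeps
    sigma_v2 = D_a / tau_P
    decay = 1.0 - dt / tau_P
    kick = np.sqrt(2.0 * sigma_v2 * dt / tau_P)
    v0 = np.sqrt(sigma_v2) * rng.standard_normal(2)
    noise = kick * rng.standard_normal((n_steps, 2))
    # AR(1) recursion v_k = decay v_{k-1} + kick n_k, vectorized
    v = lfilter([1.0], [1.0, -decay], noise, axis=0)
    v += v0 * decay ** np.arange(1, n_steps + 1)[:, None]
    pos = np.vstack([np.zeros(2), np.cumsum(v * dt, axis=0)])
    out = pos[:: n_substeps]
    times = np.arange(n_samples + 1) * sample_interval
    return Trajectory(times=times, positions=out)


def velocity_histogram(
    trajectories: list[Trajectory] | Trajectory, bins: int = 41
) -> VelocityDistribution:
    """Centered histograms of the velocity components with a Gaussian fit.

    Pools v_x and v_y over all trajectories; the Gaussian fit is the
    maximum-likelihood (mean, std) of v_x.  Positive excess kurtosis
    signals the heavier-than-Gaussian centre and tails characteristic of
    intermittent amoeboid motion.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    vx, vy = [], []
    for tr in trajectories:
        d = np.diff(tr.positions, axis=0) / tr.sample_interval
        vx.append(d[:, 0])
        vy.append(d[:, 1])
    vx = np.concatenate(vx)
    vy = np.concatenate(vy)
    if len(vx) < 1000:
        raise ValueError("need at least 1000 velocity samples")
    lim = max(np.abs(vx).max(), np.abs(vy).max())
    edges = np.linspace(-lim, lim, bins + 1)
    counts_x, _ = np.histogram(vx, edges)
    counts_y, _ = np.histogram(vy, edges)
    mu, sd = float(np.mean(vx)), float(np.std(vx))
    z = (vx - mu) / sd
    p_center = float(np.mean(np.abs(z) < 0.5))
    p_tail = float(np.mean(np.abs(z) > 2.0))
    g_center = stats.norm.cdf(0.5) - stats.norm.cdf(-0.5)
    g_tail = 2.0 * stats.norm.sf(2.0)
    return VelocityDistribution(
        bin_edges=edges,
        counts_x=counts_x,
        counts_y=counts_y,
        mu=mu,
        sigma=sd,
        excess_kurtosis_x=float(stats.kurtosis(vx, fisher=True)),
        excess_kurtosis_y=float(stats.kurtosis(vy, fisher=True)),
        ks_pvalue_xy=float(stats.ks_2samp(vx, vy).pvalue),
        center_excess=p_center / g_center - 1.0,
        tail_excess=p_tail / g_tail - 1.0,
        samples_x=vx,
        samples_y=vy,
    )
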