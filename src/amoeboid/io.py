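"""Run archives, mask stacks and tabular output.

Simulation runs are stored in HDF5 (datasets ``phi``, ``c``, ``times``,
``offsets``, ``com``, ``area``, ``amount``, ``delta``; the full
configuration as a YAML attribute).  Phase-field and concentration
frames can also be exported as 8-bit TIFF stacks for interoperability
with imaging tools, and mask stacks from such tools can be loaded back
into a snapshot series for the contour pipeline.  Trajectories and
kymographs round-trip through plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .engine import SimulationConfig, SnapshotSeries
from .grid import GridSpec
from .motility import Trajectory
from .noise import NoiseParams
from .phasefield import PhaseFieldParams
from .polarity import BiochemParams
from .contour import Kymograph

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "save_run",
    "load_run",
    "export_tiff",
    "load_mask_stack",
    "save_trajectory",
    "load_trajectory",
    "save_kymograph",
]


def config_to_dict(config: SimulationConfig) -> dict:
    """Flatten a SimulationConfig into a YAML-friendly dict of parameter names."""
    p, b, nz, g = config.phase, config.biochem, config.noise, config.grid
    return {
        "tau": p.tau,
        "gamma": p.gamma,
        "epsilon": p.epsilon,
        "beta": p.beta,
        "A_o": p.A_o,
        "alpha": p.alpha,
        "k_a": b.k_a,
        "delta_o": b.delta_o,
        "C_o": b.C_o,
        "M": b.M,
        "rho": b.rho,
        "D": b.D,
        "sigma": nz.sigma,
        "k_eta": nz.k_eta,
        "nx": g.nx,
        "ny": g.ny,
        "dx": g.dx,
        "dt": g.dt,
        "duration": config.duration,
        "burn_in": config.burn_in,
        "snapshot_interval": config.snapshot_interval,
        "recenter_threshold": config.recenter_threshold,
        "seed": config.seed,
        "store_fields": config.store_fields,
        "c_init": config.c_init,
        "k_a_ramp": config.k_a_ramp,
    }


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    phase = PhaseFieldParams(
        **{k: d.pop(k) for k in ("tau", "gamma", "epsilon", "beta", "A_o", "alpha") if k in d}
    )
    biochem = BiochemParams(
        **{k: d.pop(k) for k in ("k_a", "delta_o", "C_o", "M", "rho", "D") if k in d}
    )
    noise = NoiseParams(**{k: d.pop(k) for k in ("sigma", "k_eta") if k in d})
    grid = GridSpec(**{k: d.pop(k) for k in ("nx", "ny", "dx", "dt") if k in d})
    return SimulationConfig(phase=phase, biochem=biochem, noise=noise, grid=grid, **d)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def save_run(snapshots: SnapshotSeries, path: str | Path) -> None:
    """Write a snapshot series to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.attrs["config"] = yaml.safe_dump(config_to_dict(snapshots.config))
        fh.attrs["seed"] = snapshots.seed
        from . import __version__

        fh.attrs["code_version"] = __version__
        for name in ("times", "com", "offsets", "area", "amount", "delta"):
            fh.create_dataset(name, data=getattr(snapshots, name))
        if snapshots.phi is not None:
            fh.create_dataset("phi", data=snapshots.phi, compression="gzip", shuffle=True)
        if snapshots.c is not None:
            fh.create_dataset("c", data=snapshots.c, compression="gzip", shuffle=True)


def load_run(path: str | Path) -> SnapshotSeries:
    with h5py.File(path, "r") as fh:
        config = config_from_dict(yaml.safe_load(fh.attrs["config"]))
        return SnapshotSeries(
            times=fh["times"][:],
            com=fh["com"][:],
            offsets=fh["offsets"][:],
            area=fh["area"][:],
            amount=fh["amount"][:],
            delta=fh["delta"][:],
            phi=fh["phi"][:] if "phi" in fh else None,
            c=fh["c"][:] if "c" in fh else None,
            config=config,
            seed=int(fh.attrs["seed"]),
        )


def export_tiff(snapshots: SnapshotSeries, phi_path: str | Path, c_path: str | Path | None = None) -> None:
    """Export phi (and optionally c) frames as 8-bit TIFF stacks.

    phi maps [0, 1] onto [0, 255]; c is scaled by its global maximum.
    The sub-pixel contour information degrades to ~dx after the 8-bit
    round trip, which the analysis tolerances accommodate.
    """
    if snapshots.phi is None:
        raise ValueError("snapshot series has no stored fields")
    phi8 = np.clip(snapshots.phi * 255.0, 0, 255).astype(np.uint8)
    tifffile.imwrite(phi_path, phi8)
    if c_path is not None:
        if snapshots.c is None:
            raise ValueError("snapshot series has no stored c field")
        cmax = float(snapshots.c.max()) or 1.0
        c8 = np.clip(snapshots.c / cmax * 255.0, 0, 255).astype(np.uint8)
        tifffile.imwrite(c_path, c8)


def load_mask_stack(
    path: str | Path, grid: GridSpec, frame_interval: float = 1.0
) -> SnapshotSeries:
    """Load an 8-bit TIFF stack as a phi snapshot series (values scaled to [0, 1])."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    phi = stack.astype(np.float32) / 255.0
    n = len(phi)
    config = SimulationConfig(grid=grid, duration=n * frame_interval, burn_in=0.0)
    zeros = np.zeros((n, 2))
    return SnapshotSeries(
        times=np.arange(n) * frame_interval,
        com=zeros.copy(),
        offsets=zeros.copy(),
        area=np.zeros(n),
        amount=np.zeros(n),
        delta=np.zeros(n),
        phi=phi,
        c=None,
        config=config,
        seed=0,
    )


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": traj.times, "x_um": traj.positions[:, 0], "y_um": traj.positions[:, 1]}
    ).to_csv(path, index=False)


def load_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(times=df["time_s"].to_numpy(), positions=df[["x_um", "y_um"]].to_numpy())


def save_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """CSV matrix: rows are node indices, columns are frame times."""
    df = pd.DataFrame(kymo.matrix, columns=[f"{t:.3f}" for t in kymo.times])
    df.index.name = "node"
    df.to_csv(path)
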