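"""File export: CSV tables, XYZ trajectories, optional HDF5 container.

All text output is comma-separated, header row, UTF-8, LF, floats printed
with 9 significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Trajectory
from .profiles import DiffusionProfile

FLOAT_FMT = "%.9g"

__all__ = ["write_trajectory_csv", "write_trajectory_h5", "write_xyz",
           "write_profile_csv", "write_table"]


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")
    return path


def trajectory_frame(traj: Trajectory, bleached=None) -> pd.DataFrame:
    """Long-format table: time, id, x[, y][, bleached]."""
    S, N, dim = traj.positions.shape
    cols = {
        "time": np.repeat(traj.times, N),
        "id": np.tile(np.arange(N), S),
        "x": traj.positions[..., 0].ravel(),
    }
    if dim == 2:
        cols["y"] = traj.positions[..., 1].ravel()
    if bleached is not None:
        cols["bleached"] = np.tile(np.asarray(bleached, dtype=int), S)
    return pd.DataFrame(cols)


def write_trajectory_csv(traj: Trajectory, path, bleached=None) -> Path:
    return write_table(trajectory_frame(traj, bleached), path)


def write_trajectory_h5(traj: Trajectory, path, bleached=None) -> Path:
    """Same schema as the CSV export, in an HDF5 container (needs h5py)."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("positions", data=traj.positions)
        if bleached is not None:
            f.create_dataset("bleached", data=np.asarray(bleached, dtype=bool))
        f.attrs["seed"] = traj.config.seed
        f.attrs["dt"] = traj.config.dt
    return path


def write_xyz(traj: Trajectory, path, bleached=None) -> Path:
    """XYZ-format export for molecular viewers, one frame per sample; the
    particle type column encodes the bleach state (C fluorescent, B bleached).
    2D positions get z = 0."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    S, N, dim = traj.positions.shape
    types = np.array(["C"] * N)
    if bleached is not None:
        types = np.where(np.asarray(bleached, dtype=bool), "B", "C")
    with open(path, "w", newline="\n") as fh:
        for s in range(S):
            fh.write(f"{N}\n")
            fh.write(f"t={traj.times[s]:.9g}\n")
            for i in range(N):
                x = traj.positions[s, i, 0]
                y = traj.positions[s, i, 1] if dim == 2 else 0.0
                fh.write(f"{types[i]} {x:.9g} {y:.9g} 0\n")
    return path


def write_profile_csv(profile: DiffusionProfile, path, n: int = 256) -> Path:
    """Sample the field on a regular grid: x[, y], amplitude, diffusion."""
    L = profile.L
    if profile.dim == 1:
        x = np.linspace(-L, L, n, endpoint=False)
        a = profile.amplitude(x)
        df = pd.DataFrame({"x": x, "amplitude": a, "diffusion": a ** 2})
    else:
        ax = np.linspace(-L, L, n, endpoint=False)
        X, Y = np.meshgrid(ax, ax, indexing="ij")
        pts = np.stack([X, Y], axis=-1)
        a = profile.amplitude(pts)
        df = pd.DataFrame({"x": X.ravel(), "y": Y.ravel(),
                           "amplitude": a.ravel(), "diffusion": (a ** 2).ravel()})
    return write_table(df, path)
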