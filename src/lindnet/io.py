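"""Artifact I/O: HDF5 trajectory/dataset stores, CSV exports, atomic writes.

Layouts
-------
Trajectory store (HDF5)::

    /site{m}/lam{lam}_gam{gamma}_T{T}/
        time  float64 (N,)      fs
        rho   complex128 (N,7,7)
        rho_inf  complex128 (7,7)   stationary state
        attrs: lam, gamma, temperature, site, t_M, dt, convention, version

Dataset file (HDF5)::

    /X float32 (N,105), /Y float32 (N,13),
    /prov  compound (point_id, time_fs [-1 = infinity], row)
    attrs: meta (JSON string: norms, feature order, schedule, g_th, splits)

All writers go through a temp-file + rename so a crashed run never leaves a
partial artifact behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .dataset import GridPoint
from .lindblad import DensityTrajectory

__all__ = [
    "atomic_write",
    "save_trajectories",
    "load_trajectories",
    "save_dataset",
    "load_dataset",
    "populations_to_csv",
]


@contextmanager
def atomic_write(path):
    """Yield a temp path in the target directory; rename into place on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix + ".tmp")
    os.close(fd)
    try:
        yield tmp
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _group_name(point: GridPoint) -> str:
    return (
        f"site{point.site}/lam{point.lam:g}_gam{point.gamma:g}_T{point.temperature:g}"
    )


def save_trajectories(path, records, *, config_hash: str = "") -> None:
    """Write (point, times, states, rho_inf, t_M, meta) records to one HDF5 file."""
    with atomic_write(path) as tmp:
        with h5py.File(tmp, "w") as f:
            f.attrs["version"] = __version__
            f.attrs["config_hash"] = config_hash
            for point, times, states, rho_inf, t_M, meta in records:
                g = f.create_group(_group_name(point))
                g.create_dataset("time", data=np.asarray(times, dtype=float))
                g.create_dataset("rho", data=np.asarray(states, dtype=complex))
                g.create_dataset("rho_inf", data=np.asarray(rho_inf, dtype=complex))
                g.attrs.update(
                    lam=point.lam,
                    gamma=point.gamma,
                    temperature=point.temperature,
                    site=point.site,
                    t_M=t_M,
                    **{k: v for k, v in meta.items() if v is not None},
                )


def load_trajectories(path):
    """Read records back as (point, times, states, rho_inf, t_M, meta) tuples."""
    out = []
    with h5py.File(path, "r") as f:
        for site_grp in f.values():
            if not isinstance(site_grp, h5py.Group):
                continue
            for g in site_grp.values():
                a = dict(g.attrs)
                point = GridPoint(
                    float(a["lam"]), float(a["gamma"]),
                    float(a["temperature"]), int(a["site"]),
                )
                meta = {
                    k: v for k, v in a.items()
                    if k not in ("lam", "gamma", "temperature", "site", "t_M")
                }
                out.append(
                    (point, g["time"][()], g["rho"][()], g["rho_inf"][()],
                     float(a["t_M"]), meta)
                )
    out.sort(key=lambda r: (r[0].site, r[0].lam, r[0].gamma, r[0].temperature))
    return out


_PROV_DTYPE = np.dtype([("point_id", "i4"), ("time_fs", "f8"), ("row", "i4")])


def save_dataset(path, X, Y, prov, meta: dict, *, config_hash: str = "") -> None:
    with atomic_write(path) as tmp:
        with h5py.File(tmp, "w") as f:
            f.create_dataset("X", data=np.asarray(X, dtype=np.float32))
            f.create_dataset("Y", data=np.asarray(Y, dtype=np.float32))
            f.create_dataset("prov", data=np.asarray(prov, dtype=_PROV_DTYPE))
            f.attrs["meta"] = json.dumps(meta)
            f.attrs["version"] = __version__
            f.attrs["config_hash"] = config_hash


def load_dataset(path):
    with h5py.File(path, "r") as f:
        X = f["X"][()]
        Y = f["Y"][()]
        prov = f["prov"][()]
        meta = json.loads(f.attrs["meta"])
        meta["config_hash"] = f.attrs.get("config_hash", "")
    return X, Y, prov, meta


def populations_to_csv(traj: DensityTrajectory, path) -> None:
    """Export (t, rho_11..rho_77) for plotting."""
    pops = traj.populations
    df = pd.DataFrame(pops, columns=[f"rho_{n}{n}" for n in range(1, 8)])
    df.insert(0, "time_fs", traj.times)
    with atomic_write(path) as tmp:
        df.to_csv(tmp, index=False)
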