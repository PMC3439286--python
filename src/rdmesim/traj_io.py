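"""Trajectory container I/O (HDF5: /times, /states, /meta).

The layout is open and language-neutral: ``/times`` (T,), ``/states``
(T, M_species, N_voxels), ``/volumes`` (N,), and a ``/meta`` group whose
attributes carry the seed, solver name, species names, a schema version
and an optional JSON provenance record — enough to re-run the
simulation that produced the file.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .trajectory import Trajectory

__all__ = ["save_trajectory", "load_trajectory", "SCHEMA_VERSION", "TrajectoryFormatError"]

SCHEMA_VERSION = 1


class TrajectoryFormatError(RuntimeError):
    pass


def save_trajectory(path, traj: Trajectory, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("states", data=traj.states, compression="gzip", compression_opts=4)
        if traj.volumes is not None:
            f.create_dataset("volumes", data=traj.volumes)
        g = f.create_group("meta")
        g.attrs["schema_version"] = SCHEMA_VERSION
        g.attrs["seed"] = traj.seed
        g.attrs["solver"] = traj.solver
        g.attrs["species"] = json.dumps(traj.species_names)
        g.attrs["event_counts"] = json.dumps(traj.event_counts)
        if meta:
            g.attrs["provenance"] = json.dumps(meta, default=str)


def load_trajectory(path) -> Trajectory:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if "meta" not in f or "states" not in f or "times" not in f:
                raise TrajectoryFormatError(f"{path}: not a trajectory container")
            g = f["meta"]
            version = int(g.attrs.get("schema_version", -1))
            if version != SCHEMA_VERSION:
                raise TrajectoryFormatError(
                    f"{path}: schema version {version}, this build reads {SCHEMA_VERSION}"
                )
            return Trajectory(
                times=f["times"][...],
                states=f["states"][...],
                species_names=json.loads(g.attrs["species"]),
                seed=int(g.attrs["seed"]),
                solver=str(g.attrs["solver"]),
                event_counts=json.loads(g.attrs.get("event_counts", "{}")),
                volumes=f["volumes"][...] if "volumes" in f else None,
            )
    except OSError as e:
        raise TrajectoryFormatError(f"{path}: corrupt or not an HDF5 file ({e})") from None


def load_provenance(path) -> dict:
    with h5py.File(path, "r") as f:
        return json.loads(f["meta"].attrs.get("provenance", "{}"))
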