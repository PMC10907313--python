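"""Native trajectory dialect: plain-text CSV, self-describing and diffable.

A trajectory directory holds three files:

``meta.json``
    ``{"box": [Lx, Ly, Lz], "periodic": bool, "n_frames": int, "n_particles": int}``
``particles.csv``
    the annotation table, one row per particle (columns particle_id, kind,
    residue_index, lipid_index, lipid_species, atom_class).
``coords.csv``
    frame-major wide layout: one row per frame, first column ``time`` (ns),
    then ``x<i>,y<i>,z<i>`` for particle i in table order (nm).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory_sim import Trajectory

__all__ = ["write_trajectory", "read_trajectory"]


def write_trajectory(traj: Trajectory, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = dict(box=list(traj.box), periodic=bool(traj.periodic),
                n_frames=int(traj.n_frames), n_particles=int(len(traj.particles)))
    (directory / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    traj.particles.to_csv(directory / "particles.csv", index=False)

    n_particles = traj.coords.shape[1]
    cols = ["time"] + [f"{ax}{i}" for i in range(n_particles) for ax in "xyz"]
    flat = traj.coords.reshape(traj.n_frames, n_particles * 3)
    df = pd.DataFrame(np.column_stack([traj.times, flat]), columns=cols)
    df.to_csv(directory / "coords.csv", index=False, float_format="%.6f")
    return directory


def read_trajectory(directory) -> Trajectory:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    particles = pd.read_csv(directory / "particles.csv",
                            keep_default_na=False, na_values=[])
    df = pd.read_csv(directory / "coords.csv")
    times = df["time"].to_numpy(dtype=float)
    coords = df.drop(columns="time").to_numpy(dtype=float)
    coords = coords.reshape(len(times), meta["n_particles"], 3)
    return Trajectory(times=times, coords=coords, particles=particles,
                      box=tuple(meta["box"]), periodic=bool(meta["periodic"]))
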