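"""Trajectory and thermo-series I/O.

Frames can be written as plain multi-frame GRO (text) or XTC (via
MDAnalysis); the thermo series goes to CSV with a documented header
(time_ps, T_K, E_pot_kJmol).  Reading accepts either format and returns the
engine's in-memory Trajectory.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .build import MolecularSystem
from .engine import Trajectory
from .gromacs import write_gro

__all__ = [
    "write_gro_trajectory",
    "read_gro_trajectory",
    "write_xtc",
    "read_trajectory",
    "write_thermo_csv",
    "read_thermo_csv",
]

THERMO_COLUMNS = ("time_ps", "T_K", "E_pot_kJmol")


def write_gro_trajectory(path, traj: Trajectory, system: MolecularSystem) -> None:
    """Multi-frame GRO: concatenated frames, time recorded in each title line."""
    import dataclasses

    with open(path, "w") as fh:
        for t, coords, box in zip(traj.times, traj.coordinates, traj.boxes):
            frame_sys = dataclasses.replace(
                system, coordinates=np.asarray(coords), box=np.asarray(box)
            )
            _write_gro_into(fh, frame_sys, title=f"frame t= {t:.3f} ps")


def _write_gro_into(fh, system: MolecularSystem, title: str) -> None:
    from .gromacs import _atomname, _resname

    fh.write(f"{title}\n{system.n_beads}\n")
    for i in range(system.n_beads):
        t = str(system.bead_types[i])
        x, y, z = system.coordinates[i]
        fh.write(
            f"{(i % 99999) + 1:5d}{_resname(t):<5s}{_atomname(t):>5s}{(i % 99999) + 1:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
        )
    fh.write(f"{system.box[0]:10.5f}{system.box[1]:10.5f}{system.box[2]:10.5f}\n")


def read_gro_trajectory(path) -> Trajectory:
    traj = Trajectory()
    with open(path) as fh:
        while True:
            title = fh.readline()
            if not title:
                break
            n = int(fh.readline())
            coords = np.empty((n, 3))
            for i in range(n):
                line = fh.readline()
                coords[i] = (float(line[20:28]), float(line[28:36]), float(line[36:44]))
            box = np.array([float(v) for v in fh.readline().split()[:3]])
            t = _parse_time(title, default=float(traj.n_frames))
            traj.add_frame(t, coords, box)
    return traj


def _parse_time(title: str, default: float) -> float:
    if "t=" in title:
        try:
            return float(title.split("t=")[1].split()[0])
        except (ValueError, IndexError):
            pass
    return default


def write_xtc(path, traj: Trajectory) -> None:
    """Compressed XTC trajectory via MDAnalysis."""
    import MDAnalysis as mda

    n = len(traj.coordinates[0])
    u = mda.Universe.empty(n, trajectory=True)
    with mda.Writer(str(path), n) as w:
        for t, coords, box in zip(traj.times, traj.coordinates, traj.boxes):
            u.atoms.positions = np.asarray(coords) * 10.0  # nm -> Angstrom
            u.dimensions = [box[0] * 10, box[1] * 10, box[2] * 10, 90, 90, 90]
            u.trajectory.ts.time = t
            w.write(u.atoms)
    return None


def read_trajectory(topology_gro, xtc_path=None) -> Trajectory:
    """Read GRO (+ optional XTC) into a Trajectory, converting to nm/ps."""
    if xtc_path is None:
        return read_gro_trajectory(topology_gro)
    import MDAnalysis as mda

    u = mda.Universe(str(topology_gro), str(xtc_path))
    traj = Trajectory()
    last_t = -np.inf
    for ts in u.trajectory:
        t = float(ts.time)
        if t <= last_t:  # some writers stamp 0 everywhere
            t = last_t + 1.0
        last_t = t
        traj.add_frame(t, ts.positions / 10.0, np.asarray(ts.dimensions[:3]) / 10.0)
    return traj


def write_thermo_csv(path, traj: Trajectory) -> None:
    pd.DataFrame(
        {
            THERMO_COLUMNS[0]: traj.thermo_times,
            THERMO_COLUMNS[1]: traj.thermo_temperature,
            THERMO_COLUMNS[2]: traj.thermo_potential,
        }
    ).to_csv(path, index=False)


def read_thermo_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(THERMO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"thermo CSV missing columns: {sorted(missing)}")
    return df
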