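"""GROMACS-dialect writers (GRO / TOP / ITP / MDP) and round-trip readers.

The exporters let the at-scale slab protocol run on an external MD engine:
coordinates go to a fixed-column GRO file, the model's topology to TOP/ITP
files (atoms, bonds, angles, dihedrals, exclusions, nonbonded pair table),
and the run settings for each protocol stage to MDP files.  Only this
framework's own dialect is parsed back; these are not general-purpose
GROMACS topology readers.

GROMACS unit conventions: nm, ps, kJ/mol, amu, K, bar.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .build import MolecularSystem
from .model import ForceFieldParams

__all__ = [
    "write_gro",
    "read_gro",
    "write_pdb",
    "write_topology",
    "read_topology_counts",
    "write_mdp",
    "mdp_settings",
    "export_gromacs",
    "import_gromacs",
]

_RESNAMES = {"BB": "COI", "LNK": "LNK"}


def _resname(bead_type: str) -> str:
    if bead_type.startswith("STY"):
        return "STY"
    return _RESNAMES.get(bead_type, "CGB")


def _atomname(bead_type: str) -> str:
    return "CA"


def write_gro(path, system: MolecularSystem, title: str = "coilslab CG system") -> None:
    """Fixed-column GRO coordinate file (positions in nm, no velocities)."""
    if system.n_beads == 0:
        raise ValueError("refusing to write a system with zero beads")
    with open(path, "w") as fh:
        fh.write(f"{title}\n{system.n_beads}\n")
        for i in range(system.n_beads):
            t = str(system.bead_types[i])
            resnr = (i % 99999) + 1
            atnr = (i % 99999) + 1
            x, y, z = system.coordinates[i]
            fh.write(
                f"{resnr:5d}{_resname(t):<5s}{_atomname(t):>5s}{atnr:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        fh.write(f"{system.box[0]:10.5f}{system.box[1]:10.5f}{system.box[2]:10.5f}\n")


def read_gro(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a GRO file -> (coordinates (n,3), box (3,), residue names)."""
    with open(path) as fh:
        fh.readline()
        n = int(fh.readline())
        coords = np.empty((n, 3))
        resnames = []
        for i in range(n):
            line = fh.readline()
            resnames.append(line[5:10].strip())
            coords[i] = (float(line[20:28]), float(line[28:36]), float(line[36:44]))
        box = np.array([float(v) for v in fh.readline().split()[:3]])
    return coords, box, resnames


def write_pdb(path, system: MolecularSystem) -> None:
    """Minimal PDB for visualization (coordinates in Angstrom)."""
    with open(path, "w") as fh:
        bx = system.box * 10.0
        fh.write(
            f"CRYST1{bx[0]:9.3f}{bx[1]:9.3f}{bx[2]:9.3f}  90.00  90.00  90.00 P 1           1\n"
        )
        for i in range(system.n_beads):
            t = str(system.bead_types[i])
            x, y, z = system.coordinates[i] * 10.0
            fh.write(
                f"ATOM  {(i % 99999) + 1:5d}  CA  {_resname(t):<3s} A{(i % 9999) + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def _chain_groups(system: MolecularSystem):
    """Group chains by identical bead-type sequence -> [(indices of one
    representative chain, count)]."""
    groups: dict[tuple, list[int]] = {}
    for cid in np.unique(system.chain_ids):
        mask = system.chain_ids == cid
        key = tuple(system.bead_types[mask])
        groups.setdefault(key, []).append(int(cid))
    out = []
    for key, cids in groups.items():
        rep = np.where(system.chain_ids == cids[0])[0]
        out.append((rep, len(cids)))
    return out


def write_topology(topdir, system: MolecularSystem, ff: ForceFieldParams, name: str = "ccsys") -> dict:
    """Write topol.top + force-field and molecule ITP files.

    The nonbonded pair table implements the maximally specific scheme
    explicitly: only identical sticky types get the attractive epsilon.
    Intra-chain pairs of the same sticky type are listed under [exclusions]
    so coil-coil attraction stays interchain-only.  Returns a manifest of
    written files.
    """
    os.makedirs(topdir, exist_ok=True)
    types = sorted(set(str(t) for t in system.bead_types))
    ff_itp = os.path.join(topdir, "coilslab_ff.itp")
    with open(ff_itp, "w") as fh:
        fh.write("[ defaults ]\n; nbfunc comb-rule gen-pairs fudgeLJ fudgeQQ\n1 2 no 1.0 1.0\n\n")
        fh.write("[ atomtypes ]\n; name mass charge ptype sigma epsilon\n")
        for t in types:
            fh.write(f"{t:<10s} {ff.mass:9.3f} 0.000 A {ff.sigma:8.4f} {ff.epsilon_repulsive:8.4f}\n")
        fh.write("\n[ nonbond_params ]\n; i j func sigma epsilon\n")
        for a in range(len(types)):
            for b in range(a, len(types)):
                ti, tj = types[a], types[b]
                attractive = ti == tj and ti.startswith("STY")
                eps = ff.epsilon_coil if attractive else ff.epsilon_repulsive
                fh.write(f"{ti:<10s} {tj:<10s} 1 {ff.sigma:8.4f} {eps:8.4f}\n")

    mol_files = []
    mol_entries = []
    for gi, (rep, count) in enumerate(_chain_groups(system)):
        molname = f"{name}_mol{gi}"
        path = os.path.join(topdir, f"{molname}.itp")
        mol_files.append(path)
        mol_entries.append((molname, count))
        local = {int(g): k for k, g in enumerate(rep)}
        inmol = np.zeros(system.n_beads, dtype=bool)
        inmol[rep] = True
        bp = ff.bonded
        with open(path, "w") as fh:
            fh.write(f"[ moleculetype ]\n; name nrexcl\n{molname} 2\n\n")
            fh.write("[ atoms ]\n; nr type resnr residue atom cgnr charge mass\n")
            for k, g in enumerate(rep):
                t = str(system.bead_types[g])
                fh.write(
                    f"{k + 1:6d} {t:<10s} {k + 1:6d} {_resname(t):<5s} CA {k + 1:6d} 0.000 {ff.mass:9.3f}\n"
                )
            fh.write("\n[ bonds ]\n; i j func b0 kb\n")
            for b, (i, j) in enumerate(system.bonds):
                if inmol[i] and inmol[j]:
                    terms = bp.coil if system.bonds_in_coil[b] else bp.linker
                    fh.write(
                        f"{local[i] + 1:6d} {local[j] + 1:6d} 1 {terms.bond_r0:8.4f} {terms.bond_k:12.2f}\n"
                    )
            fh.write("\n[ angles ]\n; i j k func th0 kth\n")
            for a, (i, j, k2) in enumerate(system.angles):
                if inmol[i] and inmol[j] and inmol[k2]:
                    terms = bp.coil if system.angles_in_coil[a] else bp.linker
                    fh.write(
                        f"{local[i] + 1:6d} {local[j] + 1:6d} {local[k2] + 1:6d} 1 "
                        f"{terms.angle_theta0:8.3f} {terms.angle_k:12.2f}\n"
                    )
            fh.write("\n[ dihedrals ]\n; i j k l func phi_s k mult\n")
            for t, (i, j, k2, l) in enumerate(system.torsions):
                if inmol[i] and inmol[j] and inmol[k2] and inmol[l]:
                    terms = bp.coil if system.torsions_in_coil[t] else bp.linker
                    phi_s = terms.torsion_mult * terms.torsion_phi0 - 180.0
                    fh.write(
                        f"{local[i] + 1:6d} {local[j] + 1:6d} {local[k2] + 1:6d} {local[l] + 1:6d} 1 "
                        f"{phi_s:8.3f} {terms.torsion_k:10.3f} {terms.torsion_mult:3d}\n"
                    )
            # interchain-only attraction: exclude intra-chain same-type sticky pairs
            fh.write("\n[ exclusions ]\n")
            sticky_idx = [g for g in rep if str(system.bead_types[g]).startswith("STY")]
            for ii, g in enumerate(sticky_idx):
                partners = [
                    local[h] + 1
                    for h in sticky_idx[ii + 1 :]
                    if system.bead_types[h] == system.bead_types[g]
                ]
                if partners:
                    fh.write(f"{local[g] + 1:6d} " + " ".join(str(p) for p in partners) + "\n")

    top = os.path.join(topdir, "topol.top")
    with open(top, "w") as fh:
        fh.write('#include "coilslab_ff.itp"\n')
        for p in mol_files:
            fh.write(f'#include "{os.path.basename(p)}"\n')
        fh.write(f"\n[ system ]\n{name}\n\n[ molecules ]\n; name count\n")
        for molname, count in mol_entries:
            fh.write(f"{molname} {count}\n")
    return {"top": top, "forcefield": ff_itp, "molecules": mol_files}


def read_topology_counts(topdir) -> dict:
    """Parse this dialect's topol.top tree -> total atom/bond/angle/dihedral counts."""
    top = os.path.join(topdir, "topol.top")
    mols: dict[str, dict] = {}
    counts: list[tuple[str, int]] = []
    includes = []
    with open(top) as fh:
        section = None
        for line in fh:
            line = line.strip()
            if line.startswith("#include"):
                includes.append(line.split('"')[1])
            elif line.startswith("["):
                section = line.strip("[] ").lower()
            elif section == "molecules" and line and not line.startswith(";"):
                nm, cnt = line.split()
                counts.append((nm, int(cnt)))
    for inc in includes:
        path = os.path.join(topdir, inc)
        section = None
        current = None
        with open(path) as fh:
            for line in fh:
                line = line.split(";")[0].strip()
                if not line:
                    continue
                if line.startswith("["):
                    section = line.strip("[] ").lower()
                    continue
                if section == "moleculetype":
                    current = line.split()[0]
                    mols[current] = {"atoms": 0, "bonds": 0, "angles": 0, "dihedrals": 0}
                elif current and section in mols[current]:
                    mols[current][section] += 1
    totals = {"atoms": 0, "bonds": 0, "angles": 0, "dihedrals": 0}
    for nm, cnt in counts:
        for key in totals:
            totals[key] += cnt * mols[nm][key]
    totals["molecules"] = sum(c for _, c in counts)
    return totals


# ---------------------------------------------------------------------------
# Run-parameter (MDP) files
# ---------------------------------------------------------------------------

#: shared neighbor/cutoff/output settings for every stage
_COMMON_MDP = {
    "cutoff-scheme": "Verlet",
    "verlet-buffer-tolerance": "1e-7",
    "nstlist": "20",
    "rlist": "1.1",
    "vdw-type": "Cut-off",
    "vdw-modifier": "Potential-shift",
    "rvdw": "1.1",
    "coulombtype": "Cut-off",
    "rcoulomb": "1.1",
    "pbc": "xyz",
    "nstxout-compressed": "50000",
    "nstenergy": "50000",
    "nstlog": "50000",
}


def mdp_settings(stage: str, temperature: float = 293.0, nsteps: int | None = None, dt: float | None = None) -> dict:
    """MDP key/value settings for one protocol stage.

    Stages: ``minimize`` (steepest descent to <50 kJ/mol/nm, 2 pm steps),
    ``npt`` (slab formation: 200 ns, dt 20 fs, 150 K, z-only semi-isotropic
    Parrinello-Rahman at 1 bar, compressibility 3e-4 1/bar, tau 5 ps),
    ``nvt`` (equilibration: 200 ns, dt 20 fs at the target temperature) and
    ``production`` (20 us, dt 25 fs).  Dynamics use the sd integrator with a
    friction of 0.2 1/ps (tau-t = 5 ps) and COM-motion removal every 10
    steps.
    """
    mdp = dict(_COMMON_MDP)
    if stage == "minimize":
        mdp.update(
            {"integrator": "steep", "emtol": "50", "emstep": "0.002", "nsteps": "100000"}
        )
        return mdp
    defaults = {
        "npt": (0.020, int(round(200_000 / 0.020))),  # 200 ns
        "nvt": (0.020, int(round(200_000 / 0.020))),  # 200 ns
        "production": (0.025, int(round(20_000_000 / 0.025))),  # 20 us
    }
    if stage not in defaults:
        raise ValueError(f"unknown stage {stage!r}")
    d_dt, d_nsteps = defaults[stage]
    dt = d_dt if dt is None else dt
    nsteps = d_nsteps if nsteps is None else nsteps
    ref_t = 150.0 if stage == "npt" else temperature
    mdp.update(
        {
            "integrator": "sd",
            "dt": f"{dt:g}",
            "nsteps": str(int(nsteps)),
            "tc-grps": "System",
            "tau-t": "5.0",  # inverse of the 0.2 1/ps friction
            "ref-t": f"{ref_t:g}",
            "gen-vel": "yes",
            "gen-temp": f"{ref_t:g}",
            "comm-mode": "Linear",
            "nstcomm": "10",
        }
    )
    if stage == "npt":
        mdp.update(
            {
                "pcoupl": "Parrinello-Rahman",
                "pcoupltype": "semiisotropic",
                "tau-p": "5.0",
                "ref-p": "1.0 1.0",
                "compressibility": "0 3e-4",
            }
        )
    return mdp


def write_mdp(path, settings: dict) -> None:
    with open(path, "w") as fh:
        for key, val in settings.items():
            fh.write(f"{key:<26s} = {val}\n")


def export_gromacs(
    outdir,
    system: MolecularSystem,
    ff: ForceFieldParams,
    stages: dict | None = None,
    name: str = "ccsys",
) -> dict:
    """Write a complete run bundle: conf.gro, topology, and per-stage MDP files.

    ``stages`` maps stage name -> kwargs for :func:`mdp_settings`; defaults
    to the full slab protocol (minimize / npt / nvt / production).  Returns a
    manifest dict of written paths.
    """
    if system.n_beads == 0:
        raise ValueError("refusing to export a system with zero beads")
    os.makedirs(outdir, exist_ok=True)
    gro = os.path.join(outdir, "conf.gro")
    write_gro(gro, system, title=name)
    manifest = {"gro": gro}
    manifest.update(write_topology(outdir, system, ff, name=name))
    if stages is None:
        stages = {"minimize": {}, "npt": {}, "nvt": {}, "production": {}}
    manifest["mdp"] = {}
    for stage, kwargs in stages.items():
        path = os.path.join(outdir, f"{stage}.mdp")
        write_mdp(path, mdp_settings(stage, **kwargs))
        manifest["mdp"][stage] = path
    return manifest


def import_gromacs(outdir) -> dict:
    """Re-import an exported bundle for consistency checks.

    Returns bead count and box from conf.gro plus bonded-term totals from
    the topology; used to verify that export round-trips exactly.
    """
    coords, box, _ = read_gro(os.path.join(outdir, "conf.gro"))
    counts = read_topology_counts(outdir)
    return {"n_beads": len(coords), "box": box, "coordinates": coords, **counts}
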