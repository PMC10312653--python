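"""Slab phase-coexistence protocol orchestration.

The slab pipeline: single-molecule equilibration runs, random selection of
equilibrated conformations, packing to a standardized coil budget,
NPT-style z-compression into a slab, box expansion (keeping the slab
centered, molecules whole), NVT equilibration, production, and equilibration
detection on center/edge density time series.

At-scale runs (20 us, 450-coil boxes) are prepared as exported GROMACS-format
bundles; the internal engine drives the same pipeline at desk scale.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .build import MolecularSystem, pack_slab_box, unwrap_molecules
from .engine import IntegratorSettings, Trajectory, compress_z, minimize, run_langevin
from .gromacs import export_gromacs
from .model import ForceFieldParams, ProteinSpec

__all__ = [
    "SlabRunPlan",
    "DensityTimeSeries",
    "select_configurations",
    "expand_z",
    "prepare_slab_run",
    "detect_equilibration",
    "density_timeseries",
    "run_desk_slab",
]

#: study temperatures (K) for the slab protocol
DEFAULT_TEMPERATURES = (253.0, 273.0, 293.0, 313.0)


@dataclass(frozen=True)
class SlabRunPlan:
    """Per-stage settings of the slab protocol for one protein.

    The defaults encode the at-scale protocol: pack into 25x25x100 nm, NPT
    compression for 200 ns (dt 20 fs) at 150 K, expansion to z = 150 nm, NVT
    equilibration for 200 ns (dt 20 fs) at the target temperature, and 20 us
    production at dt 25 fs, three replicates at 253/273/293/313 K.
    """

    protein: ProteinSpec
    temperatures: tuple = DEFAULT_TEMPERATURES
    replicates: int = 3
    coil_budget: int = 450
    pack_box: tuple = (25.0, 25.0, 100.0)
    pack_tolerance: float = 1.0
    final_z: float = 150.0
    npt_ns: float = 200.0
    npt_dt: float = 0.020
    npt_temperature: float = 150.0
    nvt_ns: float = 200.0
    nvt_dt: float = 0.020
    production_us: float = 20.0
    production_dt: float = 0.025
    rdd: float = 1.6  # nm, domain-decomposition minimum cell size
    base_seed: int = 0
    scaled_down: bool = False

    def seed_for(self, temperature: float, replicate: int) -> int:
        ti = list(self.temperatures).index(temperature)
        return (self.base_seed * 7919 + ti * 101 + replicate * 13 + 1) % (2**31 - 1)


def desk_scale_plan(protein: ProteinSpec, **overrides) -> SlabRunPlan:
    """Scaled-down preset for the internal engine (labeled as such)."""
    defaults = dict(
        coil_budget=18,
        pack_box=(10.0, 10.0, 40.0),
        final_z=40.0,
        npt_ns=0.5,
        nvt_ns=1.0,
        production_us=0.008,
        replicates=1,
        scaled_down=True,
    )
    defaults.update(overrides)
    return SlabRunPlan(protein=protein, **defaults)


# ---------------------------------------------------------------------------
# Configuration selection
# ---------------------------------------------------------------------------

def select_configurations(
    traj: Trajectory,
    n: int = 5,
    t_equil: float = 100_000.0,
    rng_seed: int = 0,
) -> list[np.ndarray]:
    """Randomly select ``n`` distinct equilibrated frames (time >= t_equil).

    Mirrors the standard mitigation of configurational bias: the slab box is
    packed from several conformations drawn from the equilibrated portion of
    a single-molecule run (equilibration is conservatively taken to begin by
    100 ns for the at-scale protocol).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = [i for i, t in enumerate(traj.times) if t >= t_equil]
    if len(idx) < n:
        raise ValueError(
            f"only {len(idx)} frames at t >= {t_equil} ps; need {n} "
            "(extend the run or lower t_equil)"
        )
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(idx, size=n, replace=False)
    return [np.array(traj.coordinates[i]) for i in chosen]


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------

def expand_z(system: MolecularSystem, new_z: float) -> MolecularSystem:
    """Expand the box z-length, keeping the slab centered and molecules whole.

    Molecules are unwrapped via bond connectivity first (so none is split
    across the boundary by the expansion), then rigidly shifted so the
    system's geometric center sits at z = new_z / 2.
    """
    if new_z < system.box[2]:
        raise ValueError("expand_z cannot shrink the box")
    sysu = unwrap_molecules(system)
    coords = sysu.coordinates.copy()
    center = coords[:, 2].mean()
    coords[:, 2] += new_z / 2.0 - center
    box = sysu.box.copy()
    box[2] = new_z
    return replace(sysu, coordinates=coords, box=box)


# ---------------------------------------------------------------------------
# Run-bundle preparation (external engine)
# ---------------------------------------------------------------------------

def prepare_slab_run(
    plan: SlabRunPlan,
    packed: MolecularSystem,
    ff: ForceFieldParams,
    outdir,
) -> dict:
    """Emit per-temperature, per-replicate exported run bundles + manifest.

    Every directory carries the packed coordinates, topology, and MDP files
    for each stage (minimize, NPT at 150 K, NVT and production at the target
    temperature), with distinct pseudo-random seeds per replicate.  The
    manifest (manifest.json) records stages, seeds and files, including the
    mdrun -rdd setting used for domain decomposition at scale.
    """
    n_coils_packed = int(packed.coil_ids.max()) + 1
    expected = (plan.coil_budget // plan.protein.n_coils) * plan.protein.n_coils
    if n_coils_packed != expected:
        raise ValueError(
            f"packed system has {n_coils_packed} coils but the plan expects {expected}"
        )
    os.makedirs(outdir, exist_ok=True)
    manifest = {
        "protein": plan.protein.name,
        "coil_budget": plan.coil_budget,
        "coils_placed": n_coils_packed,
        "final_z_nm": plan.final_z,
        "rdd_nm": plan.rdd,
        "scaled_down": plan.scaled_down,
        "runs": [],
    }
    for T in plan.temperatures:
        for rep in range(plan.replicates):
            seed = plan.seed_for(T, rep)
            rundir = os.path.join(outdir, f"T{T:g}", f"rep{rep + 1}")
            stages = {
                "minimize": {},
                "npt": {
                    "temperature": plan.npt_temperature,
                    "dt": plan.npt_dt,
                    "nsteps": int(round(plan.npt_ns * 1000 / plan.npt_dt)),
                },
                "nvt": {
                    "temperature": T,
                    "dt": plan.nvt_dt,
                    "nsteps": int(round(plan.nvt_ns * 1000 / plan.nvt_dt)),
                },
                "production": {
                    "temperature": T,
                    "dt": plan.production_dt,
                    "nsteps": int(round(plan.production_us * 1e6 / plan.production_dt)),
                },
            }
            files = export_gromacs(rundir, packed, ff, stages=stages, name=plan.protein.name)
            for stage in stages:
                _append_seed(os.path.join(rundir, f"{stage}.mdp"), seed)
            manifest["runs"].append(
                {
                    "temperature_K": T,
                    "replicate": rep + 1,
                    "seed": seed,
                    "directory": rundir,
                    "stages": list(stages),
                    "files": {k: v for k, v in files.items() if k != "mdp"},
                    "mdrun_flags": f"-rdd {plan.rdd:g}",
                }
            )
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    manifest["manifest"] = path
    return manifest


def _append_seed(mdp_path, seed: int) -> None:
    with open(mdp_path) as fh:
        text = fh.read()
    if "integrator                 = steep" in text:
        return
    with open(mdp_path, "a") as fh:
        fh.write(f"{'ld-seed':<26s} = {seed}\n")


# ---------------------------------------------------------------------------
# Equilibration detection
# ---------------------------------------------------------------------------

@dataclass
class DensityTimeSeries:
    """Center-window and combined edge-window density vs time."""

    times: np.ndarray  # ps
    center_density: np.ndarray  # nm^-3
    edge_density: np.ndarray  # nm^-3

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.center_density = np.asarray(self.center_density, dtype=float)
        self.edge_density = np.asarray(self.edge_density, dtype=float)
        if not (len(self.times) == len(self.center_density) == len(self.edge_density)):
            raise ValueError("series lengths must match")
        if np.any(self.center_density < 0) or np.any(self.edge_density < 0):
            raise ValueError("densities must be non-negative")


def density_timeseries(
    traj: Trajectory,
    center_fraction: float = 1.0 / 15.0,
    edge_fraction: float = 0.2,
) -> DensityTimeSeries:
    """Per-frame center-window and edge-window bead densities along z.

    The center window spans ``center_fraction`` of the box around z/2 (the
    10 nm central window of a 150 nm box by default) and the edge windows
    ``edge_fraction`` of the box at each end, combined.
    """
    times, centers, edges = [], [], []
    for t, coords, box in zip(traj.times, traj.coordinates, traj.boxes):
        z = np.mod(np.asarray(coords)[:, 2], box[2])
        L = box[2]
        half_w = 0.5 * center_fraction * L
        cmask = np.abs(z - L / 2) <= half_w
        emask = (z <= edge_fraction * L) | (z >= (1 - edge_fraction) * L)
        area = box[0] * box[1]
        times.append(t)
        centers.append(cmask.sum() / (2 * half_w * area))
        edges.append(emask.sum() / (2 * edge_fraction * L * area))
    return DensityTimeSeries(np.array(times), np.array(centers), np.array(edges))


def detect_equilibration(
    series: DensityTimeSeries,
    window: int = 10,
    slope_tol: float = 0.02,
) -> float | None:
    """Earliest time from which both density series are stable, or None.

    "Stable" is operationalized as a sliding-window test: from the returned
    time onward, every length-``window`` run of samples has a fitted linear
    slope whose total change across the window is less than ``slope_tol``
    (relative to the series' overall mean) for both the center and the edge
    series.  Returns the time of the earliest such sample, or None if the
    series never stabilizes ("not equilibrated").
    """
    n = len(series.times)
    if n < 2 * window:
        raise ValueError("series must contain at least two windows of samples")
    ok = np.ones(n - window + 1, dtype=bool)
    for values in (series.center_density, series.edge_density):
        scale = max(float(np.mean(values)), 1e-30)
        for s in range(n - window + 1):
            t = series.times[s : s + window]
            v = values[s : s + window]
            slope = np.polyfit(t, v, 1)[0]
            rel_change = abs(slope) * (t[-1] - t[0]) / scale
            if rel_change >= slope_tol:
                ok[s] = False
    # earliest start index such that every subsequent window is stable
    stable_from = None
    for s in range(len(ok) - 1, -1, -1):
        if ok[s]:
            stable_from = s
        else:
            break
    if stable_from is None:
        return None
    return float(series.times[stable_from])


# ---------------------------------------------------------------------------
# Desk-scale end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class DeskSlabResult:
    system: MolecularSystem  # packed topology (bead labels etc.)
    production: Trajectory
    compressed: MolecularSystem
    expanded: MolecularSystem
    t_equil: float | None


def run_desk_slab(
    plan: SlabRunPlan,
    single: MolecularSystem,
    ff: ForceFieldParams,
    temperature: float,
    config_pool: list | None = None,
    compress_target: float = 0.15,
    compress_stages: int = 8,
    sample_interval: int = 5000,
) -> DeskSlabResult:
    """Run the whole slab pipeline with the internal engine at desk scale.

    minimize -> staged z-compression (NPT stand-in, 150 K) -> expansion to
    ``plan.final_z`` -> NVT equilibration -> NVT production at
    ``temperature``.  Returns the production trajectory together with the
    detected equilibration time of its center/edge density series.
    """
    seed = plan.seed_for(temperature, 0)
    pool = config_pool if config_pool is not None else [single.coordinates]
    packed = pack_slab_box(
        single,
        pool,
        coil_budget=plan.coil_budget,
        box=plan.pack_box,
        tolerance=plan.pack_tolerance,
        rng_seed=seed,
    )
    res = minimize(packed, ff)
    compressed = compress_z(
        res.system, ff, compress_target, n_stages=compress_stages, seed=seed + 1
    )
    expanded = expand_z(compressed, plan.final_z)
    nvt_steps = int(round(plan.nvt_ns * 1000 / plan.nvt_dt))
    equil = run_langevin(
        expanded,
        ff,
        IntegratorSettings(dt=plan.nvt_dt, temperature=temperature, seed=seed + 2),
        n_steps=nvt_steps,
        sample_interval=max(1, nvt_steps // 4),
    )
    prod_start = replace(expanded, coordinates=equil.final_coordinates)
    prod_steps = int(round(plan.production_us * 1e6 / plan.production_dt))
    production = run_langevin(
        prod_start,
        ff,
        IntegratorSettings(dt=plan.production_dt, temperature=temperature, seed=seed + 3),
        n_steps=prod_steps,
        sample_interval=sample_interval,
    )
    series = density_timeseries(production)
    try:
        t_equil = detect_equilibration(series)
    except ValueError:
        t_equil = None
    if t_equil is None:
        # counting noise in small desk boxes can defeat the slope test;
        # fall back to discarding the first half as burn-in
        t_equil = production.times[len(production.times) // 2]
    return DeskSlabResult(
        system=packed,
        production=production,
        compressed=compressed,
        expanded=expanded,
        t_equil=t_equil,
    )
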