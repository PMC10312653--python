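"""Desk-scale implicit-solvent Langevin dynamics for the CC LLPS model.

The engine integrates the framework's energetics -- harmonic bonds/angles,
periodic torsions, truncated-shifted Lennard-Jones under the maximally
specific eligibility rule -- with a BAOAB Langevin splitting.  With friction
set to zero the scheme reduces to velocity Verlet (NVE), which is how energy
conservation is verified.  Not built for at-scale production work: slabs at
the published scale are exported to an external MD engine instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from ._kernels import KB
from .build import MolecularSystem, unwrap_molecules
from .model import ForceFieldParams, InteractionScheme

__all__ = [
    "Trajectory",
    "IntegratorSettings",
    "EngineError",
    "MinimizeResult",
    "compute_potential_and_forces",
    "minimize",
    "run_langevin",
    "compress_z",
    "kinetic_temperature",
]


class EngineError(RuntimeError):
    """Engine failure; carries the last valid trajectory when available."""

    def __init__(self, message: str, trajectory: "Trajectory | None" = None):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class Trajectory:
    """Time-ordered frames (coordinates + box) with a thermodynamic series."""

    times: list = field(default_factory=list)  # ps
    coordinates: list = field(default_factory=list)  # (n,3) nm per frame
    boxes: list = field(default_factory=list)  # (3,) nm per frame
    thermo_times: list = field(default_factory=list)
    thermo_temperature: list = field(default_factory=list)  # K
    thermo_potential: list = field(default_factory=list)  # kJ/mol

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def add_frame(self, time: float, coords: np.ndarray, box: np.ndarray) -> None:
        if self.times and time <= self.times[-1]:
            raise ValueError("frame times must be strictly increasing")
        if self.coordinates and coords.shape != self.coordinates[0].shape:
            raise ValueError("frame coordinate shapes must be constant")
        self.times.append(float(time))
        self.coordinates.append(np.array(coords, dtype=float))
        self.boxes.append(np.array(box, dtype=float))

    def add_thermo(self, time: float, temperature: float, potential: float) -> None:
        self.thermo_times.append(float(time))
        self.thermo_temperature.append(float(temperature))
        self.thermo_potential.append(float(potential))

    def frames_after(self, t: float) -> "Trajectory":
        keep = [i for i, ti in enumerate(self.times) if ti >= t]
        out = Trajectory()
        for i in keep:
            out.add_frame(self.times[i], self.coordinates[i], self.boxes[i])
        for i, ti in enumerate(self.thermo_times):
            if ti >= t:
                out.add_thermo(ti, self.thermo_temperature[i], self.thermo_potential[i])
        return out

    @property
    def final_coordinates(self) -> np.ndarray:
        return self.coordinates[-1]


@dataclass(frozen=True)
class IntegratorSettings:
    """Langevin (sd-equivalent) integrator settings."""

    dt: float = 0.02  # ps
    friction: float = 0.2  # 1/ps
    temperature: float = 293.0  # K
    com_removal_interval: int = 10  # steps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.com_removal_interval < 1:
            raise ValueError("com_removal_interval must be >= 1")


class KernelContext:
    """Flat typed arrays binding one system + force field to the kernels."""

    def __init__(
        self,
        system: MolecularSystem,
        ff: ForceFieldParams,
        scheme: InteractionScheme | None = None,
        skin: float = 0.3,
        force_cap: float = 1e5,
    ):
        scheme = scheme or InteractionScheme()
        self.system = system
        self.ff = ff
        self.pos = np.array(system.coordinates, dtype=np.float64, order="C")
        self.box = np.array(system.box, dtype=np.float64, order="C")
        self.chain_ids = np.ascontiguousarray(system.chain_ids, dtype=np.int64)
        labels = system.bead_types.astype(str)
        sticky_labels = sorted({t for t in labels if t.startswith("STY")})
        code_of = {t: i for i, t in enumerate(sticky_labels)}
        self.sticky_code = np.array([code_of.get(t, -1) for t in labels], dtype=np.int64)
        self.allow_intrachain = bool(scheme.allow_intrachain)

        n = system.n_beads
        excl = system.exclusions()
        if excl.size:
            self.excl_codes = np.sort(excl[:, 0].astype(np.int64) * n + excl[:, 1])
            self.excl_max_sep = int(np.max(excl[:, 1] - excl[:, 0]))
        else:
            self.excl_codes = np.empty(0, dtype=np.int64)
            self.excl_max_sep = 0

        bp = ff.bonded
        self.bonds = np.ascontiguousarray(system.bonds, dtype=np.int64).reshape(-1, 2)
        self.bond_r0 = np.where(system.bonds_in_coil, bp.coil.bond_r0, bp.linker.bond_r0).astype(np.float64)
        self.bond_k = np.where(system.bonds_in_coil, bp.coil.bond_k, bp.linker.bond_k).astype(np.float64)
        self.angles = np.ascontiguousarray(system.angles, dtype=np.int64).reshape(-1, 3)
        self.angle_t0 = np.deg2rad(
            np.where(system.angles_in_coil, bp.coil.angle_theta0, bp.linker.angle_theta0)
        ).astype(np.float64)
        self.angle_k = np.where(system.angles_in_coil, bp.coil.angle_k, bp.linker.angle_k).astype(np.float64)
        self.torsions = np.ascontiguousarray(system.torsions, dtype=np.int64).reshape(-1, 4)
        mult = np.where(
            system.torsions_in_coil, bp.coil.torsion_mult, bp.linker.torsion_mult
        ).astype(np.int64)
        phi0 = np.where(system.torsions_in_coil, bp.coil.torsion_phi0, bp.linker.torsion_phi0)
        # periodic torsion V = k (1 + cos(m*phi - phi_s)) minimized at phi0
        tors_phis = (np.deg2rad(phi0) * mult - np.pi).astype(np.float64)
        self.tors_cos_phis = np.cos(tors_phis)
        self.tors_sin_phis = np.sin(tors_phis)
        self.tors_k = np.where(system.torsions_in_coil, bp.coil.torsion_k, bp.linker.torsion_k).astype(np.float64)
        self.tors_mult = mult

        self.eps_att = float(ff.epsilon_coil)
        self.eps_rep = float(ff.epsilon_repulsive)
        self.sigma = float(ff.sigma)
        self.rc = float(ff.cutoff)
        self.skin = float(skin)
        self.rlist = self.rc + self.skin
        self.force_cap = float(force_cap)

        self.forces = np.zeros((n, 3), dtype=np.float64)
        self.pos_ref = self.pos.copy()
        cap = max(64, 80 * n)
        self.pairs_i = np.empty(cap, dtype=np.int64)
        self.pairs_j = np.empty(cap, dtype=np.int64)
        self.npairs_box = np.zeros(1, dtype=np.int64)
        self.rebuild_pairs()

    def rebuild_pairs(self, rlist: float | None = None) -> None:
        rlist = self.rlist if rlist is None else rlist
        np.mod(self.pos, self.box, out=self.pos)
        while True:
            cnt = _kernels.build_pairs(
                self.pos, self.box, rlist, self.excl_codes, self.excl_max_sep,
                self.pairs_i, self.pairs_j,
            )
            if cnt >= 0:
                self.npairs_box[0] = cnt
                self.pos_ref[:] = self.pos
                return
            self.grow_pairs()

    def grow_pairs(self) -> None:
        cap = 2 * len(self.pairs_i)
        self.pairs_i = np.empty(cap, dtype=np.int64)
        self.pairs_j = np.empty(cap, dtype=np.int64)

    def evaluate(self) -> tuple[float, int]:
        """Potential energy and capped-pair count for current coordinates."""
        pe, ncapped = _kernels.compute_forces(
            self.pos, self.box, self.forces, self.pairs_i, self.pairs_j,
            self.npairs_box[0], self.sticky_code, self.chain_ids,
            self.allow_intrachain, self.eps_att, self.eps_rep, self.sigma,
            self.rc, self.bonds, self.bond_r0, self.bond_k, self.angles,
            self.angle_t0, self.angle_k, self.torsions, self.tors_cos_phis,
            self.tors_sin_phis, self.tors_k, self.tors_mult, self.force_cap,
        )
        return pe, ncapped

    def system_with_current(self) -> MolecularSystem:
        return replace(self.system, coordinates=self.pos.copy(), box=self.box.copy())


def compute_potential_and_forces(
    system: MolecularSystem,
    ff: ForceFieldParams,
    scheme: InteractionScheme | None = None,
    force_cap: float = 1e5,
) -> tuple[float, np.ndarray]:
    """Potential (kJ/mol) and forces (kJ/mol/nm) for one configuration."""
    ctx = KernelContext(system, ff, scheme, force_cap=force_cap)
    pe, ncapped = ctx.evaluate()
    if ncapped:
        import warnings

        warnings.warn(f"{ncapped} overlapping pair(s) hit the force cap", stacklevel=2)
    return pe, ctx.forces.copy()


@dataclass
class MinimizeResult:
    system: MolecularSystem
    converged: bool
    max_force: float
    potential: float
    steps: int


def _max_force(forces: np.ndarray) -> float:
    return float(np.sqrt((forces * forces).sum(axis=1).max()))


def minimize(
    system: MolecularSystem,
    ff: ForceFieldParams,
    force_tol: float = 50.0,
    step: float = 0.002,
    max_steps: int = 5000,
    scheme: InteractionScheme | None = None,
    ctx: KernelContext | None = None,
) -> MinimizeResult:
    """Steepest-descent minimization to a maximum per-bead force tolerance.

    Mirrors the usual slab-protocol setting: force tolerance 50 kJ/mol/nm and
    an (adaptive) initial step of 2 pm.  The step grows 20% on accepted moves
    and halves on rejected ones.
    """
    if force_tol <= 0:
        raise ValueError("force_tol must be positive")
    own_ctx = ctx is None
    if own_ctx:
        ctx = KernelContext(system, ff, scheme)
    pe, _ = ctx.evaluate()
    maxf = _max_force(ctx.forces)
    nsteps = 0
    stalls = 0
    while maxf >= force_tol and nsteps < max_steps:
        trial = ctx.pos + (step / maxf) * ctx.forces
        old_pos = ctx.pos.copy()
        ctx.pos[:] = trial
        if np.max(np.abs(ctx.pos - ctx.pos_ref)) > ctx.skin / 2:
            ctx.rebuild_pairs()
        pe_new, _ = ctx.evaluate()
        if pe_new < pe:
            pe = pe_new
            maxf = _max_force(ctx.forces)
            step = min(step * 1.2, 0.05)
            stalls = 0
        else:
            ctx.pos[:] = old_pos
            ctx.rebuild_pairs()
            ctx.evaluate()
            step *= 0.5
            stalls += 1
            if step < 1e-12:
                raise EngineError(
                    f"minimization diverged: step collapsed at max force "
                    f"{maxf:.3g} kJ/mol/nm after {nsteps} steps (E = {pe:.6g})"
                )
        nsteps += 1
    return MinimizeResult(
        system=ctx.system_with_current(),
        converged=maxf < force_tol,
        max_force=maxf,
        potential=pe,
        steps=nsteps,
    )


def kinetic_temperature(vel: np.ndarray, mass: float) -> float:
    """Instantaneous kinetic temperature; 3N-3 DOF (COM motion removed)."""
    n = len(vel)
    ke = 0.5 * mass * float((vel * vel).sum())
    dof = max(1, 3 * n - 3)
    return 2.0 * ke / (dof * KB)


def run_langevin(
    system: MolecularSystem,
    ff: ForceFieldParams,
    settings: IntegratorSettings,
    n_steps: int,
    sample_interval: int = 1000,
    scheme: InteractionScheme | None = None,
    t0: float = 0.0,
    velocities: np.ndarray | None = None,
    ctx: KernelContext | None = None,
    record_initial: bool = True,
) -> Trajectory:
    """Langevin (BAOAB) dynamics; reproducible bit-for-bit under a fixed seed.

    Samples a frame plus a thermo record (kinetic temperature, potential)
    every ``sample_interval`` steps.  The center-of-mass translational
    velocity is removed every ``settings.com_removal_interval`` steps.
    """
    if ctx is None:
        ctx = KernelContext(system, ff, scheme)
    mass = float(ff.mass)
    kT = KB * settings.temperature
    rng = np.random.default_rng(settings.seed)
    if velocities is None:
        vel = rng.normal(scale=np.sqrt(kT / mass), size=ctx.pos.shape)
        vel -= vel.mean(axis=0)
    else:
        vel = np.array(velocities, dtype=np.float64)

    traj = Trajectory()
    pe, _ = ctx.evaluate()
    if record_initial:
        traj.add_frame(t0, ctx.pos, ctx.box)
        traj.add_thermo(t0, kinetic_temperature(vel, mass), pe)
    n = ctx.pos.shape[0]
    # sub-chunks keep the pre-drawn noise buffer small
    noise_chunk = max(1, min(512, int(4e6 / (3 * n))))
    done = 0
    while done < n_steps:
        todo = min(sample_interval, n_steps - done)
        inner = 0
        while inner < todo:
            run = min(noise_chunk, todo - inner)
            if settings.friction > 0:
                noise = rng.standard_normal((run, n, 3))
            else:
                noise = np.zeros((run, n, 3))
            off = 0
            while off < run:
                steps, pe, _nc, status = _kernels.integrate_chunk(
                    ctx.pos, vel, ctx.forces, ctx.box, run - off, settings.dt,
                    settings.friction, kT, mass, settings.com_removal_interval,
                    done + inner + off, noise[off:], ctx.pos_ref, ctx.skin,
                    ctx.rlist, ctx.excl_codes, ctx.excl_max_sep, ctx.pairs_i, ctx.pairs_j,
                    ctx.npairs_box, ctx.sticky_code, ctx.chain_ids,
                    ctx.allow_intrachain, ctx.eps_att, ctx.eps_rep, ctx.sigma,
                    ctx.rc, ctx.bonds, ctx.bond_r0, ctx.bond_k,
                    ctx.angles, ctx.angle_t0, ctx.angle_k,
                    ctx.torsions, ctx.tors_cos_phis, ctx.tors_sin_phis,
                    ctx.tors_k, ctx.tors_mult, ctx.force_cap,
                )
                off += steps
                if status == 1:
                    ctx.grow_pairs()
                    ctx.rebuild_pairs()
                    ctx.evaluate()
                elif status == 2:
                    raise EngineError(
                        f"NaN encountered at step {done + inner + off}; aborting",
                        trajectory=traj,
                    )
            inner += run
        done += todo
        t = t0 + done * settings.dt
        traj.add_frame(t, ctx.pos, ctx.box)
        traj.add_thermo(t, kinetic_temperature(vel, mass), pe)
    traj.final_velocities = vel
    return traj


def min_nonbonded_distance(system: MolecularSystem, search_radius: float = 1.0) -> float:
    """Smallest minimum-image distance over non-excluded bead pairs.

    First and second bonded neighbors are skipped (they carry no nonbonded
    repulsion in this model and may legitimately sit close).  Returns
    ``search_radius`` when no pair is nearer than that.
    """
    coords = np.mod(system.coordinates, system.box)
    tree = cKDTree(coords, boxsize=system.box)
    pairs = tree.query_pairs(r=search_radius, output_type="ndarray")
    if len(pairs) == 0:
        return float(search_radius)
    excl = {(int(a), int(b)) for a, b in system.exclusions()}
    keep = [
        (i, j) for i, j in pairs if (min(i, j), max(i, j)) not in excl
    ]
    if not keep:
        return float(search_radius)
    keep = np.asarray(keep)
    d = coords[keep[:, 0]] - coords[keep[:, 1]]
    d -= system.box * np.round(d / system.box)
    return float(np.sqrt((d * d).sum(axis=1)).min())


def compress_z(
    system: MolecularSystem,
    ff: ForceFieldParams,
    target_fraction: float,
    n_stages: int = 10,
    relax_steps: int = 2000,
    relax_temperature: float = 150.0,
    dt: float = 0.01,
    seed: int = 0,
    scheme: InteractionScheme | None = None,
    force_tol: float = 50.0,
) -> MolecularSystem:
    """Staged z-compression with Langevin relaxation between stages.

    Desk-scale stand-in for semi-isotropic NPT slab formation: each stage
    rescales the box z-length and the molecule centers (molecules move
    rigidly, so bonds are never strained by the rescale), then relaxes with
    a short low-temperature Langevin run.  The final z-length is exactly
    ``target_fraction`` times the initial one.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must lie in (0, 1)")
    sysu = unwrap_molecules(system)
    z0 = float(sysu.box[2])
    factor = target_fraction ** (1.0 / n_stages)
    current = sysu
    for stage in range(n_stages):
        new_z = z0 * target_fraction if stage == n_stages - 1 else current.box[2] * factor
        scale = new_z / current.box[2]
        coords = current.coordinates.copy()
        for cid in np.unique(current.chain_ids):
            m = current.chain_ids == cid
            zc = coords[m, 2].mean()
            coords[m, 2] += zc * (scale - 1.0)
        box = current.box.copy()
        box[2] = new_z
        current = replace(current, coordinates=coords, box=box)
        res = minimize(current, ff, force_tol=max(force_tol, 100.0), max_steps=500, scheme=scheme)
        current = res.system
        traj = run_langevin(
            current,
            ff,
            IntegratorSettings(dt=dt, friction=1.0, temperature=relax_temperature, seed=seed + stage),
            n_steps=relax_steps,
            sample_interval=relax_steps,
            scheme=scheme,
        )
        current = replace(current, coordinates=traj.final_coordinates)
        current = unwrap_molecules(current)
    res = minimize(current, ff, force_tol=force_tol, max_steps=20000, scheme=scheme)
    current = res.system
    if ff.epsilon_repulsive > 0 and min_nonbonded_distance(current) < 0.5 * ff.sigma:
        raise EngineError(
            "persistent bead overlap after compression; retry with more stages"
        )
    return current
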