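"""Desk-scale study presets: the package's single-CPU miniatures.

Two canned studies mirror the framework's characterization experiments at
sizes a single CPU can run (see docs/methods.md for the rationale behind
the sizes):

- :func:`census_study` — multimerization capacity of a 3-coil protein's
  coils for a given multimer mode (dilute cubic box, 293 K);
- :func:`slab_ratio_study` — dense/dilute density ratio of a miniature
  3-coil slab at one temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .analysis import (
    MultimerComposition,
    cluster_distribution,
    dense_dilute,
    density_profile,
    multimer_census,
    recenter_slab,
    scaled_windows,
)
from .build import build_protein, pack_slab_box
from .engine import IntegratorSettings, minimize, run_langevin
from .model import cc_protein, default_forcefield
from .slab import desk_scale_plan, run_desk_slab

__all__ = ["census_study", "slab_ratio_study", "CensusResult", "SlabRatioResult"]

#: desk census conditions (fixed; see methods note)
CENSUS_COPIES = 8
CENSUS_BOX = (22.0, 22.0, 22.0)
CENSUS_TEMPERATURE = 293.0
CENSUS_DT = 0.025  # ps
CENSUS_EQUIL_STEPS = 80_000  # 2 ns
CENSUS_PROD_STEPS = 400_000  # 10 ns
CENSUS_SAMPLE = 10_000  # frames every 0.25 ns

#: desk slab conditions (fixed; see methods note)
SLAB_COIL_BUDGET = 18
SLAB_PACK_BOX = (10.0, 10.0, 40.0)
SLAB_FINAL_Z = 40.0
SLAB_NVT_NS = 0.5
SLAB_PRODUCTION_US = 0.006  # 6 ns
SLAB_DT = 0.025


@dataclass
class CensusResult:
    composition: MultimerComposition
    mode: str
    n_coils: int


def census_study(mode: str, seed: int = 0, prod_steps: int = CENSUS_PROD_STEPS) -> CensusResult:
    """Multimer census of the 3-coil protein for one multimer mode.

    Packs ``CENSUS_COPIES`` copies into the dilute census box, equilibrates
    2 ns and analyzes ``prod_steps`` of production at 293 K.
    """
    ff = default_forcefield(mode)
    spec = cc_protein(3, mode)
    single = build_protein(spec, ff)
    packed = pack_slab_box(
        single,
        [single.coordinates],
        coil_budget=CENSUS_COPIES * spec.n_coils,
        box=CENSUS_BOX,
        tolerance=1.0,
        rng_seed=seed,
    )
    res = minimize(packed, ff)
    equil = run_langevin(
        res.system,
        ff,
        IntegratorSettings(dt=CENSUS_DT, temperature=CENSUS_TEMPERATURE, seed=seed + 1),
        n_steps=CENSUS_EQUIL_STEPS,
        sample_interval=CENSUS_EQUIL_STEPS,
    )
    start = replace(res.system, coordinates=equil.final_coordinates)
    traj = run_langevin(
        start,
        ff,
        IntegratorSettings(dt=CENSUS_DT, temperature=CENSUS_TEMPERATURE, seed=seed + 2),
        n_steps=prod_steps,
        sample_interval=CENSUS_SAMPLE,
    )
    comp = multimer_census(traj.frames_after(traj.times[0] + 1.0), start)
    return CensusResult(comp, mode, CENSUS_COPIES * spec.n_coils)


@dataclass
class SlabRatioResult:
    temperature: float
    rho_dense: float
    rho_dilute: float
    ratio: float
    max_cluster_fraction: float


def slab_ratio_study(
    temperature: float,
    seed: int = 0,
    production_us: float = SLAB_PRODUCTION_US,
) -> SlabRatioResult:
    """Dense/dilute density ratio of a miniature dimer-mode 3-coil slab."""
    ff = default_forcefield("dimer")
    spec = cc_protein(3, "dimer")
    single = build_protein(spec, ff)
    plan = desk_scale_plan(
        spec,
        coil_budget=SLAB_COIL_BUDGET,
        pack_box=SLAB_PACK_BOX,
        final_z=SLAB_FINAL_Z,
        nvt_ns=SLAB_NVT_NS,
        nvt_dt=SLAB_DT,
        production_us=production_us,
        production_dt=SLAB_DT,
        temperatures=(temperature,),
        base_seed=seed,
    )
    result = run_desk_slab(plan, single, ff, temperature=temperature)
    equil = recenter_slab(result.production.frames_after(result.t_equil))
    prof = density_profile(equil)
    dense_w, dilute_w = scaled_windows(prof.box[2])
    rho_dense, rho_dilute = dense_dilute(prof, dense_w, dilute_w)
    dist = cluster_distribution(equil, result.system.chain_ids, stride=2)
    # detection limit: one bead in the dilute windows over the analyzed frames
    box = prof.box
    v_dilute = box[0] * box[1] * sum(hi - lo for lo, hi in dilute_w)
    floor = 1.0 / (v_dilute * max(1, equil.n_frames))
    ratio = rho_dense / max(rho_dilute, floor)
    return SlabRatioResult(
        temperature=temperature,
        rho_dense=rho_dense,
        rho_dilute=rho_dilute,
        ratio=ratio,
        max_cluster_fraction=dist.max_cluster_fraction,
    )
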