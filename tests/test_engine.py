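"""Engine correctness: forces, minimization, thermostat, compression."""

import dataclasses

import numpy as np
import pytest

from coilslab.build import build_protein, pack_slab_box
from coilslab.engine import (
    EngineError,
    IntegratorSettings,
    compress_z,
    compute_potential_and_forces,
    min_nonbonded_distance,
    minimize,
    run_langevin,
)
from coilslab.model import (
    InteractionScheme,
    cc_protein,
    default_forcefield,
    lj_shifted,
)


@pytest.fixture(scope="module")
def perturbed_two_coil():
    """Small two-coil chain with randomized coordinates (all terms active)."""
    ff = default_forcefield("dimer")
    spec = cc_protein(2, "dimer", coil_length=10, linker_length=5)
    sysm = build_protein(spec, ff)
    rng = np.random.default_rng(0)
    sysm.coordinates += rng.normal(scale=0.05, size=sysm.coordinates.shape)
    return sysm, ff


def _two_sticky_beads(r, same_chain=False, ff=None):
    """Minimal system: two isolated sticky beads of the same coil type."""
    ff = ff or default_forcefield("dimer")
    empty2 = lambda shape: np.empty(shape, dtype=int)
    return dataclasses.replace(
        build_protein(cc_protein(1, "dimer", coil_length=7), ff),
        coordinates=np.array([[5.0, 5.0, 5.0], [5.0 + r, 5.0, 5.0]]),
        bead_types=np.array(["STY_c1", "STY_c1"], dtype=object),
        chain_ids=np.zeros(2, dtype=int) if same_chain else np.arange(2),
        segment_ids=np.zeros(2, dtype=int),
        coil_ids=np.arange(2),
        box=np.array([10.0, 10.0, 10.0]),
        bonds=empty2((0, 2)),
        angles=empty2((0, 3)),
        torsions=empty2((0, 4)),
        bonds_in_coil=np.empty(0, dtype=bool),
        angles_in_coil=np.empty(0, dtype=bool),
        torsions_in_coil=np.empty(0, dtype=bool),
    )


class TestForces:
    def test_forces_match_finite_differences(self, perturbed_two_coil):
        """Analytic forces = central finite differences to 1e-5 relative."""
        sysm, ff = perturbed_two_coil
        pe, forces = compute_potential_and_forces(sysm, ff)
        h = 1e-6
        rng = np.random.default_rng(3)
        worst = 0.0
        for idx in rng.choice(sysm.n_beads, size=10, replace=False):
            for k in range(3):
                up = sysm.copy()
                up.coordinates[idx, k] += h
                down = sysm.copy()
                down.coordinates[idx, k] -= h
                ep, _ = compute_potential_and_forces(up, ff)
                em, _ = compute_potential_and_forces(down, ff)
                fd = -(ep - em) / (2 * h)
                worst = max(worst, abs(fd - forces[idx, k]) / max(1.0, abs(fd)))
        assert worst < 1e-5

    def test_pair_energy_zero_at_cutoff(self, perturbed_two_coil):
        _, ff = perturbed_two_coil
        sysm = _two_sticky_beads(ff.cutoff, ff=ff)
        pe, _ = compute_potential_and_forces(sysm, ff)
        assert pe == pytest.approx(0.0, abs=1e-12)

    def test_pair_energy_matches_shifted_lj_inside_cutoff(self, perturbed_two_coil):
        _, ff = perturbed_two_coil
        r = 0.6
        sysm = _two_sticky_beads(r, ff=ff)
        pe, _ = compute_potential_and_forces(sysm, ff)
        assert pe == pytest.approx(lj_shifted(r, ff.epsilon_coil, ff.sigma, ff.cutoff), rel=1e-12)

    def test_intrachain_sticky_pair_not_attractive(self):
        ff = default_forcefield("dimer")
        rmin = 2 ** (1 / 6) * ff.sigma
        inter = _two_sticky_beads(rmin, same_chain=False, ff=ff)
        intra = _two_sticky_beads(rmin, same_chain=True, ff=ff)
        pe_inter, _ = compute_potential_and_forces(inter, ff)
        pe_intra, _ = compute_potential_and_forces(intra, ff)
        assert pe_inter == pytest.approx(lj_shifted(rmin, ff.epsilon_coil, ff.sigma), rel=1e-9)
        # same geometry on one chain: only the weak excluded-volume term
        assert pe_intra == pytest.approx(
            lj_shifted(rmin, ff.epsilon_repulsive, ff.sigma), rel=1e-9
        )

    def test_allow_intrachain_scheme_restores_attraction(self):
        ff = default_forcefield("dimer")
        rmin = 2 ** (1 / 6) * ff.sigma
        intra = _two_sticky_beads(rmin, same_chain=True, ff=ff)
        pe, _ = compute_potential_and_forces(
            intra, ff, scheme=InteractionScheme(allow_intrachain=True)
        )
        assert pe == pytest.approx(lj_shifted(rmin, ff.epsilon_coil, ff.sigma), rel=1e-9)

    def test_bond_restoring_force_is_k_delta(self):
        ff = default_forcefield("dimer")
        sysm = build_protein(cc_protein(1, "dimer", coil_length=7), ff)
        two = dataclasses.replace(
            sysm,
            coordinates=sysm.coordinates[:2],
            bead_types=sysm.bead_types[:2],
            chain_ids=sysm.chain_ids[:2],
            segment_ids=sysm.segment_ids[:2],
            coil_ids=sysm.coil_ids[:2],
            bonds=np.array([[0, 1]]),
            angles=np.empty((0, 3), dtype=int),
            torsions=np.empty((0, 4), dtype=int),
            bonds_in_coil=np.array([True]),
            angles_in_coil=np.empty(0, dtype=bool),
            torsions_in_coil=np.empty(0, dtype=bool),
        )
        delta = 0.01
        r0 = ff.bonded.coil.bond_r0
        two.coordinates[1] = two.coordinates[0] + (r0 + delta, 0, 0)
        _, forces = compute_potential_and_forces(two, ff)
        # bonded neighbors are excluded from nonbonded terms: pure k*delta
        expected = ff.bonded.coil.bond_k * delta
        assert abs(forces[1, 0]) == pytest.approx(expected, rel=1e-9)
        assert forces[1, 0] == pytest.approx(-forces[0, 0], rel=1e-12)

    def test_translation_across_periodic_boundary_invariant(self, perturbed_two_coil):
        sysm, ff = perturbed_two_coil
        pe0, f0 = compute_potential_and_forces(sysm, ff)
        shifted = sysm.copy()
        shifted.coordinates = shifted.coordinates + 0.7 * shifted.box  # crosses boundary
        pe1, f1 = compute_potential_and_forces(shifted, ff)
        assert pe1 == pytest.approx(pe0, rel=1e-10)
        assert np.allclose(f0, f1, atol=1e-8)

    def test_overlapping_beads_capped_with_warning(self):
        ff = default_forcefield("dimer")
        sysm = _two_sticky_beads(1e-4, ff=ff)
        with pytest.warns(UserWarning, match="force cap"):
            pe, forces = compute_potential_and_forces(sysm, ff)
        assert np.all(np.isfinite(forces))


class TestMinimize:
    def test_harmonic_dimer_relaxes_to_bond_length(self):
        ff = default_forcefield("dimer")
        sysm = build_protein(cc_protein(1, "dimer", coil_length=7), ff)
        r0 = ff.bonded.coil.bond_r0
        two = dataclasses.replace(
            sysm,
            coordinates=np.array([[5.0, 5.0, 5.0], [5.0 + r0 + 0.1, 5.0, 5.0]]),
            bead_types=np.array(["BB", "BB"], dtype=object),
            chain_ids=np.zeros(2, dtype=int),
            segment_ids=np.zeros(2, dtype=int),
            coil_ids=np.zeros(2, dtype=int),
            box=np.array([10.0, 10.0, 10.0]),
            bonds=np.array([[0, 1]]),
            angles=np.empty((0, 3), dtype=int),
            torsions=np.empty((0, 4), dtype=int),
            bonds_in_coil=np.array([True]),
            angles_in_coil=np.empty(0, dtype=bool),
            torsions_in_coil=np.empty(0, dtype=bool),
        )
        res = minimize(two, ff, force_tol=1.0)
        r = np.linalg.norm(res.system.coordinates[1] - res.system.coordinates[0])
        assert r == pytest.approx(r0, abs=0.005)

    def test_converged_exit_below_50(self, two_coil_system, dimer_ff):
        res = minimize(two_coil_system, dimer_ff)
        assert res.converged
        assert res.max_force < 50.0

    def test_already_minimal_returned_quickly(self, two_coil_system, dimer_ff):
        first = minimize(two_coil_system, dimer_ff)
        again = minimize(first.system, dimer_ff)
        assert again.steps == 0
        assert np.array_equal(again.system.coordinates, first.system.coordinates)

    def test_invalid_tolerance_rejected(self, two_coil_system, dimer_ff):
        with pytest.raises(ValueError):
            minimize(two_coil_system, dimer_ff, force_tol=-1.0)


class TestLangevin:
    def test_equipartition_temperature(self, dimer_ff):
        """Non-interacting beads at 293 K: kinetic temperature within 2%."""
        rng = np.random.default_rng(5)
        n = 400
        sysm = _two_sticky_beads(0.6, ff=dimer_ff)
        sysm = dataclasses.replace(
            sysm,
            coordinates=rng.uniform(0, 12, (n, 3)),
            bead_types=np.array(["BB"] * n, dtype=object),
            chain_ids=np.arange(n),
            segment_ids=np.zeros(n, dtype=int),
            coil_ids=np.full(n, -1),
            box=np.array([12.0, 12.0, 12.0]),
        )
        ff = dataclasses.replace(dimer_ff, epsilon_repulsive=0.0)
        traj = run_langevin(
            sysm,
            ff,
            IntegratorSettings(dt=0.02, temperature=293.0, seed=9),
            n_steps=30000,
            sample_interval=300,
        )
        mean_T = np.mean(traj.thermo_temperature[10:])
        assert mean_T == pytest.approx(293.0, rel=0.02)

    def test_com_momentum_removed(self, dimer_ff):
        sysm = build_protein(cc_protein(1, "dimer", coil_length=14), dimer_ff)
        traj = run_langevin(
            sysm,
            dimer_ff,
            IntegratorSettings(dt=0.01, temperature=293.0, seed=2, com_removal_interval=10),
            n_steps=100,
            sample_interval=100,
        )
        v = traj.final_velocities
        thermal = np.sqrt(0.00831446 * 293 / dimer_ff.mass)
        assert np.linalg.norm(v.mean(axis=0)) < 1e-10 * thermal * len(v)

    def test_identical_seeds_identical_trajectories(self, two_coil_system, dimer_ff):
        settings = IntegratorSettings(dt=0.02, temperature=293.0, seed=77)
        a = run_langevin(two_coil_system, dimer_ff, settings, n_steps=2000, sample_interval=500)
        b = run_langevin(two_coil_system, dimer_ff, settings, n_steps=2000, sample_interval=500)
        assert all(np.array_equal(x, y) for x, y in zip(a.coordinates, b.coordinates))

    def test_different_seeds_diverge(self, two_coil_system, dimer_ff):
        a = run_langevin(
            two_coil_system, dimer_ff,
            IntegratorSettings(seed=1), n_steps=500, sample_interval=500,
        )
        b = run_langevin(
            two_coil_system, dimer_ff,
            IntegratorSettings(seed=2), n_steps=500, sample_interval=500,
        )
        assert not np.array_equal(a.final_coordinates, b.final_coordinates)

    def test_nve_energy_conservation(self, dimer_ff):
        """friction=0 (velocity-Verlet limit): drift < 0.1% over 1e4 steps."""
        ff = dimer_ff
        single = build_protein(cc_protein(1, "dimer", coil_length=20), ff)
        res = minimize(single, ff, force_tol=5.0, max_steps=20000)
        from coilslab._kernels import KB

        # gentle thermal start so the total energy is well away from zero
        warm = run_langevin(
            res.system, ff,
            IntegratorSettings(dt=0.005, friction=1.0, temperature=100.0, seed=4),
            n_steps=2000, sample_interval=2000,
        )
        start = dataclasses.replace(res.system, coordinates=warm.final_coordinates)
        settings = IntegratorSettings(dt=0.004, friction=0.0, temperature=100.0, seed=4)
        traj = run_langevin(
            start, ff, settings,
            n_steps=10000, sample_interval=100,
            velocities=warm.final_velocities,
        )
        n = start.n_beads
        ke = [
            0.5 * ff.mass * float((v * v).sum())
            for v in [warm.final_velocities]
        ]
        etot = np.array(traj.thermo_potential) + np.array(traj.thermo_temperature) * (
            0.00831446261815324 * (3 * n - 3) / 2
        )
        drift = abs(etot[-1] - etot[0]) / abs(etot[0])
        assert drift < 1e-3

    def test_numerical_blowup_aborts_with_trajectory(self, dimer_ff):
        # uncapped forces on nearly-overlapping beads must abort, not loop
        from coilslab.engine import KernelContext

        sysm = _two_sticky_beads(0.5, ff=dimer_ff)
        # near-zero separation (representable at the origin): LJ overflows to inf
        sysm.coordinates[:] = [[0.0, 0.0, 0.0], [1e-26, 0.0, 0.0]]
        ctx = KernelContext(sysm, dimer_ff, force_cap=1e308)
        with pytest.raises(EngineError) as err:
            run_langevin(
                sysm, dimer_ff,
                IntegratorSettings(dt=50.0, temperature=293.0, seed=1),
                n_steps=2000, sample_interval=100, ctx=ctx,
            )
        assert err.value.trajectory is not None


@pytest.fixture(scope="module")
def packed_small():
    ff = default_forcefield("dimer")
    single = build_protein(cc_protein(2, "dimer"), ff)
    packed = pack_slab_box(
        single, [single.coordinates], coil_budget=6,
        box=(8.0, 8.0, 30.0), tolerance=1.0, rng_seed=21,
    )
    return packed, ff


class TestCompressZ:

    def test_final_z_is_exact_target(self, packed_small):
        packed, ff = packed_small
        out = compress_z(packed, ff, target_fraction=0.15, n_stages=6, relax_steps=400)
        assert out.box[2] == pytest.approx(0.15 * packed.box[2])
        assert out.box[0] == packed.box[0]

    def test_compressed_system_relaxed_and_overlap_free(self, packed_small):
        packed, ff = packed_small
        out = compress_z(packed, ff, target_fraction=0.2, n_stages=6, relax_steps=400)
        assert min_nonbonded_distance(out) >= 0.5 * ff.sigma
        res = minimize(out, ff)
        assert res.max_force < 50.0

    def test_ideal_gas_density_scales_inversely(self, dimer_ff):
        rng = np.random.default_rng(8)
        n = 300
        base = _two_sticky_beads(0.6, ff=dimer_ff)
        gas = dataclasses.replace(
            base,
            coordinates=rng.uniform(0, (6.0, 6.0, 30.0), (n, 3)),
            bead_types=np.array(["BB"] * n, dtype=object),
            chain_ids=np.arange(n),
            segment_ids=np.zeros(n, dtype=int),
            coil_ids=np.full(n, -1),
            box=np.array([6.0, 6.0, 30.0]),
        )
        ff = dataclasses.replace(dimer_ff, epsilon_repulsive=0.0)
        out = compress_z(gas, ff, target_fraction=0.5, n_stages=4, relax_steps=100)
        rho0 = n / np.prod(gas.box)
        rho1 = n / np.prod(out.box)
        assert rho1 == pytest.approx(rho0 / 0.5, rel=1e-9)

    def test_invalid_fraction_rejected(self, packed_small):
        packed, ff = packed_small
        with pytest.raises(ValueError):
            compress_z(packed, ff, target_fraction=1.2)
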