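"""Density profiles, binodals, clusters, census, LLPS calls, and metrics."""

import numpy as np
import pytest

from coilslab.analysis import (
    average_profiles,
    build_binodal,
    call_llps,
    cluster_distribution,
    dense_dilute,
    density_profile,
    kde_kl,
    molecule_clusters,
    multimer_census,
    radius_of_gyration,
    rmsd,
    scaled_windows,
)
from coilslab.engine import Trajectory
from coilslab.fixtures import SlabFixtureSpec, make_cluster_fixture, make_slab_fixture


def _uniform_traj(n=4000, box=(10.0, 10.0, 50.0), n_frames=5, seed=0):
    rng = np.random.default_rng(seed)
    traj = Trajectory()
    for k in range(n_frames):
        traj.add_frame(float(k), rng.uniform(0, 1, (n, 3)) * np.asarray(box), np.asarray(box))
    return traj


class TestDensityProfile:
    def test_uniform_beads_give_flat_profile(self):
        box = (10.0, 10.0, 50.0)
        traj = _uniform_traj(n=20000, box=box, n_frames=10)
        prof = density_profile(traj)
        expected = 20000 / np.prod(box)
        assert np.allclose(prof.mean_density, expected, rtol=0.1)

    def test_zero_outside_constructed_window(self):
        box = np.array([10.0, 10.0, 150.0])
        rng = np.random.default_rng(1)
        traj = Trajectory()
        for k in range(3):
            pts = rng.uniform((0, 0, 70), (10, 10, 80), (5000, 3))
            traj.add_frame(float(k), pts, box)
        prof = density_profile(traj)
        outside = (prof.slice_centers < 70) | (prof.slice_centers > 80)
        assert np.all(prof.mean_density[outside] == 0)

    @pytest.mark.parametrize("box_z", [50.0, 49.0])
    def test_density_conservation(self, box_z):
        traj = _uniform_traj(n=3777, box=(10.0, 10.0, box_z), n_frames=4)
        prof = density_profile(traj)
        widths = np.full(len(prof.slice_centers), prof.slice_width)
        widths[-1] = prof.box[2] - (len(widths) - 1) * prof.slice_width
        volume = prof.box[0] * prof.box[1] * widths
        total = float((prof.mean_density * volume).sum())
        assert total == pytest.approx(3777, rel=1e-9)

    def test_non_multiple_box_flags_truncation(self):
        box = (10.0, 10.0, 49.0)
        traj = _uniform_traj(box=box, n=100, n_frames=1)
        prof = density_profile(traj)
        assert prof.truncated_last_slice

    def test_replicate_averaging_mean_sd(self):
        box = np.array([5.0, 5.0, 20.0])
        profs = []
        for level in (1.0, 2.0, 3.0):
            traj = Trajectory()
            n = int(level * np.prod(box))
            rng = np.random.default_rng(int(level))
            traj.add_frame(0.0, rng.uniform(0, 1, (n, 3)) * box, box)
            profs.append(density_profile(traj))
        avg = average_profiles(profs)
        stack = np.vstack([p.mean_density for p in profs])
        assert np.allclose(avg.mean_density, stack.mean(axis=0))
        assert np.allclose(avg.sd_density, stack.std(axis=0))


class TestDenseDilute:
    def test_fixture_densities_recovered_exactly_by_window(self):
        fixture = make_slab_fixture(
            SlabFixtureSpec(dense_density=2.0, dilute_density=0.02, n_frames=30, rng_seed=3)
        )
        prof = density_profile(fixture.trajectory)
        dense, dilute = dense_dilute(prof)
        assert dense == pytest.approx(2.0, rel=0.05)
        assert dilute == pytest.approx(0.02, rel=0.05)

    def test_uniform_profile_equal_branches(self):
        traj = _uniform_traj(n=30000, box=(10.0, 10.0, 150.0), n_frames=5)
        dense, dilute = dense_dilute(density_profile(traj))
        assert dense == pytest.approx(dilute, rel=0.05)

    def test_empty_box(self):
        box = np.array([10.0, 10.0, 150.0])
        traj = Trajectory()
        traj.add_frame(0.0, np.empty((0, 3)), box)
        dense, dilute = dense_dilute(density_profile(traj))
        assert (dense, dilute) == (0.0, 0.0)

    def test_window_outside_box_rejected(self):
        traj = _uniform_traj(box=(10.0, 10.0, 50.0), n=100, n_frames=1)
        with pytest.raises(ValueError):
            dense_dilute(density_profile(traj))  # 150 nm windows vs 50 nm box

    def test_scaled_windows(self):
        dense, dilute = scaled_windows(75.0)
        assert dense == (35.0, 40.0)
        assert dilute[0] == (0.5, 17.5)


class TestBinodal:
    def test_identical_replicates_zero_sd(self):
        b = build_binodal([(253, 5.0, 0.1)] * 3)
        (p,) = b.points
        assert p.rho_dense == pytest.approx(5.0) and p.sd_dense == pytest.approx(0.0, abs=1e-12)
        assert p.rho_dilute == pytest.approx(0.1) and p.sd_dilute == pytest.approx(0.0, abs=1e-12)

    def test_overlapping_intervals_melted_and_omitted(self):
        reps = [(293, 5.0, 4.5), (293, 6.0, 5.5), (293, 4.0, 3.5)]
        b = build_binodal(reps)
        assert len(b.points) == 0
        assert len(b.melted_points) == 1
        assert b.melted_points[0].melted

    def test_single_coexisting_temperature(self):
        reps = [
            (253, 5.0, 0.1), (253, 5.1, 0.12), (253, 4.9, 0.08),
            (313, 1.0, 0.9), (313, 1.1, 1.0), (313, 0.9, 0.8),
        ]
        b = build_binodal(reps)
        assert [p.temperature for p in b.points] == [253]

    def test_monotone_fixture_series_stay_ordered(self):
        reps = [(T, 6.0 - 0.01 * (T - 250), 0.05) for T in (253, 273, 293)]
        b = build_binodal(reps)
        dense = [p.rho_dense for p in b.points]
        assert dense == sorted(dense, reverse=True)


def _brute_force_clusters(coords, box, chain_ids, cutoff):
    """O(n^2) union-find oracle over all inter-chain bead pairs."""
    chains = np.unique(chain_ids)
    parent = {int(c): int(c) for c in chains}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        parent[find(a)] = find(b)

    box = np.asarray(box)
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if chain_ids[i] == chain_ids[j]:
                continue
            d = coords[i] - coords[j]
            d -= box * np.round(d / box)
            if np.sqrt((d * d).sum()) <= cutoff:
                union(int(chain_ids[i]), int(chain_ids[j]))
    sizes = {}
    for c in chains:
        root = find(int(c))
        sizes[root] = sizes.get(root, 0) + 1
    return sorted(sizes.values(), reverse=True)


class TestMoleculeClusters:
    def test_two_chains_within_cutoff_cluster(self):
        box = (20.0, 20.0, 20.0)
        a = np.column_stack([np.arange(5) * 0.4, np.zeros(5), np.zeros(5)]) + 5.0
        b = a + (0.0, 0.5, 0.0)
        coords = np.vstack([a, b])
        ids = np.repeat([0, 1], 5)
        assert list(molecule_clusters(coords, box, ids, cutoff=0.9)) == [2]

    def test_two_chains_beyond_cutoff_separate(self):
        box = (20.0, 20.0, 20.0)
        a = np.column_stack([np.arange(5) * 0.4, np.zeros(5), np.zeros(5)]) + 5.0
        b = a + (0.0, 1.0, 0.0)
        coords = np.vstack([a, b])
        ids = np.repeat([0, 1], 5)
        assert list(molecule_clusters(coords, box, ids, cutoff=0.9)) == [1, 1]

    def test_transitive_linkage(self):
        box = (30.0, 30.0, 30.0)
        a = np.zeros((3, 3)) + (5.0, 5.0, 5.0)
        b = a + (0.5, 0, 0)
        c = b + (0.5, 0, 0)  # a-c distance 1.0 > cutoff, but linked via b
        coords = np.vstack([a, b, c])
        ids = np.repeat([0, 1, 2], 3)
        sizes = molecule_clusters(coords, box, ids, cutoff=0.9)
        assert list(sizes) == [3]
        assert list(sizes) == _brute_force_clusters(coords, box, ids, 0.9)

    def test_periodic_contact_across_boundary(self):
        box = (10.0, 10.0, 10.0)
        a = np.array([[0.1, 5.0, 5.0]])
        b = np.array([[9.8, 5.0, 5.0]])  # 0.3 nm across the boundary
        sizes = molecule_clusters(np.vstack([a, b]), box, np.array([0, 1]), cutoff=0.9)
        assert list(sizes) == [2]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle_random_systems(self, seed):
        rng = np.random.default_rng(seed)
        n_chains = int(rng.integers(3, 13))
        box = (8.0, 8.0, 8.0)
        coords = []
        ids = []
        for c in range(n_chains):
            start = rng.uniform(0, 8, 3)
            pts = start + rng.normal(0, 0.3, (4, 3)).cumsum(axis=0)
            coords.append(pts)
            ids.extend([c] * 4)
        coords = np.mod(np.vstack(coords), box)
        ids = np.array(ids)
        ours = list(molecule_clusters(coords, box, ids, cutoff=0.9))
        oracle = _brute_force_clusters(coords, box, ids, 0.9)
        assert ours == oracle

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            molecule_clusters(np.empty((0, 3)), (10, 10, 10), np.empty(0), 0.9)

    def test_distribution_normalized(self):
        fixture_coords, box, ids, truth = make_cluster_fixture({2: 3, 1: 2})
        traj = Trajectory()
        traj.add_frame(0.0, fixture_coords, box)
        dist = cluster_distribution(traj, ids)
        assert sum(dist.probabilities.values()) == pytest.approx(1.0, abs=1e-12)


class _StubSystem:
    """Minimal system-like object for census tests (all beads same sticky type)."""

    def __init__(self, coil_ids, chain_ids, n_beads=None):
        self.coil_ids = np.asarray(coil_ids)
        self.chain_ids = np.asarray(chain_ids)
        n = len(self.coil_ids) if n_beads is None else n_beads
        self.bead_types = np.array(["STY_c1"] * n, dtype=object)


def _coil_pair_system(n_beads=6, offset=0.5, n_contacts=None):
    """Two coils on different chains with an exact number of contact pairs.

    Sticky beads sit 2 nm apart along x, so only the facing (a_i, b_i) pairs
    can be within the 0.9 nm cutoff; ``n_contacts`` of them are.
    """
    box = np.array([30.0, 30.0, 30.0])
    a = np.column_stack([np.arange(n_beads) * 2.0, np.zeros(n_beads), np.zeros(n_beads)]) + 5
    b = a.copy()
    b[:, 1] += offset
    if n_contacts is not None:
        b[n_contacts:, 1] += 8.0  # push the rest out of range
    coords = np.vstack([a, b])
    sysm = _StubSystem(
        coil_ids=np.repeat([0, 1], n_beads),
        chain_ids=np.repeat([0, 1], n_beads),
    )
    traj = Trajectory()
    traj.add_frame(0.0, coords, box)
    return traj, sysm


class TestMultimerCensus:
    def test_five_contacts_make_a_dimer(self):
        traj, sysm = _coil_pair_system(n_contacts=5)
        comp = multimer_census(traj, sysm, min_contacts=3)
        assert comp.fractions["dimer"] == pytest.approx(1.0)

    def test_two_contacts_below_min_three_stay_monomers(self):
        traj, sysm = _coil_pair_system(n_contacts=2)
        comp = multimer_census(traj, sysm, min_contacts=3)
        assert comp.fractions["monomer"] == pytest.approx(1.0)

    def test_three_mutually_bound_coils_trimer(self):
        box = np.array([30.0, 30.0, 30.0])
        base = np.column_stack([np.arange(6) * 2.0, np.zeros(6), np.zeros(6)]) + 5
        coords = np.vstack([base, base + (0, 0.5, 0), base + (0, 0.25, 0.43)])
        sysm = _StubSystem(np.repeat([0, 1, 2], 6), np.repeat([0, 1, 2], 6))
        traj = Trajectory()
        traj.add_frame(0.0, coords, box)
        comp = multimer_census(traj, sysm, min_contacts=3)
        assert comp.fractions["trimer"] == pytest.approx(1.0)

    def test_no_contacts_all_monomers(self):
        traj, sysm = _coil_pair_system(offset=5.0)
        comp = multimer_census(traj, sysm)
        assert comp.fractions["monomer"] == pytest.approx(1.0)

    def test_same_chain_contacts_ignored(self):
        traj, sysm = _coil_pair_system(n_contacts=6)
        sysm.chain_ids = np.zeros_like(sysm.chain_ids)  # both coils on one chain
        comp = multimer_census(traj, sysm)
        assert comp.fractions["monomer"] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        traj, sysm = _coil_pair_system(n_contacts=4)
        comp = multimer_census(traj, sysm)
        assert sum(comp.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_min_contacts_validated(self):
        traj, sysm = _coil_pair_system()
        with pytest.raises(ValueError):
            multimer_census(traj, sysm, min_contacts=0)


class TestCallLLPS:
    def _fixture(self, dense, dilute, cluster_sizes, n_chains):
        fix = make_slab_fixture(
            SlabFixtureSpec(dense_density=dense, dilute_density=dilute, n_frames=20, rng_seed=5)
        )
        prof = density_profile(fix.trajectory)

        class _Dist:
            max_cluster_fraction = max(cluster_sizes) / n_chains

        return prof, _Dist()

    def test_slab_plus_spanning_cluster_is_llps(self):
        prof, dist = self._fixture(2.0, 0.02, [95], 100)
        v = call_llps(prof, dist, n_proteins=100)
        assert v.is_llps and v.density_ratio > 10

    def test_uniform_gas_not_llps(self):
        prof, dist = self._fixture(0.5, 0.5, [100], 100)
        assert not call_llps(prof, dist, n_proteins=100).is_llps

    def test_dense_slab_but_small_cluster_not_llps(self):
        prof, dist = self._fixture(2.0, 0.02, [30], 100)
        assert not call_llps(prof, dist, n_proteins=100).is_llps

    def test_zero_dilute_density_is_infinite_ratio(self):
        fix = make_slab_fixture(
            SlabFixtureSpec(dense_density=1.0, dilute_density=0.0, n_frames=5, rng_seed=2)
        )
        prof = density_profile(fix.trajectory)

        class _Dist:
            max_cluster_fraction = 1.0

        v = call_llps(prof, _Dist(), n_proteins=10)
        assert v.density_ratio == np.inf and v.is_llps


class TestRadiusOfGyration:
    def test_single_bead_zero(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]]) == 0.0

    def test_two_unit_masses_two_nm_apart(self):
        rg = radius_of_gyration([[0, 0, 0], [2.0, 0, 0]])
        assert rg == pytest.approx(1.0)

    def test_translation_invariance(self, rng):
        coords = rng.normal(size=(30, 3))
        masses = rng.uniform(1, 3, 30)
        a = radius_of_gyration(coords, masses)
        b = radius_of_gyration(coords + 7.3, masses)
        assert a == pytest.approx(b, rel=1e-12)

    def test_mass_weighting(self):
        # heavy bead pins the COM: Rg shrinks toward it
        light = radius_of_gyration([[0, 0, 0], [2, 0, 0]], [1, 1])
        heavy = radius_of_gyration([[0, 0, 0], [2, 0, 0]], [10, 1])
        assert heavy < light

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration([[0, 0, 0]], [0.0])


class TestRmsd:
    def test_identical_structures_zero(self, rng):
        x = rng.normal(size=(20, 3))
        assert rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_translated_copy_fits_to_zero(self, rng):
        x = rng.normal(size=(20, 3))
        assert rmsd(x + (1.0, -2.0, 0.5), x, fit=True) == pytest.approx(0.0, abs=1e-9)

    def test_rotated_copy_fits_to_zero(self, rng):
        x = rng.normal(size=(20, 3))
        th = 0.7
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        assert rmsd(x @ rot.T, x, fit=True) == pytest.approx(0.0, abs=1e-9)

    def test_unfitted_uniform_displacement_is_exact(self, rng):
        x = rng.normal(size=(15, 3))
        d = 0.37
        assert rmsd(x + (d, 0, 0), x, fit=False) == pytest.approx(d, rel=1e-12)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestKdeKl:
    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=2000)
        assert kde_kl(x, x) == pytest.approx(0.0, abs=1e-10)

    def test_gaussian_shift_closed_form(self, rng):
        # KL(N(0,1) || N(1,1)) = 0.5 nats
        p = rng.normal(0.0, 1.0, 20000)
        q = rng.normal(1.0, 1.0, 20000)
        assert kde_kl(p, q) == pytest.approx(0.5, abs=0.05)

    def test_asymmetry_on_skewed_samples(self, rng):
        p = rng.exponential(1.0, 5000)
        q = rng.normal(1.0, 1.0, 5000)
        assert kde_kl(p, q) != pytest.approx(kde_kl(q, p), abs=1e-3)

    def test_nonnegative(self, rng):
        p = rng.normal(0, 1, 500)
        q = rng.normal(0.2, 1.2, 500)
        assert kde_kl(p, q) >= 0.0

    def test_disjoint_support_warns(self, rng):
        p = rng.normal(0, 0.1, 500)
        q = rng.normal(50, 0.1, 500)
        with pytest.warns(UserWarning):
            v = kde_kl(p, q)
        assert np.isfinite(v) and v > 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            kde_kl([], [1.0])
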