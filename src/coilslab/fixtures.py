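"""Synthetic systems and trajectories with known ground truth.

These generators make every analysis and protocol operation testable without
running molecular dynamics: slab-shaped bead distributions with prescribed
dense/dilute densities, cluster arrangements with exact composition, and
density time series with a known equilibration time.  Fixture chains are
straight bead rods -- no physics is implied, and none is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Trajectory
from .slab import DensityTimeSeries

__all__ = [
    "SlabFixtureSpec",
    "SlabFixture",
    "make_slab_fixture",
    "make_cluster_fixture",
    "make_density_timeseries",
]

#: beads/nm^3 above which a random-insertion fixture is refused
CLOSE_PACKING_DENSITY = 6.0


@dataclass(frozen=True)
class SlabFixtureSpec:
    """Slab-shaped density fixture: dense window inside a dilute background."""

    box: tuple = (25.0, 25.0, 150.0)
    slab_window: tuple = (70.0, 80.0)
    dense_density: float = 2.0  # nm^-3
    dilute_density: float = 0.02  # nm^-3
    n_frames: int = 50
    noise: float = 0.0  # relative per-frame fluctuation of bead counts
    chain_size: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.dense_density >= self.dilute_density >= 0):
            raise ValueError("need dense >= dilute >= 0")
        lo, hi = self.slab_window
        if not (0 <= lo < hi <= self.box[2]):
            raise ValueError("slab window must lie inside the box")
        if max(self.dense_density, self.dilute_density) > CLOSE_PACKING_DENSITY:
            raise ValueError("requested density exceeds close packing")


@dataclass
class SlabFixture:
    """Generated trajectory plus its machine-readable ground truth."""

    trajectory: Trajectory
    chain_ids: np.ndarray
    truth: dict = field(default_factory=dict)


def _poissonish(rng, mean, noise):
    if noise <= 0:
        return int(round(mean))
    return max(0, int(round(rng.normal(mean, noise * max(mean, 1.0)))))


def make_slab_fixture(spec: SlabFixtureSpec) -> SlabFixture:
    """Uniformly random beads at the prescribed densities inside/outside the slab.

    Beads are grouped into synthetic chains of ``chain_size`` (labels only;
    positions stay independent).  The ground-truth record carries the true
    densities and window for comparison against analysis output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    box = np.asarray(spec.box, dtype=float)
    lo, hi = spec.slab_window
    area = box[0] * box[1]
    v_dense = area * (hi - lo)
    v_dilute = area * (box[2] - (hi - lo))
    traj = Trajectory()
    n_chain_ref = None
    for k in range(spec.n_frames):
        n_dense = _poissonish(rng, spec.dense_density * v_dense, spec.noise)
        n_dilute = _poissonish(rng, spec.dilute_density * v_dilute, spec.noise)
        dense_pts = rng.uniform(
            low=(0, 0, lo), high=(box[0], box[1], hi), size=(n_dense, 3)
        )
        dil = rng.uniform(low=0, high=1, size=(n_dilute, 3))
        dil[:, 0] *= box[0]
        dil[:, 1] *= box[1]
        # dilute z avoids the slab window
        gap = box[2] - (hi - lo)
        z = dil[:, 2] * gap
        z = np.where(z < lo, z, z + (hi - lo))
        dil[:, 2] = z
        coords = np.vstack([dense_pts, dil])
        if n_chain_ref is None:
            n_chain_ref = len(coords)
        elif len(coords) != n_chain_ref:
            # constant frame shape: pad/trim with uniform dilute beads
            if len(coords) > n_chain_ref:
                coords = coords[:n_chain_ref]
            else:
                extra = rng.uniform(low=0, high=box, size=(n_chain_ref - len(coords), 3))
                coords = np.vstack([coords, extra])
        traj.add_frame(float(k), coords, box)
    n = n_chain_ref or 0
    chain_ids = np.arange(n) // spec.chain_size
    return SlabFixture(
        trajectory=traj,
        chain_ids=chain_ids,
        truth={
            "dense_density": spec.dense_density,
            "dilute_density": spec.dilute_density,
            "slab_window": tuple(spec.slab_window),
            "box": tuple(spec.box),
            "n_beads": n,
        },
    )


def make_cluster_fixture(
    composition: dict,
    cutoff: float = 0.9,
    box: tuple = (30.0, 30.0, 30.0),
    chain_size: int = 5,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """One frame of chains arranged into clusters of exact composition.

    ``composition`` maps cluster size (in molecules) -> count of such
    clusters.  Within a cluster, neighboring chains are closer than
    ``cutoff``; distinct clusters are separated by more than 2x cutoff.
    Returns (coords, box, chain_ids, ground_truth).
    """
    box = np.asarray(box, dtype=float)
    sizes = [s for s, c in sorted(composition.items()) for _ in range(int(c))]
    if not sizes:
        raise ValueError("composition must request at least one cluster")
    bead_gap = 0.4 * cutoff  # intra-chain spacing: never bridges clusters
    chain_gap = 0.6 * cutoff  # distance between chains of one cluster
    cluster_margin = 2.5 * cutoff
    # lay clusters on a grid with guaranteed separation
    max_chains = max(sizes)
    cell = max_chains * chain_gap + chain_size * bead_gap + cluster_margin
    per_axis = int(np.floor(box[0] / cell)), int(np.floor(box[1] / cell)), int(
        np.floor(box[2] / cell)
    )
    capacity = per_axis[0] * per_axis[1] * per_axis[2]
    if capacity < len(sizes):
        raise ValueError(
            f"cannot place {len(sizes)} clusters with separation {cluster_margin} "
            f"in box {tuple(box)}"
        )
    coords = []
    chain_ids = []
    cid = 0
    slot = 0
    for size in sizes:
        ix = slot % per_axis[0]
        iy = (slot // per_axis[0]) % per_axis[1]
        iz = slot // (per_axis[0] * per_axis[1])
        origin = np.array([ix, iy, iz]) * cell + 0.5 * cluster_margin
        slot += 1
        for c in range(size):
            start = origin + np.array([c * chain_gap, 0.0, 0.0])
            pts = start + np.outer(np.arange(chain_size) * bead_gap, np.array([0, 0, 1.0]))
            coords.append(pts)
            chain_ids.extend([cid] * chain_size)
            cid += 1
    coords = np.vstack(coords)
    truth = {
        "composition": {int(s): int(c) for s, c in composition.items()},
        "n_chains": cid,
        "cutoff": cutoff,
    }
    return coords, box, np.array(chain_ids), truth


def make_density_timeseries(
    profile_type: str,
    n_samples: int = 100,
    level: float = 2.0,
    edge_level: float = 0.05,
    drift_rate: float = 0.02,
    step_index: int = 50,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[DensityTimeSeries, dict]:
    """Synthetic center/edge density series with known equilibration time.

    ``profile_type``: ``stable`` (constant), ``drift`` (linear ramp
    throughout; never equilibrates), or ``step`` (level change at
    ``step_index``, constant afterwards).  Returns the series plus a ground
    truth record.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples, dtype=float) * 100.0  # ps
    if profile_type == "stable":
        center = np.full(n_samples, level)
        truth_idx = 0
    elif profile_type == "drift":
        center = level * (1.0 + drift_rate * np.arange(n_samples))
        truth_idx = None
    elif profile_type == "step":
        center = np.where(np.arange(n_samples) < step_index, 2.0 * level, level)
        truth_idx = step_index
    else:
        raise ValueError(f"unknown profile type {profile_type!r}")
    edge = np.full(n_samples, edge_level)
    if noise > 0:
        center = np.maximum(0, center + rng.normal(0, noise * level, n_samples))
        edge = np.maximum(0, edge + rng.normal(0, noise * edge_level, n_samples))
    series = DensityTimeSeries(t, center, edge)
    truth = {
        "type": profile_type,
        "equilibration_index": truth_idx,
        "equilibration_time": None if truth_idx is None else float(t[truth_idx]),
    }
    return series, truth
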