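"""Trajectory analyses for slab phase-coexistence simulations.

Density profiles along z, dense/dilute coexistence densities and binodals,
whole-molecule cluster-size distributions, a coil-level multimer census, the
two-marker LLPS call, and the structural validation metrics (radius of
gyration, RMSD with optimal superposition, Gaussian-KDE Kullback-Leibler
divergence).

Unless noted otherwise, densities are *number* densities in beads/nm^3 and
all distances use the minimum-image convention in orthorhombic boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "DensityProfile",
    "BinodalPoint",
    "Binodal",
    "ClusterSizeDistribution",
    "MultimerComposition",
    "density_profile",
    "dense_dilute",
    "recenter_slab",
    "scaled_windows",
    "build_binodal",
    "molecule_clusters",
    "cluster_distribution",
    "multimer_census",
    "call_llps",
    "helical_fraction",
    "radius_of_gyration",
    "rmsd",
    "kde_kl",
]

#: analysis windows (nm) for the 150 nm slab convention: the dense region is
#: the slab center at 70-80 nm, the dilute region the combined box ends.
DENSE_WINDOW = (70.0, 80.0)
DILUTE_WINDOWS = ((1.0, 35.0), (115.0, 150.0))
REFERENCE_BOX_Z = 150.0


def scaled_windows(box_z: float):
    """Dense/dilute windows rescaled from the 150 nm convention to ``box_z``."""
    s = box_z / REFERENCE_BOX_Z
    dense = (DENSE_WINDOW[0] * s, DENSE_WINDOW[1] * s)
    dilute = tuple((lo * s, hi * s) for lo, hi in DILUTE_WINDOWS)
    return dense, dilute


# ---------------------------------------------------------------------------
# Density profiles and binodals
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """z-profile of time-averaged number density, in fixed-width slices."""

    slice_centers: np.ndarray  # nm
    mean_density: np.ndarray  # nm^-3
    sd_density: np.ndarray  # nm^-3 across replicates (zeros for one replicate)
    slice_width: float  # nm
    box: np.ndarray  # nm
    truncated_last_slice: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_nm": self.slice_centers,
                "density_nm3": self.mean_density,
                "sd_nm3": self.sd_density,
            }
        )


def _frame_histogram(coords, box, edges, area):
    z = np.mod(coords[:, 2], box[2])
    counts, _ = np.histogram(z, bins=edges)
    widths = np.diff(edges)
    return counts / (widths * area)


def density_profile(traj, slice_width: float = 2.0) -> DensityProfile:
    """Time-averaged number-density profile along z in fixed slices.

    ``traj`` is an engine Trajectory (or anything with ``coordinates`` and
    ``boxes`` sequences).  Callers are expected to pass only the equilibrated
    portion.  If the box z-length is not a multiple of the slice width, the
    last slice is truncated and flagged.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    box = np.asarray(traj.boxes[0], dtype=float)
    nz = int(np.floor(box[2] / slice_width + 1e-9))
    edges = np.arange(nz + 1) * slice_width
    truncated = False
    if edges[-1] < box[2] - 1e-9:
        edges = np.append(edges, box[2])
        truncated = True
    area = box[0] * box[1]
    acc = np.zeros(len(edges) - 1)
    for coords, b in zip(traj.coordinates, traj.boxes):
        acc += _frame_histogram(np.asarray(coords), np.asarray(b), edges, area)
    mean = acc / traj.n_frames
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(
        slice_centers=centers,
        mean_density=mean,
        sd_density=np.zeros_like(mean),
        slice_width=slice_width,
        box=box,
        truncated_last_slice=truncated,
    )


def average_profiles(profiles: list[DensityProfile]) -> DensityProfile:
    """Replicate mean +- population standard deviation, slice by slice."""
    stack = np.vstack([p.mean_density for p in profiles])
    ref = profiles[0]
    return DensityProfile(
        slice_centers=ref.slice_centers,
        mean_density=stack.mean(axis=0),
        sd_density=stack.std(axis=0),
        slice_width=ref.slice_width,
        box=ref.box,
        truncated_last_slice=ref.truncated_last_slice,
    )


def recenter_slab(traj) -> "object":
    """Shift each frame along z so the slab's center of mass sits at z/2.

    Slabs drift along z during NVT production; analysis windows are fixed,
    so frames are recentered first (the protocol keeps slabs centered).  The
    center is the circular mean of bead z-positions, which is well defined
    under periodic boundaries.
    """
    from .engine import Trajectory

    out = Trajectory()
    for t, coords, box in zip(traj.times, traj.coordinates, traj.boxes):
        coords = np.asarray(coords, dtype=float)
        box = np.asarray(box, dtype=float)
        theta = 2.0 * np.pi * np.mod(coords[:, 2], box[2]) / box[2]
        center = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
        center = (center / (2.0 * np.pi)) % 1.0 * box[2]
        shifted = coords.copy()
        shifted[:, 2] = np.mod(coords[:, 2] - center + box[2] / 2.0, box[2])
        out.add_frame(t, shifted, box)
    return out


def dense_dilute(
    profile: DensityProfile,
    dense_window: tuple[float, float] = DENSE_WINDOW,
    dilute_windows=DILUTE_WINDOWS,
) -> tuple[float, float]:
    """Mean density in the slab-center window and in the combined box-end windows.

    Defaults follow the 150 nm box convention (dense: 70-80 nm; dilute: 1-35
    and 115-150 nm); pass :func:`scaled_windows` output for other boxes.
    """
    z_hi = profile.box[2]
    for lo, hi in (dense_window, *dilute_windows):
        if lo < 0 or hi > z_hi + 1e-9:
            raise ValueError(f"analysis window ({lo}, {hi}) outside box z-range")
    c = profile.slice_centers
    dense_mask = (c >= dense_window[0]) & (c <= dense_window[1])
    dilute_mask = np.zeros_like(dense_mask)
    for lo, hi in dilute_windows:
        dilute_mask |= (c >= lo) & (c <= hi)
    rho_dense = float(profile.mean_density[dense_mask].mean()) if dense_mask.any() else 0.0
    rho_dilute = float(profile.mean_density[dilute_mask].mean()) if dilute_mask.any() else 0.0
    return rho_dense, rho_dilute


@dataclass(frozen=True)
class BinodalPoint:
    temperature: float  # K
    rho_dilute: float
    sd_dilute: float
    rho_dense: float
    sd_dense: float
    melted: bool


@dataclass
class Binodal:
    """Coexistence densities vs temperature; melted points are excluded."""

    points: list = field(default_factory=list)  # non-melted BinodalPoints
    melted_points: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "T_K": p.temperature,
                    "rho_dilute_nm3": p.rho_dilute,
                    "sd_dilute_nm3": p.sd_dilute,
                    "rho_dense_nm3": p.rho_dense,
                    "sd_dense_nm3": p.sd_dense,
                }
                for p in self.points
            ]
        )


def build_binodal(replicate_points) -> Binodal:
    """Binodal from per-replicate (T, rho_dense, rho_dilute) tuples.

    Replicates at the same temperature are combined as unweighted mean +-
    population sd.  A temperature is flagged melted -- and omitted from the
    binodal -- when the dense and dilute mean +- sd intervals overlap.
    """
    by_temp: dict[float, list[tuple[float, float]]] = {}
    for T, dense, dilute in replicate_points:
        by_temp.setdefault(float(T), []).append((float(dense), float(dilute)))
    binodal = Binodal()
    for T in sorted(by_temp):
        dense = np.array([d for d, _ in by_temp[T]])
        dilute = np.array([g for _, g in by_temp[T]])
        dm, ds = dense.mean(), dense.std()
        gm, gs = dilute.mean(), dilute.std()
        melted = (dm - ds) <= (gm + gs)
        point = BinodalPoint(T, gm, gs, dm, ds, melted)
        (binodal.melted_points if melted else binodal.points).append(point)
    return binodal


# ---------------------------------------------------------------------------
# Molecular clusters and multimer census
# ---------------------------------------------------------------------------

@dataclass
class ClusterSizeDistribution:
    """P(cluster size in molecules), by cluster-count convention."""

    probabilities: dict  # size -> probability
    n_frames: int
    cutoff: float
    max_cluster_fraction: float = 0.0  # largest observed cluster / n molecules

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if self.probabilities and abs(total - 1.0) > 1e-9:
            raise ValueError("cluster probabilities must sum to 1")


def _contact_graph_components(coords, box, labels, cutoff):
    """Connected components of the label-level contact graph.

    Two labels are linked when any bead pair between them is within
    ``cutoff`` (minimum image).  Returns per-label component ids.
    """
    coords = np.mod(coords, box)
    tree = cKDTree(coords, boxsize=box)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    uniq, inv = np.unique(labels, return_inverse=True)
    nlab = len(uniq)
    if len(pairs):
        li, lj = inv[pairs[:, 0]], inv[pairs[:, 1]]
        keep = li != lj
        data = np.ones(keep.sum(), dtype=np.int8)
        graph = coo_matrix((data, (li[keep], lj[keep])), shape=(nlab, nlab))
    else:
        graph = coo_matrix((nlab, nlab))
    _, comp = connected_components(graph, directed=False)
    return uniq, comp


def molecule_clusters(coords, box, chain_ids, cutoff: float = 0.9) -> np.ndarray:
    """Cluster sizes (in molecules) for one frame, single-linkage at ``cutoff``.

    Two molecules interact when any inter-molecular bead pair lies within the
    cutoff (0.9 nm by default); clusters are connected components.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty frame")
    _, comp = _contact_graph_components(coords, np.asarray(box, float), np.asarray(chain_ids), cutoff)
    _, counts = np.unique(comp, return_counts=True)
    return np.sort(counts)[::-1]


def cluster_distribution(traj, chain_ids, cutoff: float = 0.9, stride: int = 1) -> ClusterSizeDistribution:
    """Cluster-size distribution accumulated over trajectory frames.

    Per-frame cluster sizes are pooled and normalized to probabilities by
    cluster count (every observed cluster contributes one count).
    """
    counts: dict[int, int] = {}
    n_frames = 0
    n_mol = len(np.unique(chain_ids))
    max_frac = 0.0
    for k in range(0, traj.n_frames, stride):
        sizes = molecule_clusters(traj.coordinates[k], traj.boxes[k], chain_ids, cutoff)
        for s in sizes:
            counts[int(s)] = counts.get(int(s), 0) + 1
        max_frac = max(max_frac, sizes[0] / n_mol)
        n_frames += 1
    total = sum(counts.values())
    probs = {s: c / total for s, c in sorted(counts.items())}
    return ClusterSizeDistribution(probs, n_frames, cutoff, max_frac)


@dataclass
class MultimerComposition:
    """Fraction of coil segments in monomers/dimers/.../larger multimers."""

    fractions: dict  # "monomer" | "dimer" | "trimer" | "tetramer" | "larger" -> mean
    sd: dict
    n_frames: int

    SPECIES = ("monomer", "dimer", "trimer", "tetramer", "larger")

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("multimer fractions must sum to 1")


def _census_frame(coords, box, coil_ids, chain_ids, type_codes, cutoff, min_contacts):
    """Per-frame fraction of coils in each multimer species.

    Coils i and j (different chains) are bound when at least ``min_contacts``
    attraction-eligible sticky-bead pairs (same sticky type, the only pairs
    that interact under the maximally specific scheme) lie within
    ``cutoff``; an n-mer is a connected component of n coils.
    """
    sel = (coil_ids >= 0) & (type_codes >= 0)
    coords = np.mod(np.asarray(coords, float)[sel], box)
    labels = coil_ids[sel]
    chains = chain_ids[sel]
    codes = type_codes[sel]
    tree = cKDTree(coords, boxsize=box)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    uniq, inv = np.unique(labels, return_inverse=True)
    nlab = len(uniq)
    contact_count: dict[tuple[int, int], int] = {}
    if len(pairs):
        li, lj = inv[pairs[:, 0]], inv[pairs[:, 1]]
        ci, cj = chains[pairs[:, 0]], chains[pairs[:, 1]]
        ti, tj = codes[pairs[:, 0]], codes[pairs[:, 1]]
        for a, b, ca, cb, ta, tb in zip(li, lj, ci, cj, ti, tj):
            if a == b or ca == cb or ta != tb:
                continue
            key = (min(a, b), max(a, b))
            contact_count[key] = contact_count.get(key, 0) + 1
    edges = [k for k, c in contact_count.items() if c >= min_contacts]
    if edges:
        ei = np.array([e[0] for e in edges])
        ej = np.array([e[1] for e in edges])
        graph = coo_matrix((np.ones(len(edges), dtype=np.int8), (ei, ej)), shape=(nlab, nlab))
    else:
        graph = coo_matrix((nlab, nlab))
    _, comp = connected_components(graph, directed=False)
    _, sizes = np.unique(comp, return_counts=True)
    comp_size = sizes[comp]  # per-coil component size
    frac = {}
    for name, size in zip(MultimerComposition.SPECIES[:4], (1, 2, 3, 4)):
        frac[name] = float(np.mean(comp_size == size))
    frac["larger"] = float(np.mean(comp_size > 4))
    return frac


def multimer_census(
    traj,
    system,
    cutoff: float = 0.9,
    min_contacts: int = 3,
    stride: int = 1,
) -> MultimerComposition:
    """Time-averaged multimer species composition of coil segments.

    ``system`` supplies the coil-instance labels, chain ids and sticky-bead
    mask matching the trajectory's bead order.
    """
    if min_contacts < 1:
        raise ValueError("min_contacts must be >= 1")
    labels = np.asarray(system.bead_types).astype(str)
    sticky_types = sorted({t for t in labels if t.startswith("STY")})
    code_of = {t: i for i, t in enumerate(sticky_types)}
    type_codes = np.array([code_of.get(t, -1) for t in labels])
    per_frame = {k: [] for k in MultimerComposition.SPECIES}
    n = 0
    for k in range(0, traj.n_frames, stride):
        frac = _census_frame(
            traj.coordinates[k], np.asarray(traj.boxes[k], float),
            system.coil_ids, system.chain_ids, type_codes, cutoff, min_contacts,
        )
        for name in per_frame:
            per_frame[name].append(frac[name])
        n += 1
    means = {k: float(np.mean(v)) for k, v in per_frame.items()}
    # renormalize away accumulated rounding
    total = sum(means.values())
    means = {k: v / total for k, v in means.items()}
    sds = {k: float(np.std(v)) for k, v in per_frame.items()}
    return MultimerComposition(means, sds, n)


# ---------------------------------------------------------------------------
# LLPS call
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LLPSVerdict:
    is_llps: bool
    density_ratio: float
    max_cluster_fraction: float


def call_llps(
    profile: DensityProfile,
    cluster_dist: ClusterSizeDistribution,
    n_proteins: int,
    density_ratio_min: float = 10.0,
    cluster_fraction_min: float = 0.9,
    dense_window: tuple[float, float] = DENSE_WINDOW,
    dilute_windows=DILUTE_WINDOWS,
) -> LLPSVerdict:
    """Two-marker LLPS call: sharp density transition AND a near-system-spanning cluster.

    Both markers are required: the dense/dilute density ratio must reach
    ``density_ratio_min`` and the largest molecular cluster must contain at
    least ``cluster_fraction_min`` of all proteins.
    """
    rho_dense, rho_dilute = dense_dilute(profile, dense_window, dilute_windows)
    ratio = float("inf") if rho_dilute == 0 else rho_dense / rho_dilute
    if rho_dense == 0 and rho_dilute == 0:
        ratio = 0.0
    frac = cluster_dist.max_cluster_fraction
    return LLPSVerdict(
        is_llps=bool(ratio >= density_ratio_min and frac >= cluster_fraction_min),
        density_ratio=ratio,
        max_cluster_fraction=frac,
    )


# ---------------------------------------------------------------------------
# Structural metrics
# ---------------------------------------------------------------------------

def helical_fraction(coordinates, phi0: float = 50.0, tolerance_deg: float = 40.0) -> float:
    """Fraction of consecutive pseudo-torsions within ``tolerance_deg`` of ``phi0``.

    A cheap helicity metric for C-alpha traces: the ideal right-handed
    alpha-helix pseudo-torsion is close to +50 degrees.
    """
    coords = np.asarray(coordinates, dtype=float)
    if len(coords) < 4:
        raise ValueError("need at least 4 beads for a torsion")
    b1 = coords[1:-2] - coords[:-3]
    b2 = coords[2:-1] - coords[1:-2]
    b3 = coords[3:] - coords[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    x = np.einsum("ij,ij->i", n1, n2)
    phi = np.degrees(np.arctan2(y, x))
    dev = np.abs((phi - phi0 + 180.0) % 360.0 - 180.0)
    return float(np.mean(dev < tolerance_deg))


def radius_of_gyration(coordinates, masses=None) -> float:
    """Mass-weighted radius of gyration (nm)."""
    coords = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    if len(coords) == 0:
        raise ValueError("need at least one bead")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (coords * masses[:, None]).sum(axis=0) / total
    d2 = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((masses * d2).sum() / total))


def rmsd(coordinates, reference, fit: bool = True) -> float:
    """Root-mean-square deviation (nm), optionally after optimal superposition.

    With ``fit=True`` the coordinates are rigidly superposed on the reference
    by the least-squares (Kabsch) rotation after centering.
    """
    x = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    y = np.asarray(reference, dtype=float).reshape(-1, 3)
    if x.shape != y.shape:
        raise ValueError("coordinate sets must have equal size")
    if fit:
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        h = xc.T @ yc
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        x = xc @ rot
        y = yc
    return float(np.sqrt(((x - y) ** 2).sum() / len(x)))


def kde_kl(
    sample_p,
    sample_q,
    bandwidth_rule: str = "scott",
    grid_points: int = 2048,
    floor: float = 1e-12,
) -> float:
    """KL divergence KL(p||q) in nats between Gaussian KDEs of two samples.

    Both samples get a Gaussian kernel density estimate (Scott's rule by
    default); the divergence integral is evaluated by trapezoidal quadrature
    on a shared grid spanning both samples plus three bandwidths.  Where q's
    density underflows it is clamped at ``floor`` (with a warning), so the
    result is finite but then a lower bound.
    """
    p = np.asarray(sample_p, dtype=float).ravel()
    q = np.asarray(sample_q, dtype=float).ravel()
    if len(p) == 0 or len(q) == 0:
        raise ValueError("both samples must be non-empty")
    kde_p = stats.gaussian_kde(p, bw_method=bandwidth_rule)
    kde_q = stats.gaussian_kde(q, bw_method=bandwidth_rule)
    hp = np.sqrt(float(kde_p.covariance[0, 0]))
    hq = np.sqrt(float(kde_q.covariance[0, 0]))
    lo = min(p.min() - 3 * hp, q.min() - 3 * hq)
    hi = max(p.max() + 3 * hp, q.max() + 3 * hq)
    grid = np.linspace(lo, hi, grid_points)
    dp = kde_p(grid)
    dq = kde_q(grid)
    if np.any((dq <= floor) & (dp > floor)):
        import warnings

        warnings.warn(
            "q underflows on p's support; clamping to floor (result is a lower bound)",
            stacklevel=2,
        )
    dq = np.maximum(dq, floor)
    mask = dp > floor
    integrand = np.zeros_like(grid)
    integrand[mask] = dp[mask] * np.log(dp[mask] / dq[mask])
    return max(0.0, float(np.trapezoid(integrand, grid)))
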