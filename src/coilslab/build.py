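"""Construction of CG systems: single chains, packed slab boxes.

Chains are initialized as ideal alpha-helical C-alpha traces over their whole
length (coils *and* linkers); linker segments, whose bonded force constants
are 100x weaker, relax out of the helical geometry during equilibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .model import (
    BACKBONE_TYPE,
    LINKER_TYPE,
    CoilSegmentSpec,
    ForceFieldParams,
    LinkerSegmentSpec,
    ProteinSpec,
    sticky_type_label,
)

__all__ = [
    "MolecularSystem",
    "PackingPlan",
    "PackingError",
    "build_protein",
    "plan_packing",
    "pack_slab_box",
    "unwrap_molecules",
    "min_interchain_distance",
]


@dataclass
class MolecularSystem:
    """Beads + topology of one or many CG chains in an orthorhombic box.

    ``coil_ids`` assigns every bead of a coil segment a global coil-instance
    index (-1 for backbone/linker beads outside coils is not used: all beads
    of a coil segment share the instance id; linker beads carry -1).
    """

    coordinates: np.ndarray  # (n, 3) nm
    bead_types: np.ndarray  # (n,) str labels, e.g. BB / LNK / STY_c1
    chain_ids: np.ndarray  # (n,) int
    segment_ids: np.ndarray  # (n,) int, global segment instance index
    coil_ids: np.ndarray  # (n,) int, global coil instance index; -1 outside coils
    box: np.ndarray  # (3,) nm
    bonds: np.ndarray  # (nb, 2) int
    angles: np.ndarray  # (na, 3) int
    torsions: np.ndarray  # (nt, 4) int
    bonds_in_coil: np.ndarray  # (nb,) bool: all participating beads in coil segments
    angles_in_coil: np.ndarray
    torsions_in_coil: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        n = self.n_beads
        for idx in (self.bonds, self.angles, self.torsions):
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError("bonded term index out of range")

    @property
    def n_beads(self) -> int:
        return len(self.coordinates)

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_ids))

    @property
    def is_sticky(self) -> np.ndarray:
        return np.char.startswith(self.bead_types.astype(str), "STY")

    def exclusions(self) -> np.ndarray:
        """Nonbonded exclusion pairs: first and second bonded neighbors (1-2, 1-3)."""
        pairs = {tuple(sorted(b)) for b in self.bonds.tolist()}
        pairs |= {tuple(sorted((a[0], a[2]))) for a in self.angles.tolist()}
        return np.array(sorted(pairs), dtype=int).reshape(-1, 2)

    def wrapped(self) -> "MolecularSystem":
        """Copy with coordinates wrapped into [0, L)."""
        return replace(self, coordinates=np.mod(self.coordinates, self.box))

    def copy(self) -> "MolecularSystem":
        return replace(self, coordinates=self.coordinates.copy(), box=self.box.copy())


def _chain_topology(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.arange(n)
    bonds = np.column_stack([idx[:-1], idx[1:]])
    angles = np.column_stack([idx[:-2], idx[1:-1], idx[2:]])
    torsions = np.column_stack([idx[:-3], idx[1:-2], idx[2:-1], idx[3:]])
    return bonds, angles, torsions


def build_protein(spec: ProteinSpec, ff: ForceFieldParams, box_margin: float = 2.0) -> MolecularSystem:
    """Build a single chain for ``spec`` as an ideal helical C-alpha trace.

    One bead per residue; sticky/multimer-driver beads placed at the coil
    segments' heptad sticky positions; bonded terms (n-1 bonds, n-2 angles,
    n-3 torsions) generated per segment class.  The box is a bounding box
    plus ``box_margin`` on each side (callers repack/resize for real runs).
    """
    n = spec.n_residues
    if n < 4:
        raise ValueError("chain too short for a torsion-bearing helical trace")
    coords = ff.helix.trace(n)

    types = np.empty(n, dtype=object)
    seg_ids = np.zeros(n, dtype=int)
    coil_ids = np.full(n, -1, dtype=int)
    in_coil = np.zeros(n, dtype=bool)
    offset = 0
    coil_counter = 0
    for seg_index, seg in enumerate(spec.segments):
        sl = slice(offset, offset + seg.length)
        seg_ids[sl] = seg_index
        if isinstance(seg, CoilSegmentSpec):
            types[sl] = BACKBONE_TYPE
            sticky = offset + seg.sticky_positions()
            types[sticky] = sticky_type_label(seg.coil_type_id)
            coil_ids[sl] = coil_counter
            in_coil[sl] = True
            coil_counter += 1
        else:
            types[sl] = LINKER_TYPE
        offset += seg.length

    bonds, angles, torsions = _chain_topology(n)
    bonds_in_coil = in_coil[bonds].all(axis=1)
    angles_in_coil = in_coil[angles].all(axis=1)
    torsions_in_coil = in_coil[torsions].all(axis=1)

    coords = coords - coords.min(axis=0) + box_margin
    box = coords.max(axis=0) + box_margin
    return MolecularSystem(
        coordinates=coords,
        bead_types=types,
        chain_ids=np.zeros(n, dtype=int),
        segment_ids=seg_ids,
        coil_ids=coil_ids,
        box=box,
        bonds=bonds,
        angles=angles,
        torsions=torsions,
        bonds_in_coil=bonds_in_coil,
        angles_in_coil=angles_in_coil,
        torsions_in_coil=torsions_in_coil,
    )


# ---------------------------------------------------------------------------
# Slab packing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PackingPlan:
    """Copy count for a coil budget: as many copies as fit under the budget."""

    protein: ProteinSpec
    coil_budget: int
    copies: int
    coils_placed: int
    tolerance: float
    box: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.coils_placed > self.coil_budget:
            raise ValueError("packing plan exceeds its coil budget")


class PackingError(RuntimeError):
    pass


#: default slab packing box (nm): elongated in z, expanded to 150 nm later
DEFAULT_PACK_BOX = (25.0, 25.0, 100.0)


def plan_packing(
    protein: ProteinSpec,
    coil_budget: int = 450,
    box: tuple[float, float, float] = DEFAULT_PACK_BOX,
    tolerance: float = 1.0,
) -> PackingPlan:
    """Maximal number of chain copies whose total coil count fits the budget.

    With the standard 450-coil budget, 2- and 3-coil proteins place exactly
    450 coils (225 / 150 copies) while the 4-coil protein places 448 coils
    (112 copies).
    """
    if coil_budget < protein.n_coils:
        raise ValueError("coil budget smaller than one protein copy")
    copies = coil_budget // protein.n_coils
    return PackingPlan(
        protein=protein,
        coil_budget=coil_budget,
        copies=copies,
        coils_placed=copies * protein.n_coils,
        tolerance=tolerance,
        box=tuple(float(b) for b in box),
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via random unit quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def pack_slab_box(
    single: MolecularSystem,
    config_pool: list[np.ndarray],
    coil_budget: int = 450,
    box: tuple[float, float, float] = DEFAULT_PACK_BOX,
    tolerance: float = 1.0,
    rng_seed: int = 0,
    protein: ProteinSpec | None = None,
    max_attempts_per_copy: int = 5000,
) -> MolecularSystem:
    """Randomly pack chain copies into a box with a minimum inter-chain distance.

    Copies are drawn round-robin from ``config_pool`` (conformations of the
    same chain, e.g. frames selected from an equilibrated single-molecule
    run), given a uniform random rigid placement (rotation + translation) and
    accepted only if every bead is at least ``tolerance`` away (minimum-image)
    from every previously placed bead.  The copy count is the maximal number
    whose coils fit ``coil_budget``.
    """
    if not config_pool:
        raise ValueError("config_pool must contain at least one conformation")
    n_coils = int(np.max(single.coil_ids)) + 1
    if n_coils < 1:
        raise ValueError("system contains no coil segments")
    copies = coil_budget // n_coils
    if copies < 1:
        raise ValueError("coil budget smaller than one protein copy")
    box_arr = np.asarray(box, dtype=float)
    rng = np.random.default_rng(rng_seed)

    placed: list[np.ndarray] = []
    all_coords: np.ndarray | None = None
    tree: cKDTree | None = None
    for copy_index in range(copies):
        conf = np.asarray(config_pool[copy_index % len(config_pool)], dtype=float)
        if conf.shape != single.coordinates.shape:
            raise ValueError("pool conformation shape mismatch with template chain")
        centered = conf - conf.mean(axis=0)
        for _ in range(max_attempts_per_copy):
            rot = _random_rotation(rng)
            trial = centered @ rot.T + rng.uniform(0, box_arr, size=3)
            trial = np.mod(trial, box_arr)
            if tree is not None:
                d, _ = tree.query(trial, k=1)
                if np.min(d) < tolerance:
                    continue
            placed.append(trial)
            all_coords = trial if all_coords is None else np.vstack([all_coords, trial])
            tree = cKDTree(all_coords, boxsize=box_arr)
            break
        else:
            raise PackingError(
                f"could not place copy {copy_index + 1}/{copies} within "
                f"{max_attempts_per_copy} attempts "
                f"(achieved packing fraction {copy_index / copies:.2f})"
            )

    return _replicate(single, placed, box_arr)


def _replicate(single: MolecularSystem, coords_list: list[np.ndarray], box: np.ndarray) -> MolecularSystem:
    n = single.n_beads
    copies = len(coords_list)
    n_coils = int(np.max(single.coil_ids)) + 1
    n_segs = int(np.max(single.segment_ids)) + 1
    coords = np.vstack(coords_list)
    reps = np.arange(copies)

    def tile_offset(ids: np.ndarray, per_copy: int) -> np.ndarray:
        tiled = np.tile(ids, copies)
        off = np.repeat(reps * per_copy, n)
        mask = tiled >= 0
        tiled = tiled + np.where(mask, off, 0)
        return tiled

    bonds = np.vstack([single.bonds + i * n for i in reps]) if single.bonds.size else single.bonds
    angles = np.vstack([single.angles + i * n for i in reps]) if single.angles.size else single.angles
    torsions = (
        np.vstack([single.torsions + i * n for i in reps]) if single.torsions.size else single.torsions
    )
    return MolecularSystem(
        coordinates=coords,
        bead_types=np.tile(single.bead_types, copies),
        chain_ids=np.repeat(reps, n),
        segment_ids=tile_offset(single.segment_ids, n_segs),
        coil_ids=tile_offset(single.coil_ids, n_coils),
        box=box.copy(),
        bonds=bonds,
        angles=angles,
        torsions=torsions,
        bonds_in_coil=np.tile(single.bonds_in_coil, copies),
        angles_in_coil=np.tile(single.angles_in_coil, copies),
        torsions_in_coil=np.tile(single.torsions_in_coil, copies),
    )


def unwrap_molecules(system: MolecularSystem) -> MolecularSystem:
    """Make every molecule whole: walk bonds, undoing periodic jumps.

    After unwrapping, no bond crosses the periodic boundary; each molecule is
    then rigidly shifted so its geometric center lies inside the box.
    """
    coords = system.coordinates.copy()
    box = system.box
    n = system.n_beads
    adjacency: list[list[int]] = [[] for _ in range(n)]
    for i, j in system.bonds:
        adjacency[i].append(j)
        adjacency[j].append(i)
    visited = np.zeros(n, dtype=bool)
    for start in range(n):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        members = [start]
        while stack:
            i = stack.pop()
            for j in adjacency[i]:
                if not visited[j]:
                    d = coords[j] - coords[i]
                    coords[j] = coords[i] + d - box * np.round(d / box)
                    visited[j] = True
                    members.append(j)
                    stack.append(j)
        m = np.array(members)
        center = coords[m].mean(axis=0)
        coords[m] += -box * np.floor(center / box)
    return replace(system, coordinates=coords)


def min_interchain_distance(system: MolecularSystem) -> float:
    """Smallest minimum-image distance between beads of different chains."""
    coords = np.mod(system.coordinates, system.box)
    tree = cKDTree(coords, boxsize=system.box)
    pairs = tree.query_pairs(r=float(np.min(system.box)) / 2.0 - 1e-9, output_type="ndarray")
    if len(pairs) == 0:
        return float("inf")
    inter = system.chain_ids[pairs[:, 0]] != system.chain_ids[pairs[:, 1]]
    if not inter.any():
        return float("inf")
    d = coords[pairs[inter, 0]] - coords[pairs[inter, 1]]
    d -= system.box * np.round(d / system.box)
    return float(np.sqrt((d * d).sum(axis=1).min()))
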