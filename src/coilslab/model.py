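"""Domain model and force-field parameterization for coiled-coil LLPS proteins.

A coiled-coil (CC) protein is a linear chain of *coil segments* (helical,
sticker-like, multimer-forming) and *linker segments* (disordered, inert
spacers), coarse-grained at one bead per residue (C-alpha mapping).  Phase
behavior is driven entirely by short-range attractions between the sticky
beads of coil segments; linkers are excluded-volume only, i.e. they interact
equally with solvent (implicit) and protein.

Units follow the GROMACS convention throughout: nm, ps, kJ/mol, amu, K.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "BeadClass",
    "MultimerMode",
    "CoilSegmentSpec",
    "LinkerSegmentSpec",
    "ProteinSpec",
    "BondedTermSet",
    "BondedParams",
    "HelixGeometry",
    "ForceFieldParams",
    "InteractionScheme",
    "InteractionTable",
    "MULTIMER_MODES",
    "multimer_mode",
    "default_forcefield",
    "build_interaction_table",
    "lj_shifted",
    "cc_protein",
    "protein_from_config",
    "forcefield_from_config",
]

# Bead-class names used on type labels
BACKBONE = "backbone"
COIL_STICKY = "coil_sticky"
MULTIMER_DRIVER = "multimer_driver"
LINKER_INERT = "linker_inert"

#: heptad positions (0..6, i.e. a..g) carrying sticky / multimer-driver beads,
#: per multimer mode.  Positions a and d (0 and 3) form the classic dimer
#: interface stripe; trimer and tetramer modes add further positions so the
#: coil presents additional angularly separated sticky faces, which -- combined
#: with excluded volume -- caps the number of simultaneous partners.
STICKY_PATTERNS: dict[str, tuple[int, ...]] = {
    "dimer": (0, 3),
    "trimer": (0, 3, 4),
    "tetramer": (0, 2, 3, 5),
}


@dataclass(frozen=True)
class BeadClass:
    """One coarse-grained bead category (one bead = one residue)."""

    name: str
    mass: float = 109.0  # amu; average amino-acid mass
    sigma: float = 0.47  # nm
    base_epsilon: float = 0.0  # kJ/mol; attractive well depth for sticky classes

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("bead mass must be positive")
        if self.sigma <= 0:
            raise ValueError("bead sigma must be positive")
        if self.base_epsilon < 0:
            raise ValueError("base_epsilon must be non-negative")
        if self.name == LINKER_INERT and self.base_epsilon != 0:
            raise ValueError("linker_inert beads are excluded-volume only")


@dataclass(frozen=True)
class MultimerMode:
    """Multimeric multivalency of a coil segment (dimer / trimer / tetramer).

    ``epsilon_coil`` is the coil-coil sticky interaction strength in kJ/mol.
    The dimer default (5.5) is the strength at which dimer-forming coils
    best match an atomistic coiled-coil dimer; trimer- and tetramer-forming
    coils use lowered strengths (4.5 and 4.0) so they stop producing
    aberrantly large multimers.  The trimer value is calibrated against the
    multimer census (see docs/methods.md).
    """

    name: str
    epsilon_coil: float
    max_valence: int

    _VALENCE = {"dimer": 2, "trimer": 3, "tetramer": 4}

    def __post_init__(self) -> None:
        if self.name not in self._VALENCE:
            raise ValueError(
                f"unknown multimer mode {self.name!r}; "
                f"valid modes: {sorted(self._VALENCE)}"
            )
        if self.epsilon_coil <= 0:
            raise ValueError("epsilon_coil must be positive")
        if self.max_valence != self._VALENCE[self.name]:
            raise ValueError(
                f"max_valence {self.max_valence} inconsistent with mode {self.name!r}"
            )


MULTIMER_MODES: dict[str, MultimerMode] = {
    "dimer": MultimerMode("dimer", epsilon_coil=5.5, max_valence=2),
    "trimer": MultimerMode("trimer", epsilon_coil=4.5, max_valence=3),
    "tetramer": MultimerMode("tetramer", epsilon_coil=4.0, max_valence=4),
}


def multimer_mode(mode: Union[str, MultimerMode]) -> MultimerMode:
    """Resolve a mode name (or pass through a MultimerMode)."""
    if isinstance(mode, MultimerMode):
        return mode
    try:
        return MULTIMER_MODES[mode]
    except KeyError:
        raise ValueError(
            f"unknown multimer mode {mode!r}; valid modes: {sorted(MULTIMER_MODES)}"
        ) from None


@dataclass(frozen=True)
class CoilSegmentSpec:
    """A helical sticker segment with a heptad-repeat bead organization.

    ``coil_type_id`` labels the coil's interaction type: under the maximally
    specific scheme, attraction exists only between sticky beads of coils
    carrying the same type id on *different* chains.
    """

    length: int
    coil_type_id: str
    mode: MultimerMode
    sticky_pattern: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.length < 7:
            raise ValueError("coil segments must span at least one heptad (7 residues)")
        if not self.coil_type_id:
            raise ValueError("coil segment requires a non-empty coil_type_id")
        pattern = self.pattern
        if any(p < 0 or p > 6 for p in pattern):
            raise ValueError("sticky_pattern positions must lie in heptad range 0..6")

    @property
    def pattern(self) -> tuple[int, ...]:
        if self.sticky_pattern is not None:
            return tuple(self.sticky_pattern)
        return STICKY_PATTERNS[self.mode.name]

    def sticky_positions(self) -> np.ndarray:
        """Indices (within the segment) of sticky / multimer-driver beads."""
        pattern = set(self.pattern)
        return np.array([i for i in range(self.length) if i % 7 in pattern], dtype=int)


@dataclass(frozen=True)
class LinkerSegmentSpec:
    """A disordered, inert spacer segment."""

    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("linker segments must contain at least one residue")


SegmentSpec = Union[CoilSegmentSpec, LinkerSegmentSpec]


@dataclass(frozen=True)
class ProteinSpec:
    """Ordered coil/linker architecture of one CC protein chain."""

    name: str
    segments: tuple[SegmentSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.n_coils < 1:
            raise ValueError("a CC protein requires at least one coil segment")

    @property
    def coils(self) -> tuple[CoilSegmentSpec, ...]:
        return tuple(s for s in self.segments if isinstance(s, CoilSegmentSpec))

    @property
    def n_coils(self) -> int:
        return len(self.coils)

    @property
    def n_linkers(self) -> int:
        return sum(1 for s in self.segments if isinstance(s, LinkerSegmentSpec))

    @property
    def n_residues(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def mode(self) -> MultimerMode:
        return self.coils[0].mode


def cc_protein(
    n_coils: int,
    mode: Union[str, MultimerMode] = "dimer",
    coil_length: int = 32,
    linker_length: int = 25,
    name: str | None = None,
) -> ProteinSpec:
    """Build an ``n``-coil-``(n-1)``-linker protein with alternating segments.

    Each coil position gets its own ``coil_type_id`` (``c1``, ``c2``, ...),
    which is what the maximally specific interaction scheme requires: coil i
    of one chain attracts only coil i of another chain.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    mode = multimer_mode(mode)
    segments: list[SegmentSpec] = []
    for i in range(n_coils):
        if i > 0:
            segments.append(LinkerSegmentSpec(linker_length))
        segments.append(CoilSegmentSpec(coil_length, f"c{i + 1}", mode))
    if name is None:
        name = f"{n_coils}-coil-{n_coils - 1}-linker-{mode.name}"
    return ProteinSpec(name, tuple(segments))


# ---------------------------------------------------------------------------
# Bonded parameterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BondedTermSet:
    """Harmonic bond/angle plus periodic torsion parameters for one segment class."""

    bond_r0: float  # nm
    bond_k: float  # kJ/mol/nm^2
    angle_theta0: float  # degrees
    angle_k: float  # kJ/mol/rad^2
    torsion_phi0: float  # degrees; equilibrium dihedral
    torsion_k: float  # kJ/mol
    torsion_mult: int = 1

    def __post_init__(self) -> None:
        if min(self.bond_k, self.angle_k, self.torsion_k) < 0:
            raise ValueError("force constants must be non-negative")

    def weakened(self, factor: float) -> "BondedTermSet":
        """Same equilibrium geometry with all force constants divided by ``factor``."""
        return replace(
            self,
            bond_k=self.bond_k / factor,
            angle_k=self.angle_k / factor,
            torsion_k=self.torsion_k / factor,
        )


@dataclass(frozen=True)
class BondedParams:
    """Bonded terms for coil (helix-forming) and linker (disordered) segments.

    Linker force constants are the coil constants divided by
    ``linker_weakening`` (default 100), which reproduces realistic
    disordered-linker dimensions while keeping the same equilibrium geometry.
    """

    coil: BondedTermSet
    linker: BondedTermSet
    linker_weakening: float = 100.0

    @classmethod
    def from_coil(cls, coil: BondedTermSet, weakening: float = 100.0) -> "BondedParams":
        return cls(coil=coil, linker=coil.weakened(weakening), linker_weakening=weakening)


@dataclass(frozen=True)
class HelixGeometry:
    """Ideal alpha-helix C-alpha trace parameters."""

    rise: float = 0.15  # nm per residue
    twist_deg: float = 100.0  # degrees per residue
    radius: float = 0.23  # nm, C-alpha helix radius

    def trace(self, n: int) -> np.ndarray:
        """Coordinates of an ``n``-residue ideal helical C-alpha trace (nm)."""
        i = np.arange(n)
        theta = np.deg2rad(self.twist_deg) * i
        return np.column_stack(
            [self.radius * np.cos(theta), self.radius * np.sin(theta), self.rise * i]
        )

    def equilibrium_terms(
        self,
        bond_k: float = 5000.0,
        angle_k: float = 150.0,
        torsion_k: float = 20.0,
    ) -> BondedTermSet:
        """Helix-restraining bonded terms with equilibria measured off the ideal trace."""
        p = self.trace(4)
        r0 = float(np.linalg.norm(p[1] - p[0]))
        v1, v2 = p[0] - p[1], p[2] - p[1]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        theta0 = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        phi0 = float(_dihedral(p[0], p[1], p[2], p[3]))
        return BondedTermSet(r0, bond_k, theta0, angle_k, phi0, torsion_k, 1)


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees (IUPAC convention; right-handed helix > 0)."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(y, np.dot(n1, n2))))


# ---------------------------------------------------------------------------
# Nonbonded parameterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceFieldParams:
    """Complete parameter set: bead classes, bonded terms, nonbonded LJ table.

    All Lennard-Jones interactions are truncated and shifted so that the pair
    energy is exactly zero at ``cutoff`` (1.1 nm by default).  Non-sticky
    pairs use the same LJ form with a small ``epsilon_repulsive`` so they are
    effectively excluded-volume only.
    """

    multimer_mode: MultimerMode
    bonded: BondedParams
    bead_classes: tuple[BeadClass, ...]
    helix: HelixGeometry = HelixGeometry()
    sigma: float = 0.47  # nm, uniform bead diameter
    mass: float = 109.0  # amu, uniform bead mass
    epsilon_repulsive: float = 0.1  # kJ/mol, excluded-volume pairs
    cutoff: float = 1.1  # nm
    shifted: bool = True

    @property
    def epsilon_coil(self) -> float:
        return self.multimer_mode.epsilon_coil

    def pair_epsilon(self, attractive: bool) -> float:
        return self.epsilon_coil if attractive else self.epsilon_repulsive


def default_forcefield(
    mode: Union[str, MultimerMode] = "dimer",
    *,
    epsilon_coil: float | None = None,
    bond_k: float = 5000.0,
    angle_k: float = 150.0,
    torsion_k: float = 20.0,
    linker_weakening: float = 100.0,
    **overrides,
) -> ForceFieldParams:
    """Default force field for a given multimer mode.

    Coil bonded equilibria come from the ideal-helix geometry; linker bonded
    force constants are the coil constants / ``linker_weakening``.  The coil
    sticky strength defaults to 5.5 kJ/mol for dimer-forming coils and
    4.0 kJ/mol for trimer- and tetramer-forming coils.
    """
    mode = multimer_mode(mode)
    if epsilon_coil is not None:
        mode = replace(mode, epsilon_coil=float(epsilon_coil))
    helix = overrides.pop("helix", HelixGeometry())
    coil_terms = helix.equilibrium_terms(bond_k, angle_k, torsion_k)
    bonded = BondedParams.from_coil(coil_terms, linker_weakening)
    sigma = overrides.get("sigma", 0.47)
    mass = overrides.get("mass", 109.0)
    classes = (
        BeadClass(BACKBONE, mass, sigma, 0.0),
        BeadClass(COIL_STICKY, mass, sigma, mode.epsilon_coil),
        BeadClass(MULTIMER_DRIVER, mass, sigma, mode.epsilon_coil),
        BeadClass(LINKER_INERT, mass, sigma, 0.0),
    )
    return ForceFieldParams(
        multimer_mode=mode, bonded=bonded, bead_classes=classes, helix=helix, **overrides
    )


def lj_shifted(
    r: Union[float, np.ndarray], epsilon: float, sigma: float, cutoff: float = 1.1
) -> Union[float, np.ndarray]:
    """Truncated-and-shifted Lennard-Jones energy (kJ/mol); zero beyond cutoff."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        x6 = (sigma / r) ** 6
        xc6 = (sigma / cutoff) ** 6
        v = 4.0 * epsilon * (x6 * x6 - x6) - 4.0 * epsilon * (xc6 * xc6 - xc6)
    out = np.where(r < cutoff, v, 0.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Interaction scheme / eligibility table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionScheme:
    """Which coil-coil attractions are permitted.

    Under ``maximally_specific`` only sticky beads of coils with identical
    ``coil_type_id`` on *different* chains attract; everything else is
    excluded-volume only.  Intrachain attraction is disabled by default.
    """

    mode: str = "maximally_specific"
    allow_intrachain: bool = False

    def __post_init__(self) -> None:
        if self.mode != "maximally_specific":
            raise ValueError("only the maximally_specific scheme is supported")


ATTRACTIVE = "attractive"
REPULSIVE = "repulsive-only"
EXCLUDED = "excluded"


@dataclass
class InteractionTable:
    """Pair eligibility by bead type, plus the intrachain rule.

    ``type_pairs`` classifies interchain bead-type pairs; :meth:`classify`
    additionally applies the intrachain restriction (all intrachain
    sticky-sticky attraction excluded under the default scheme).
    """

    type_pairs: dict[tuple[str, str], tuple[str, float]]
    scheme: InteractionScheme
    epsilon_repulsive: float

    def classify(self, type_i: str, type_j: str, same_chain: bool = False) -> tuple[str, float]:
        kind, eps = self.type_pairs[_ordered(type_i, type_j)]
        if kind == ATTRACTIVE and same_chain and not self.scheme.allow_intrachain:
            return REPULSIVE, self.epsilon_repulsive
        return kind, eps

    def attractive_pairs(self) -> list[tuple[str, str]]:
        return sorted(k for k, (kind, _) in self.type_pairs.items() if kind == ATTRACTIVE)


def _ordered(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def sticky_type_label(coil_type_id: str) -> str:
    return f"STY_{coil_type_id}"


#: bead type labels for the two inert classes
BACKBONE_TYPE = "BB"
LINKER_TYPE = "LNK"


def build_interaction_table(
    proteins: Sequence[ProteinSpec],
    scheme: InteractionScheme,
    ff: ForceFieldParams,
) -> InteractionTable:
    """Pair-eligibility table for a system composed of the given proteins.

    Attraction (well depth ``ff.epsilon_coil``) is granted only to
    sticky-bead pairs of identical coil type; every other pair is
    repulsive-only with the small excluded-volume epsilon.
    """
    sticky_types: list[str] = []
    for prot in proteins:
        for coil in prot.coils:
            if not coil.coil_type_id:
                raise ValueError(f"coil segment in {prot.name!r} lacks a coil_type_id")
            label = sticky_type_label(coil.coil_type_id)
            if label not in sticky_types:
                sticky_types.append(label)
    all_types = [BACKBONE_TYPE, LINKER_TYPE] + sticky_types
    table: dict[tuple[str, str], tuple[str, float]] = {}
    for i, ti in enumerate(all_types):
        for tj in all_types[i:]:
            if ti == tj and ti in sticky_types:
                table[_ordered(ti, tj)] = (ATTRACTIVE, ff.epsilon_coil)
            else:
                table[_ordered(ti, tj)] = (REPULSIVE, ff.epsilon_repulsive)
    return InteractionTable(table, scheme, ff.epsilon_repulsive)


# ---------------------------------------------------------------------------
# Config-file loading
# ---------------------------------------------------------------------------

def protein_from_config(source) -> ProteinSpec:
    """Load a ProteinSpec from a YAML mapping, path, or file object.

    Schema::

        name: my-protein            # optional
        multimer_mode: dimer        # dimer | trimer | tetramer
        epsilon_coil: 5.5           # optional override, kJ/mol
        segments:
          - {type: coil, length: 32, coil_type_id: c1}
          - {type: linker, length: 25}
          - {type: coil, length: 32, coil_type_id: c2}
    """
    cfg = _load_mapping(source)
    mode = multimer_mode(cfg.get("multimer_mode", "dimer"))
    if "epsilon_coil" in cfg:
        mode = replace(mode, epsilon_coil=float(cfg["epsilon_coil"]))
    segments: list[SegmentSpec] = []
    n_coil = 0
    for seg in cfg["segments"]:
        if seg["type"] == "coil":
            n_coil += 1
            segments.append(
                CoilSegmentSpec(
                    length=int(seg["length"]),
                    coil_type_id=str(seg.get("coil_type_id", f"c{n_coil}")),
                    mode=mode,
                    sticky_pattern=tuple(seg["sticky_pattern"])
                    if "sticky_pattern" in seg
                    else None,
                )
            )
        elif seg["type"] == "linker":
            segments.append(LinkerSegmentSpec(length=int(seg["length"])))
        else:
            raise ValueError(f"unknown segment type {seg['type']!r}")
    return ProteinSpec(str(cfg.get("name", "protein")), tuple(segments))


def forcefield_from_config(source) -> ForceFieldParams:
    """Load ForceFieldParams from a YAML mapping, path, or file object.

    Recognized keys (all optional): ``multimer_mode``, ``epsilon_coil``,
    ``cutoff``, ``sigma``, ``mass``, ``epsilon_repulsive``, ``bond_k``,
    ``angle_k``, ``torsion_k``, ``linker_weakening``.
    """
    cfg = _load_mapping(source)
    kwargs = {}
    for key in ("epsilon_coil", "bond_k", "angle_k", "torsion_k", "linker_weakening"):
        if key in cfg:
            kwargs[key] = float(cfg[key])
    for key in ("cutoff", "sigma", "mass", "epsilon_repulsive"):
        if key in cfg:
            kwargs[key] = float(cfg[key])
    return default_forcefield(cfg.get("multimer_mode", "dimer"), **kwargs)


def _load_mapping(source) -> Mapping:
    if isinstance(source, Mapping):
        return source
    if hasattr(source, "read"):
        return yaml.safe_load(source)
    with open(source) as fh:
        return yaml.safe_load(fh)
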