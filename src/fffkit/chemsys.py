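"""Molecular geometry, bond graph, clusters, exclusion sets and internal
coordinates.

Conventions
-----------
Atom indices are 0-based inside the library and 1-based in every file format
and user-facing message.  Coordinates carry an explicit unit tag
(``"angstrom"`` or ``"bohr"``); computation converts to bohr.

A *bonded cluster* is a maximal set of atoms connected by a path of chemical
bonds.  The *exclusion set* of atom A contains A itself plus its bonded
neighbors up to a chosen graph distance (2 or 3): these pairs carry no
nonbonded interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

__all__ = [
    "MolecularSystem",
    "BondedTopology",
    "InternalCoordinate",
    "detect_bonds",
    "cluster_partition",
    "exclusion_sets",
    "bond_angle",
    "snapshot_equilibrium_internals",
    "build_topology",
]

_VALID_UNITS = ("angstrom", "bohr")

# reference triads collinear to within this many radians store theta_eq as pi
LINEAR_ANGLE_TOL = 1e-8


class GeometryError(ValueError):
    """Degenerate geometry (coincident atoms, zero bond length)."""


class ConfigurationError(ValueError):
    """Missing or inconsistent configuration (e.g. an element radius)."""


@dataclass(frozen=True)
class MolecularSystem:
    """Elements plus Cartesian coordinates, optionally with a reference
    (equilibrium) geometry in the same units."""

    elements: tuple[str, ...]
    coords: np.ndarray
    units: str = "angstrom"
    ref_coords: np.ndarray | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(str(e).capitalize() for e in self.elements))
        if self.units not in _VALID_UNITS:
            raise ConfigurationError(f"unknown unit tag {self.units!r}; expected one of {_VALID_UNITS}")
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError("coords must be an (n_atoms, 3) array")
        if len(self.elements) != coords.shape[0] or coords.shape[0] < 1:
            raise GeometryError("elements and coords must have identical length >= 1")
        if self.ref_coords is not None:
            ref = np.asarray(self.ref_coords, dtype=float)
            if ref.shape != coords.shape:
                raise GeometryError("ref_coords must match coords in shape")
            object.__setattr__(self, "ref_coords", ref)
        d = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((d ** 2).sum(axis=-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() == 0.0:
            a, b = np.unravel_index(np.argmin(dist), dist.shape)
            raise GeometryError(f"atoms {a + 1} and {b + 1} share identical coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def to_bohr(self) -> "MolecularSystem":
        if self.units == "bohr":
            return self
        f = ANGSTROM_TO_BOHR
        ref = None if self.ref_coords is None else self.ref_coords * f
        return MolecularSystem(self.elements, self.coords * f, "bohr", ref)

    def to_angstrom(self) -> "MolecularSystem":
        if self.units == "angstrom":
            return self
        f = BOHR_TO_ANGSTROM
        ref = None if self.ref_coords is None else self.ref_coords * f
        return MolecularSystem(self.elements, self.coords * f, "angstrom", ref)

    def with_coords(self, coords: np.ndarray) -> "MolecularSystem":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def distance(self, a: int, b: int, use_ref: bool = False) -> float:
        xyz = self.ref_coords if use_ref else self.coords
        if xyz is None:
            raise GeometryError("system has no reference coordinates")
        return float(np.linalg.norm(xyz[a] - xyz[b]))


@dataclass(frozen=True)
class InternalCoordinate:
    """One internal coordinate with its equilibrium value.

    kind is ``"bond"`` (value in the length unit of the parent system),
    ``"angle"`` (radians) or ``"urey_bradley"`` (outer-atom distance of a
    bonded angle, length units).
    """

    kind: str
    atoms: tuple[int, ...]
    eq_value: float
    units: str = "bohr"


@dataclass
class BondedTopology:
    bonds: list[tuple[int, int]]
    clusters: list[frozenset[int]] = field(default_factory=list)
    exclusion: dict[int, frozenset[int]] = field(default_factory=dict)
    internal_coords: list[InternalCoordinate] = field(default_factory=list)


def detect_bonds(system: MolecularSystem, radii: dict[str, float]) -> list[tuple[int, int]]:
    """Pairs (A, B) with d_AB no greater than the sum of the two elements'
    atom-typing radii (inclusive at equality).  ``radii`` is in the same
    length unit as ``system``."""
    missing = sorted({e for e in system.elements if e not in radii})
    if missing:
        raise ConfigurationError(f"no atom-typing radius configured for element(s): {', '.join(missing)}")
    xyz = system.coords
    bonds: list[tuple[int, int]] = []
    n = system.n_atoms
    for a in range(n):
        for b in range(a + 1, n):
            d = float(np.linalg.norm(xyz[a] - xyz[b]))
            if d <= radii[system.elements[a]] + radii[system.elements[b]]:
                bonds.append((a, b))
    return bonds


def cluster_partition(bonds: Iterable[tuple[int, int]], n_atoms: int) -> list[frozenset[int]]:
    """Connected components of the bond graph; isolated atoms form singleton
    clusters.  Returned sorted by smallest member for reproducibility."""
    parent = list(range(n_atoms))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in bonds:
        if a >= n_atoms or b >= n_atoms:
            raise IndexError(f"bond ({a + 1},{b + 1}) references atom beyond n_atoms={n_atoms}")
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, set[int]] = {}
    for i in range(n_atoms):
        groups.setdefault(find(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=min)


def exclusion_sets(bonds: Iterable[tuple[int, int]], n_atoms: int, max_separation: int = 3) -> dict[int, frozenset[int]]:
    """Per-atom sets of atoms at BFS graph distance 0..max_separation.

    Distance 0 is the atom itself, so A is always in its own exclusion set.
    """
    if max_separation not in (2, 3):
        raise ConfigurationError("max_separation must be 2 or 3")
    adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    out: dict[int, frozenset[int]] = {}
    for start in range(n_atoms):
        seen = {start: 0}
        frontier = [start]
        for depth in range(1, max_separation + 1):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = depth
                        nxt.append(v)
            frontier = nxt
        out[start] = frozenset(seen)
    return out


def bond_angle(system: MolecularSystem, a: int, b: int, c: int) -> float:
    """Angle A-B-C at vertex B, in radians, clamped into (0, pi].

    The raw cosine is clamped to [-1, 1] so accumulated roundoff near
    collinear triads can never produce NaN.
    """
    if len({a, b, c}) != 3:
        raise GeometryError("bond angle requires three distinct atoms")
    xyz = system.coords
    v1 = xyz[a] - xyz[b]
    v2 = xyz[c] - xyz[b]
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise GeometryError(f"degenerate geometry: coincident atoms in triad ({a + 1},{b + 1},{c + 1})")
    cos_t = float(np.dot(v1, v2) / (n1 * n2))
    cos_t = min(1.0, max(-1.0, cos_t))
    theta = math.acos(cos_t)
    return theta if theta > 0.0 else math.pi


def _angles_from_bonds(bonds: Sequence[tuple[int, int]]) -> list[tuple[int, int, int]]:
    adj: dict[int, set[int]] = {}
    for a, b in bonds:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    triads = []
    for center, nbrs in sorted(adj.items()):
        ordered = sorted(nbrs)
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                triads.append((ordered[i], center, ordered[j]))
    return triads


def snapshot_equilibrium_internals(
    system: MolecularSystem,
    bonds: Sequence[tuple[int, int]],
    include_urey_bradley: bool = False,
) -> list[InternalCoordinate]:
    """Read every bond length, bonded angle and (optionally) Urey-Bradley
    outer-atom distance off the reference geometry.

    Reference triads collinear to within ``LINEAR_ANGLE_TOL`` store an
    equilibrium angle of exactly pi; near-linear but genuinely bent reference
    angles are kept as computed, never rounded.
    """
    if system.ref_coords is None:
        raise GeometryError(
            "the new separation scheme requires a reference (equilibrium) geometry; ref_coords is missing"
        )
    ref_system = replace(system, coords=system.ref_coords)
    out: list[InternalCoordinate] = []
    for a, b in bonds:
        out.append(InternalCoordinate("bond", (a, b), ref_system.distance(a, b), system.units))
    for a, b, c in _angles_from_bonds(bonds):
        theta = bond_angle(ref_system, a, b, c)
        if math.pi - theta < LINEAR_ANGLE_TOL:
            theta = math.pi
        out.append(InternalCoordinate("angle", (a, b, c), theta, "rad"))
        if include_urey_bradley:
            out.append(InternalCoordinate("urey_bradley", (a, c), ref_system.distance(a, c), system.units))
    return out


def build_topology(
    system: MolecularSystem,
    radii: dict[str, float],
    max_separation: int = 3,
    include_urey_bradley: bool = False,
) -> BondedTopology:
    """Full pipeline: bond detection, clusters, exclusion sets, and (if a
    reference geometry is present) equilibrium internal coordinates."""
    bonds = detect_bonds(system, radii)
    topo = BondedTopology(bonds=bonds)
    topo.clusters = cluster_partition(bonds, system.n_atoms)
    topo.exclusion = exclusion_sets(bonds, system.n_atoms, max_separation)
    if system.ref_coords is not None:
        topo.internal_coords = snapshot_equilibrium_internals(system, bonds, include_urey_bradley)
    return topo


def export_topology_text(topo: BondedTopology) -> str:
    """Plain-text listing of bonds, clusters and exclusions with 1-based
    atom indices."""
    lines = ["[bonds]"]
    lines += [f"{a + 1} {b + 1}" for a, b in topo.bonds]
    lines.append("[clusters]")
    lines += [" ".join(str(i + 1) for i in sorted(c)) for c in topo.clusters]
    lines.append("[exclusions]")
    for a in sorted(topo.exclusion):
        members = " ".join(str(i + 1) for i in sorted(topo.exclusion[a]))
        lines.append(f"{a + 1}: {members}")
    return "\n".join(lines) + "\n"
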