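"""Pairwise nonbonded model (point charges + Lennard-Jones), the smooth
transition function tau, and the four-case wrapping that implements the new
bonded/nonbonded separation ansatz.

The new scheme re-expresses each intracluster nonbonded pair energy as a
wrapped potential Phi whose value, first derivative and second derivative
all vanish at the pair's equilibrium separation in the isolated cluster's
reference geometry.  Summed over pairs, the intracluster nonbonded part then
contributes nothing to the energy, forces or Hessian at the reference
geometry, so bonded force constants can be regressed *linearly* without
choosing a nonbonded parameterization first.  With a finite cutoff the wrap
additionally forces Phi and its first two derivatives to zero continuously
at the cutoff distance.

The wrap used here is the Taylor-subtraction construction: the pair
potential minus its second-order Taylor polynomial about d_eq, with the
Taylor polynomial localized by a smooth tanh window (built from the same
transition function tau) so the wrapped potential still decays to zero at
large separation, and the whole expression multiplied by a C^2 polynomial
cutoff switch when a finite cutoff is used.  Each required boundary
condition is enforced exactly by construction; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .chemsys import BondedTopology, MolecularSystem
from .units import ANGSTROM_TO_BOHR, KCALMOL_TO_HARTREE

__all__ = [
    "tau",
    "pair_potential_qLJ",
    "make_qlj_pair",
    "NonbondedModel",
    "PairWrap",
    "wrap_pair",
    "assemble_nonbonded",
]

_TANH_HALF = math.tanh(0.5)


def tau(s: float, t: float, order: int = 0) -> float:
    """Smooth transition function tau(s, t) = tanh(t/s - 1/2).

    Dimensionless and bounded in [-1, 1]; depends only on the ratio t/s, so
    it is independent of measurement units; strictly increasing in t/s; its
    square reaches ~0.819 at t/s = 2.  ``order`` differentiates with respect
    to t.
    """
    if s <= 0:
        raise ValueError("tau requires a positive scale argument s")
    v = math.tanh(t / s - 0.5)
    if order == 0:
        return v
    sech2 = (1.0 - v * v) / s
    if order == 1:
        return sech2
    return -2.0 * v * sech2 / s


def pair_potential_qLJ(
    d: float, q_a: float, q_b: float, eps_ab: float, dlj_ab: float, order: int = 0
) -> float:
    """Coulomb plus 12-6 Lennard-Jones pair energy in atomic units.

    The LJ part is parameterized by the well minimum: it reaches -eps_ab at
    d = dlj_ab.  Charges in e, distances in bohr, energies in hartree.
    """
    if d <= 0:
        raise ValueError("pair distance must be positive")
    r = dlj_ab / d
    r6 = r ** 6
    if order == 0:
        return q_a * q_b / d + eps_ab * (r6 * r6 - 2.0 * r6)
    if order == 1:
        return -q_a * q_b / d ** 2 + eps_ab * (-12.0 * r6 * r6 + 12.0 * r6) / d
    return 2.0 * q_a * q_b / d ** 3 + eps_ab * (156.0 * r6 * r6 - 84.0 * r6) / d ** 2


def make_qlj_pair(q_a, q_b, eps_ab, dlj_ab) -> Callable[[float, int], float]:
    def U(d: float, order: int = 0) -> float:
        return pair_potential_qLJ(d, q_a, q_b, eps_ab, dlj_ab, order)

    return U


@dataclass
class NonbondedModel:
    """Per-atom charges (e) and LJ parameters (hartree / bohr), plus the
    scheme and exclusion policy.

    ``mixing='geometric'`` combines per-atom LJ parameters as geometric means
    for both the well depth and the minimum distance; ``pair_overrides``
    maps a frozenset of element symbols to (eps, dlj)."""

    charges: np.ndarray
    lj_eps: np.ndarray
    lj_d: np.ndarray
    mixing: str = "geometric"
    cutoff: float = math.inf
    scheme: str = "new"
    exclusion_policy: int = 3
    pair_overrides: dict | None = None

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_eps = np.asarray(self.lj_eps, dtype=float)
        self.lj_d = np.asarray(self.lj_d, dtype=float)
        if np.any(self.lj_eps < 0):
            raise ValueError("LJ well depths must be non-negative")
        if np.any(self.lj_d <= 0):
            raise ValueError("LJ minimum distances must be positive")
        if not (self.cutoff > 0):
            raise ValueError("cutoff must be positive or infinite")
        if self.scheme not in ("new", "old"):
            raise ValueError("scheme must be 'new' or 'old'")
        if self.mixing != "geometric":
            raise ValueError("only the geometric mixing rule is implemented")

    @classmethod
    def from_element_table(
        cls,
        elements,
        charge_by_element: dict[str, float],
        eps_kcal_by_element: dict[str, float] | None = None,
        dlj_angstrom_by_element: dict[str, float] | None = None,
        **kw,
    ) -> "NonbondedModel":
        """Build per-atom arrays from element-keyed tables in conventional
        units (kcal/mol well depths, angstrom minimum distances)."""
        q = np.array([charge_by_element.get(e, 0.0) for e in elements])
        if eps_kcal_by_element is None:
            eps = np.zeros(len(q))
            dlj = np.ones(len(q))
        else:
            eps = np.array([eps_kcal_by_element[e] * KCALMOL_TO_HARTREE for e in elements])
            dlj = np.array([dlj_angstrom_by_element[e] * ANGSTROM_TO_BOHR for e in elements])
        return cls(q, eps, dlj, **kw)

    def pair_parameters(self, a: int, b: int) -> tuple[float, float, float, float]:
        eps = math.sqrt(self.lj_eps[a] * self.lj_eps[b])
        dlj = math.sqrt(self.lj_d[a] * self.lj_d[b])
        return float(self.charges[a]), float(self.charges[b]), eps, dlj


@dataclass(frozen=True)
class PairWrap:
    """How one pair's nonbonded potential is wrapped under the new scheme."""

    kind: str  # "intracluster" | "intercluster"
    d_eq: float | None = None
    cutoff: float = math.inf

    def __post_init__(self):
        if self.kind not in ("intracluster", "intercluster"):
            raise ValueError("pair kind must be intracluster or intercluster")
        if self.kind == "intracluster" and (self.d_eq is None or self.d_eq <= 0):
            raise ValueError("an intracluster wrap requires the pair's equilibrium distance d_eq")


def _window(d: float, d_eq: float, order: int = 0) -> float:
    """Localization window w(d): 1 with two flat derivatives at d_eq,
    decaying to 0 as d -> infinity.

    w = 1 - ((tau(d_eq, d) - tau(d_eq, d_eq)) / (1 - tau(d_eq, d_eq)))^3.
    The cubic power makes the first and second derivatives vanish at d_eq.
    """
    norm = 1.0 - _TANH_HALF
    z = (tau(d_eq, d) - _TANH_HALF) / norm
    if order == 0:
        return 1.0 - z ** 3
    z1 = tau(d_eq, d, 1) / norm
    if order == 1:
        return -3.0 * z * z * z1
    z2 = tau(d_eq, d, 2) / norm
    return -6.0 * z * z1 * z1 - 3.0 * z * z * z2


def _cutoff_switch(d: float, cutoff: float, order: int = 0) -> float:
    """C^2 switch S(d) = (1 - (d/cutoff)^6)^3 for d < cutoff, else 0.

    S, S' and S'' are continuous at d = cutoff, and S -> 1 pointwise as the
    cutoff goes to infinity."""
    if not math.isfinite(cutoff):
        return 1.0 if order == 0 else 0.0
    if d >= cutoff:
        return 0.0
    x = d / cutoff
    p = 1.0 - x ** 6
    if order == 0:
        return p ** 3
    dp = -6.0 * x ** 5 / cutoff
    if order == 1:
        return 3.0 * p * p * dp
    d2p = -30.0 * x ** 4 / cutoff ** 2
    return 6.0 * p * dp * dp + 3.0 * p * p * d2p


def wrap_pair(u_pair: Callable[[float, int], float], wrap: PairWrap) -> Callable[[float, int], float]:
    """Return the wrapped 1-D pair function Phi(d, order) for the new scheme.

    Intracluster: Phi and its first two d-derivatives vanish at d_eq.
    Finite cutoff (either kind): Phi == 0 for d >= cutoff with C^2 behavior
    at the cutoff.  Intercluster at infinite cutoff: Phi is u_pair itself.
    """
    if wrap.kind == "intercluster":

        def phi_inter(d: float, order: int = 0) -> float:
            if d >= wrap.cutoff:
                return 0.0
            if not math.isfinite(wrap.cutoff):
                return u_pair(d, order)
            if order == 0:
                return _cutoff_switch(d, wrap.cutoff) * u_pair(d, 0)
            if order == 1:
                return (
                    _cutoff_switch(d, wrap.cutoff, 1) * u_pair(d, 0)
                    + _cutoff_switch(d, wrap.cutoff) * u_pair(d, 1)
                )
            return (
                _cutoff_switch(d, wrap.cutoff, 2) * u_pair(d, 0)
                + 2.0 * _cutoff_switch(d, wrap.cutoff, 1) * u_pair(d, 1)
                + _cutoff_switch(d, wrap.cutoff) * u_pair(d, 2)
            )

        return phi_inter

    d_eq = wrap.d_eq
    u0 = u_pair(d_eq, 0)
    u1 = u_pair(d_eq, 1)
    u2 = u_pair(d_eq, 2)

    def phi_free(d: float, order: int = 0) -> float:
        # u_pair minus its localized second-order Taylor polynomial at d_eq
        dd = d - d_eq
        T = (u0 + u1 * dd + 0.5 * u2 * dd * dd, u1 + u2 * dd, u2)
        w = (_window(d, d_eq, 0), _window(d, d_eq, 1), _window(d, d_eq, 2))
        if order == 0:
            return u_pair(d, 0) - T[0] * w[0]
        if order == 1:
            return u_pair(d, 1) - (T[1] * w[0] + T[0] * w[1])
        return u_pair(d, 2) - (T[2] * w[0] + 2.0 * T[1] * w[1] + T[0] * w[2])

    if not math.isfinite(wrap.cutoff):
        return phi_free

    def phi_cut(d: float, order: int = 0) -> float:
        if d >= wrap.cutoff:
            return 0.0
        if order == 0:
            return _cutoff_switch(d, wrap.cutoff) * phi_free(d, 0)
        if order == 1:
            return (
                _cutoff_switch(d, wrap.cutoff, 1) * phi_free(d, 0)
                + _cutoff_switch(d, wrap.cutoff) * phi_free(d, 1)
            )
        return (
            _cutoff_switch(d, wrap.cutoff, 2) * phi_free(d, 0)
            + 2.0 * _cutoff_switch(d, wrap.cutoff, 1) * phi_free(d, 1)
            + _cutoff_switch(d, wrap.cutoff) * phi_free(d, 2)
        )

    return phi_cut


def _cluster_index(topology: BondedTopology, n_atoms: int) -> np.ndarray:
    idx = np.full(n_atoms, -1, dtype=int)
    for ci, cl in enumerate(topology.clusters):
        for a in cl:
            idx[a] = ci
    return idx


def assemble_nonbonded(
    system: MolecularSystem,
    topology: BondedTopology,
    model: NonbondedModel,
    coords: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Total nonbonded energy (hartree) and per-atom forces (hartree/bohr).

    Sums over unordered pairs outside the exclusion sets.  Under the old
    scheme each pair contributes the raw q+LJ energy; under the new scheme
    each pair contributes its wrapped Phi, with intracluster pairs anchored
    at their reference-geometry equilibrium distance.  ``coords`` (bohr)
    defaults to the system's coordinates.
    """
    sysb = system.to_bohr()
    xyz = np.asarray(coords, dtype=float) if coords is not None else sysb.coords
    n = sysb.n_atoms
    if not topology.exclusion:
        raise ValueError("topology has no exclusion sets; build them first")
    if model.scheme == "new" and sysb.ref_coords is None:
        raise ValueError("the new scheme requires a reference geometry to anchor intracluster wraps")
    cl = _cluster_index(topology, n)
    energy = 0.0
    forces = np.zeros((n, 3))
    for a in range(n):
        excl = topology.exclusion[a]
        for b in range(a + 1, n):
            if b in excl:
                continue
            qa, qb, eps, dlj = model.pair_parameters(a, b)
            u = make_qlj_pair(qa, qb, eps, dlj)
            v = xyz[a] - xyz[b]
            d = float(np.linalg.norm(v))
            if model.scheme == "old":
                if d >= model.cutoff:
                    continue
                e, de = u(d, 0), u(d, 1)
            else:
                same = cl[a] == cl[b] and cl[a] >= 0
                if same:
                    d_eq = float(np.linalg.norm(sysb.ref_coords[a] - sysb.ref_coords[b]))
                    phi = wrap_pair(u, PairWrap("intracluster", d_eq, model.cutoff))
                else:
                    phi = wrap_pair(u, PairWrap("intercluster", cutoff=model.cutoff))
                e, de = phi(d, 0), phi(d, 1)
            energy += e
            f = -de * v / d
            forces[a] += f
            forces[b] -= f
    return energy, forces
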