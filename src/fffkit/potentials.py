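"""Flexibility-term model potentials with analytic derivatives.

Every potential is written so that, at its equilibrium internal coordinate,
the energy and first derivative are exactly zero and the second derivative
(curvature) equals the force constant ``k``.  This is what lets force
constants transfer between potential forms and keeps harmonic normal-mode
frequencies independent of the anharmonicity parameters.

Stretch forms (internal coordinate: bond length d, bohr)
--------------------------------------------------------
harmonic      U = (1/2) k (d - d_eq)^2
Morse         U = D (1 - exp(-g (d - d_eq)))^2,          D = k / (2 g^2)
Manz          U = (3k/(5 g^2)) [1 - (5/2) e^(-g D d) + (3/2) e^(-(5/3) g D d)]

The Manz stretch is a two-exponential form whose outer exponent (5/3)g
descends from the short-range-repulsion decay of overlapping atomic
densities; its exponent g (written gamma-naught) is a quantum-mechanically
derived quantity, not a regression parameter (see :mod:`fffkit.exponents`).
Both Morse and Manz approach a finite bond dissociation energy:
k/(2 g^2) (Morse) and 3k/(5 g^2) (Manz).

Angle-bend forms (internal coordinate: theta in (0, pi], radians)
-----------------------------------------------------------------
harmonic         U = (1/2) k (theta - theta_eq)^2
cosine           U = k (1 - cos(theta - theta_eq))
harmonic cosine  U = (1/2) k (cos theta - cos theta_eq)^2
new (tanh-regularized)
                 U = 2 k (cos theta - cos theta_eq)^2
                     / [ h(theta) (sin^2 theta + 3 sin^2 theta_eq) ]
                 h(theta) = tanh(nu sin(theta/2)) / tanh(nu sin(theta_eq/2))

The new bend is a function of cos(theta) alone (sin^2 = 1 - cos^2 and
sin(theta/2) = sqrt((1-cos theta)/2)), so it is infinitely differentiable
across theta = pi and symmetric under the folding theta -> 2 pi - theta.
The 1:3 weighting of sin^2(theta) against sin^2(theta_eq) in the denominator
makes the curvature at theta_eq equal k for every theta_eq including pi,
and the h factor drives U to +infinity as theta -> 0, modelling the Pauli
repulsion that keeps real bond angles away from zero.  The default tanh
multiplier is nu = 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FlexTerm",
    "FlexibilityModel",
    "stretch_energy",
    "stretch_dissociation_energy",
    "bend_energy",
    "h_factor",
    "cross_term_energy",
    "gm_basis_energy",
    "term_energy",
    "term_gradient_cartesian",
    "term_hessian_cartesian",
    "MANZ_COEFF_2",
    "MANZ_COEFF_3",
    "manz_coefficients",
]

STRETCH_KINDS = {"stretch_harmonic", "stretch_morse", "stretch_manz", "stretch_gm_basis", "urey_bradley"}
BEND_KINDS = {"bend_new", "bend_harmonic", "bend_cosine", "bend_harmonic_cosine", "bend_mm3"}
CROSS_KINDS = {"bond_bond_cross"}

DEFAULT_TANH_MULTIPLIER = 2.0

# Coefficients of the two-exponential Manz stretch bracket
#   1 - coeff_2 * e^(-g dd) + coeff_3 * e^(-(5/3) g dd)
# fixed by requiring zero energy and zero force at d = d_eq:
#   1 - coeff_2 + coeff_3 = 0  and  coeff_2 - (5/3) coeff_3 = 0.
MANZ_COEFF_2 = 2.5
MANZ_COEFF_3 = 1.5


def manz_coefficients() -> tuple[float, float]:
    """Solve the zero-energy / zero-force conditions at d_eq for the
    two-exponential stretch bracket and return (coeff_2, coeff_3).

    The linear system is  [[ -1, 1], [1, -5/3]] @ [c2, c3] = [-1, 0].
    """
    a = np.array([[-1.0, 1.0], [1.0, -5.0 / 3.0]])
    rhs = np.array([-1.0, 0.0])
    c2, c3 = np.linalg.solve(a, rhs)
    return float(c2), float(c3)


class PotentialDomainError(ValueError):
    pass


@dataclass(frozen=True)
class FlexTerm:
    """One flexibility term.

    eq_value is d_eq in bohr for stretch forms or theta_eq in radians for
    bends; exponent is gamma (bohr^-1) for Morse/Manz or the dimensionless
    tanh multiplier nu for the new bend; the bond-bond cross term carries its
    second equilibrium length in eq_value2.  Force constants are hartree
    bohr^-2 for stretch/cross forms and hartree (radians treated as
    dimensionless) for bends.
    """

    kind: str
    atoms: tuple[int, ...]
    eq_value: float
    force_constant: float = 0.0
    exponent: float | None = None
    basis_index: int | None = None
    eq_value2: float | None = None
    mm3_coefficients: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.kind not in STRETCH_KINDS | BEND_KINDS | CROSS_KINDS:
            raise TypeError(f"unknown flexibility term kind {self.kind!r}")
        if not math.isfinite(self.force_constant):
            raise ValueError("force constant must be finite")
        if self.kind in ("stretch_morse", "stretch_manz") or (
            self.kind == "urey_bradley" and self.exponent is not None
        ):
            if self.exponent is None or self.exponent <= 0:
                raise ValueError(f"{self.kind} requires a positive exponent")
        if self.kind in BEND_KINDS and not (0.0 < self.eq_value <= math.pi):
            raise ValueError("equilibrium angle must lie in (0, pi]")
        if self.kind == "bend_new":
            nu = DEFAULT_TANH_MULTIPLIER if self.exponent is None else self.exponent
            if nu <= 0:
                raise ValueError("tanh multiplier nu must be positive")
        if self.kind == "stretch_gm_basis" and (self.basis_index is None or self.basis_index < 1):
            raise ValueError("gm basis term requires basis_index m >= 1")
        if self.kind in CROSS_KINDS and self.eq_value2 is None:
            raise ValueError("bond-bond cross term requires both equilibrium bond lengths")

    @property
    def stretch_form(self) -> str:
        """Resolve urey_bradley terms to the stretch form they borrow."""
        if self.kind != "urey_bradley":
            return self.kind
        return "stretch_manz" if self.exponent is not None else "stretch_harmonic"


# ---------------------------------------------------------------------------
# stretch potentials
# ---------------------------------------------------------------------------

def _harmonic(d, d_eq, k, order):
    dd = d - d_eq
    if order == 0:
        return 0.5 * k * dd * dd
    if order == 1:
        return k * dd
    return k


def _morse(d, d_eq, k, g, order):
    diss = k / (2.0 * g * g)
    e = math.exp(-g * (d - d_eq))
    if order == 0:
        return diss * (1.0 - e) ** 2
    if order == 1:
        return 2.0 * diss * g * e * (1.0 - e)
    return 2.0 * diss * g * g * (2.0 * e * e - e)


def _manz(d, d_eq, k, g, order):
    pref = 3.0 * k / (5.0 * g * g)
    dd = d - d_eq
    e1 = math.exp(-g * dd)
    e2 = math.exp(-(5.0 / 3.0) * g * dd)
    if order == 0:
        return pref * (1.0 - MANZ_COEFF_2 * e1 + MANZ_COEFF_3 * e2)
    if order == 1:
        return pref * g * (MANZ_COEFF_2 * e1 - MANZ_COEFF_3 * (5.0 / 3.0) * e2)
    return pref * g * g * (-MANZ_COEFF_2 * e1 + MANZ_COEFF_3 * (25.0 / 9.0) * e2)


def stretch_energy(d: float, term: FlexTerm, order: int = 0) -> float:
    """Energy (hartree) or derivative of a stretch-form term at bond length
    ``d`` (bohr); ``order`` in {0, 1, 2} differentiates with respect to d."""
    if order not in (0, 1, 2):
        raise ValueError("derivative order must be 0, 1 or 2")
    if d <= 0:
        raise PotentialDomainError("bond length must be positive")
    form = term.stretch_form if term.kind in STRETCH_KINDS else None
    if form is None:
        raise TypeError(f"{term.kind} is not a stretch form")
    if form == "stretch_harmonic":
        return _harmonic(d, term.eq_value, term.force_constant, order)
    if form == "stretch_morse":
        return _morse(d, term.eq_value, term.force_constant, term.exponent, order)
    if form == "stretch_manz":
        return _manz(d, term.eq_value, term.force_constant, term.exponent, order)
    # gm basis: energy is k times the dimensionless basis value
    val = gm_basis_energy(d, term.eq_value, term.basis_index, order=order)
    return term.force_constant * val


def stretch_dissociation_energy(term: FlexTerm) -> float:
    """The d -> infinity limit of the stretch energy (hartree)."""
    form = term.stretch_form
    g = term.exponent
    if form == "stretch_morse":
        return term.force_constant / (2.0 * g * g)
    if form == "stretch_manz":
        return 3.0 * term.force_constant / (5.0 * g * g)
    raise ValueError(f"{term.kind} has no finite dissociation energy")


def gm_basis_energy(d: float, d_eq: float, m: int, order: int = 0) -> float:
    """Dimensionless two-sided stretch basis function g_m.

    Contract: g_m(d_eq) = 0 with zero slope there; g_m -> 1 as d -> infinity;
    g_m(0) = -1 for odd m and +1 for even m.  The implemented closed form is

        g_m(x) = 1 - exp(-m x^2 (x-1)^2) + (-1)^m [(1 - x e^(1-x)) e^(-x^2)]^m

    with x = d/d_eq; each of the printed limits follows directly.
    """
    if m is None or m < 1:
        raise ValueError("basis index m must be a positive integer")
    if order not in (0, 1, 2):
        raise ValueError("derivative order must be 0, 1 or 2")
    x = d / d_eq
    sgn = -1.0 if m % 2 else 1.0

    q = x * x * (x - 1.0) ** 2
    qp = 4.0 * x ** 3 - 6.0 * x * x + 2.0 * x
    qpp = 12.0 * x * x - 12.0 * x + 2.0
    A = math.exp(-m * q)

    ex = math.exp(1.0 - x)
    v = 1.0 - x * ex
    vp = (x - 1.0) * ex
    vpp = (2.0 - x) * ex
    w = math.exp(-x * x)
    wp = -2.0 * x * w
    wpp = (4.0 * x * x - 2.0) * w
    u = v * w
    up = vp * w + v * wp
    upp = vpp * w + 2.0 * vp * wp + v * wpp

    if order == 0:
        return 1.0 - A + sgn * u ** m
    Ap = -m * qp * A
    Bp = m * u ** (m - 1) * up
    if order == 1:
        return (-Ap + sgn * Bp) / d_eq
    App = (-m * qpp + (m * qp) ** 2) * A
    if m == 1:
        Bpp = upp
    else:
        Bpp = m * (m - 1) * u ** (m - 2) * up * up + m * u ** (m - 1) * upp
    return (-App + sgn * Bpp) / (d_eq * d_eq)


# ---------------------------------------------------------------------------
# bend potentials
# ---------------------------------------------------------------------------

def h_factor(theta: float, theta_eq: float, nu: float = DEFAULT_TANH_MULTIPLIER, order: int = 0):
    """Regularizing factor h of the new bend: tanh(nu sin(theta/2)) scaled so
    h(theta_eq) = 1.  h(0) = 0, h is strictly increasing on (0, pi), and
    h(pi) = tanh(nu)/tanh(nu sin(theta_eq/2))."""
    c = 1.0 / math.tanh(nu * math.sin(theta_eq / 2.0))
    s = math.sin(theta / 2.0)
    t = math.tanh(nu * s)
    if order == 0:
        return c * t
    sech2 = 1.0 - t * t
    gp = 0.5 * nu * math.cos(theta / 2.0) * sech2
    if order == 1:
        return c * gp
    gpp = -0.25 * nu * s * sech2 - 0.5 * (nu * math.cos(theta / 2.0)) ** 2 * sech2 * t
    return c * gpp


def _check_angle(theta):
    if not (0.0 < theta <= math.pi):
        raise PotentialDomainError(
            "bond angle must lie in (0, pi]; fold angles beyond pi as 2*pi - theta before evaluating"
        )


def _bend_new(theta, theta_eq, k, nu, order):
    h0 = h_factor(theta, theta_eq, nu, 0)
    h1 = h_factor(theta, theta_eq, nu, 1)
    h2 = h_factor(theta, theta_eq, nu, 2)
    ct, st = math.cos(theta), math.sin(theta)
    if theta_eq == math.pi:
        # reduced form: the (cos t + 1)^2 / sin^2 t quotient simplifies,
        # removing the 0/0 at theta = pi
        A = 2.0 * k * (1.0 + ct)
        B = h0 * (1.0 - ct)
        if order == 0:
            return A / B
        A1, A2 = -2.0 * k * st, -2.0 * k * ct
        B1 = h1 * (1.0 - ct) + h0 * st
        if order == 1:
            return (A1 * B - A * B1) / (B * B)
        B2 = h2 * (1.0 - ct) + 2.0 * h1 * st + h0 * ct
        return A2 / B - 2.0 * A1 * B1 / B ** 2 - A * B2 / B ** 2 + 2.0 * A * B1 ** 2 / B ** 3
    ceq = math.cos(theta_eq)
    seq2 = math.sin(theta_eq) ** 2
    N = 2.0 * k * (ct - ceq) ** 2
    s = st * st + 3.0 * seq2
    D = h0 * s
    if order == 0:
        return N / D
    N1 = -4.0 * k * (ct - ceq) * st
    s1 = 2.0 * st * ct
    D1 = h1 * s + h0 * s1
    if order == 1:
        return (N1 * D - N * D1) / (D * D)
    N2 = 4.0 * k * st * st - 4.0 * k * (ct - ceq) * ct
    s2 = 2.0 * (ct * ct - st * st)
    D2 = h2 * s + 2.0 * h1 * s1 + h0 * s2
    return N2 / D - 2.0 * N1 * D1 / D ** 2 - N * D2 / D ** 2 + 2.0 * N * D1 ** 2 / D ** 3


def bend_energy(theta: float, term: FlexTerm, order: int = 0) -> float:
    """Energy (hartree) or derivative of a bend term at angle ``theta``
    (radians); ``order`` differentiates with respect to theta."""
    if term.kind not in BEND_KINDS:
        raise TypeError(f"{term.kind} is not a bend form")
    if order not in (0, 1, 2):
        raise ValueError("derivative order must be 0, 1 or 2")
    _check_angle(theta)
    k, teq = term.force_constant, term.eq_value
    if term.kind == "bend_harmonic":
        dd = theta - teq
        return 0.5 * k * dd * dd if order == 0 else (k * dd if order == 1 else k)
    if term.kind == "bend_cosine":
        dd = theta - teq
        return (
            k * (1.0 - math.cos(dd))
            if order == 0
            else (k * math.sin(dd) if order == 1 else k * math.cos(dd))
        )
    if term.kind == "bend_harmonic_cosine":
        ct, st = math.cos(theta), math.sin(theta)
        dc = ct - math.cos(teq)
        if order == 0:
            return 0.5 * k * dc * dc
        if order == 1:
            return -k * dc * st
        return k * (st * st - dc * ct)
    if term.kind == "bend_mm3":
        if term.mm3_coefficients is None:
            raise ValueError("bend_mm3 requires its polynomial coefficients to be supplied via configuration")
        # MM3-style sextic: U = (k/2) dd^2 * (1 + sum_i c_i dd^i), dd in rad
        dd = theta - teq
        cs = term.mm3_coefficients
        if order == 0:
            return 0.5 * k * dd * dd * (1.0 + sum(c * dd ** (i + 1) for i, c in enumerate(cs)))
        poly = 1.0 + sum(c * dd ** (i + 1) for i, c in enumerate(cs))
        dpoly = sum((i + 1) * c * dd ** i for i, c in enumerate(cs))
        if order == 1:
            return k * dd * poly + 0.5 * k * dd * dd * dpoly
        d2poly = sum((i + 1) * i * c * dd ** (i - 1) for i, c in enumerate(cs) if i >= 1)
        return k * poly + 2.0 * k * dd * dpoly + 0.5 * k * dd * dd * d2poly
    nu = term.exponent if term.exponent is not None else DEFAULT_TANH_MULTIPLIER
    return _bend_new(theta, teq, k, nu, order)


def cross_term_energy(d_ab: float, d_bc: float, term: FlexTerm) -> float:
    """Bilinear bond-bond coupling k (d_AB - d_AB^eq)(d_BC - d_BC^eq)."""
    if term.kind not in CROSS_KINDS:
        raise TypeError(f"{term.kind} is not a cross term")
    return term.force_constant * (d_ab - term.eq_value) * (d_bc - term.eq_value2)


# ---------------------------------------------------------------------------
# Cartesian plumbing
# ---------------------------------------------------------------------------

def _pair_distance(coords, a, b):
    v = coords[a] - coords[b]
    d = float(np.linalg.norm(v))
    if d == 0.0:
        raise PotentialDomainError(f"zero distance between atoms {a + 1} and {b + 1}")
    return d, v


def _angle_value(coords, a, b, c):
    u = coords[a] - coords[b]
    v = coords[c] - coords[b]
    nu_, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu_ == 0.0 or nv == 0.0:
        raise PotentialDomainError("degenerate angle: coincident atoms")
    ct = float(np.dot(u, v) / (nu_ * nv))
    ct = min(1.0, max(-1.0, ct))
    return math.acos(ct), u, v, nu_, nv, ct


def term_energy(term: FlexTerm, coords: np.ndarray) -> float:
    """Evaluate one term at Cartesian coordinates (bohr)."""
    if term.kind in STRETCH_KINDS:
        d, _ = _pair_distance(coords, *term.atoms[:2])
        return stretch_energy(d, term)
    if term.kind in BEND_KINDS:
        theta = _angle_value(coords, *term.atoms)[0]
        if theta == 0.0:
            raise PotentialDomainError("bend evaluated at theta = 0")
        return bend_energy(theta, term)
    a, b, c = term.atoms
    d1, _ = _pair_distance(coords, a, b)
    d2, _ = _pair_distance(coords, b, c)
    return cross_term_energy(d1, d2, term)


def term_gradient_cartesian(term: FlexTerm, coords: np.ndarray) -> np.ndarray:
    """Analytic Cartesian gradient dU/dR, shape (n_atoms, 3)."""
    grad = np.zeros_like(coords, dtype=float)
    if term.kind in STRETCH_KINDS:
        a, b = term.atoms[:2]
        d, v = _pair_distance(coords, a, b)
        du = stretch_energy(d, term, order=1)
        g = du * v / d
        grad[a] += g
        grad[b] -= g
        return grad
    if term.kind in CROSS_KINDS:
        a, b, c = term.atoms
        d1, v1 = _pair_distance(coords, a, b)
        d2, v2 = _pair_distance(coords, b, c)
        k = term.force_constant
        g1 = k * (d2 - term.eq_value2) * v1 / d1
        g2 = k * (d1 - term.eq_value) * v2 / d2
        grad[a] += g1
        grad[b] += -g1 + g2
        grad[c] += -g2
        return grad
    a, b, c = term.atoms
    theta, u, v, nu_, nv, ct = _angle_value(coords, a, b, c)
    st = math.sin(theta)
    if st < 1e-12:
        # at a perfectly linear triad the bend force vanishes by symmetry
        return grad
    du = bend_energy(theta, term, order=1)
    uh, vh = u / nu_, v / nv
    dth_da = (ct * uh - vh) / (nu_ * st)
    dth_dc = (ct * vh - uh) / (nv * st)
    grad[a] += du * dth_da
    grad[c] += du * dth_dc
    grad[b] += -du * (dth_da + dth_dc)
    return grad


def term_hessian_cartesian(term: FlexTerm, coords: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Cartesian second-derivative block by central differences of the
    analytic gradient, symmetrized; shape (3n, 3n)."""
    n = coords.shape[0]
    hess = np.zeros((3 * n, 3 * n))
    flat = coords.astype(float).ravel()
    for i in range(3 * n):
        fp = flat.copy()
        fm = flat.copy()
        fp[i] += step
        fm[i] -= step
        gp = term_gradient_cartesian(term, fp.reshape(n, 3)).ravel()
        gm = term_gradient_cartesian(term, fm.reshape(n, 3)).ravel()
        hess[i] = (gp - gm) / (2.0 * step)
    return 0.5 * (hess + hess.T)


@dataclass
class FlexibilityModel:
    """Ordered collection of flexibility terms for one electronic
    ground-state subdomain."""

    terms: list[FlexTerm] = field(default_factory=list)
    subdomain_label: str = "ground"

    def validate(self, n_atoms: int) -> None:
        for t in self.terms:
            if any(a < 0 or a >= n_atoms for a in t.atoms):
                raise IndexError(f"term {t.kind} references atom outside 0..{n_atoms - 1}")

    def energy(self, coords: np.ndarray) -> float:
        return float(sum(term_energy(t, coords) for t in self.terms))

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        g = np.zeros_like(coords, dtype=float)
        for t in self.terms:
            g += term_gradient_cartesian(t, coords)
        return g

    def with_force_constants(self, ks: Sequence[float]) -> "FlexibilityModel":
        if len(ks) != len(self.terms):
            raise ValueError("force constant vector length mismatch")
        import dataclasses

        return FlexibilityModel(
            [dataclasses.replace(t, force_constant=float(k)) for t, k in zip(self.terms, ks)],
            self.subdomain_label,
        )
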