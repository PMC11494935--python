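"""Bond-specific density-decay exponents and the Manz-stretch exponent.

The outer-valence electron density of an atom in a material decays roughly
exponentially, rho_avg(r) ~ e^(a - b r).  For a bonded pair AB, the decay
exponents b_A and b_B fitted over the bonding region determine the
quantum-derived exponent gamma-naught of the Manz stretch potential, and
from it a predicted Morse exponent

    gamma_Morse = gamma0 * sqrt(5/6)

obtained by equating the Morse and Manz force constants and dissociation
energies (k/(2 gamma_M^2) = 3k/(5 gamma0^2)).

Pipeline per bond: condition each spherically averaged radial profile to be
monotone non-increasing (outer-to-inner running maximum); locate the
crossing radius D where the two conditioned profiles meet along the bond
axis; least-squares fit ln(rho) = a - b r over the asymmetric window
[D - 0.5 bohr, D + 2.5 bohr]; combine b_A, b_B into gamma0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RadialDensityProfile",
    "BondExponents",
    "condition_profile",
    "crossing_radius",
    "fit_decay_exponent",
    "bond_gamma",
    "predict_morse_exponent",
    "compute_bond_exponents",
]

WINDOW_INNER = 0.5  # bohr below the crossing radius
WINDOW_OUTER = 2.5  # bohr above the crossing radius
MIN_WINDOW_SHELLS = 4


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class RadialDensityProfile:
    """Spherically averaged atomic density on a radial shell grid.

    radii in bohr (strictly increasing), densities in e/bohr^3
    (non-negative)."""

    atom_index: int
    radii: np.ndarray
    densities: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        rho = np.asarray(self.densities, dtype=float)
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "densities", rho)
        if r.size < 2 or r.size != rho.size:
            raise ProfileError("profile needs >= 2 shells with matching density values")
        if np.any(np.diff(r) <= 0):
            raise ProfileError("shell radii must be strictly increasing")
        if np.any(rho < 0):
            raise ProfileError("densities must be non-negative")


def condition_profile(profile: RadialDensityProfile) -> RadialDensityProfile:
    """Running maximum from the outermost shell inward, which makes the
    profile monotone non-increasing without lowering any shell."""
    rho = np.maximum.accumulate(profile.densities[::-1])[::-1]
    return RadialDensityProfile(profile.atom_index, profile.radii, rho)


def _log_interp(profile: RadialDensityProfile, r: np.ndarray) -> np.ndarray:
    """Log-linear interpolation of a conditioned (near-exponential) profile;
    clamped at the grid ends."""
    rho = np.clip(profile.densities, 1e-300, None)
    return np.exp(np.interp(r, profile.radii, np.log(rho)))


def crossing_radius(
    profile_a: RadialDensityProfile, profile_b: RadialDensityProfile, d_ab: float
) -> float:
    """Radius D (from atom A, along the bond) where B's conditioned density
    overtakes A's.

    Evaluated on atom A's shell grid with log-linear interpolation of B's
    profile at d_ab - r_A; D is the average of the first shell where
    rho_B > rho_A and the last shell where rho_B < rho_A.
    """
    if d_ab <= 0:
        raise ProfileError("bond distance must be positive")
    r_a = profile_a.radii
    mask = (r_a > 0) & (r_a < d_ab)
    r_a = r_a[mask]
    rho_a = profile_a.densities[mask]
    rho_b = _log_interp(profile_b, d_ab - r_a)
    gt = np.nonzero(rho_b > rho_a)[0]
    lt = np.nonzero(rho_b < rho_a)[0]
    if gt.size == 0 or lt.size == 0:
        raise ProfileError(
            f"no density crossing found between atoms {profile_a.atom_index + 1} and "
            f"{profile_b.atom_index + 1} at d = {d_ab:.3f} bohr"
        )
    return 0.5 * (float(r_a[gt[0]]) + float(r_a[lt[-1]]))


def fit_decay_exponent(profile: RadialDensityProfile, crossing: float) -> tuple[float, float]:
    """Least-squares fit of ln(rho) = a - b r over shells in the asymmetric
    window [crossing - 0.5, crossing + 2.5] bohr; returns (a, b).

    Zero-density shells inside the window are skipped with a warning; the
    window is clipped at the grid boundary when at least four usable shells
    remain, otherwise an error is raised.
    """
    r = profile.radii
    rho = profile.densities
    inside = (r >= crossing - WINDOW_INNER) & (r <= crossing + WINDOW_OUTER)
    usable = inside & (rho > 0)
    if np.any(inside & (rho == 0)):
        warnings.warn("zero-density shells inside the fit window were skipped", stacklevel=2)
    n = int(usable.sum())
    if n < 2:
        raise ProfileError("fewer than 2 usable shells inside the exponent fit window")
    clipped = (crossing - WINDOW_INNER < r[0]) or (crossing + WINDOW_OUTER > r[-1])
    if clipped and n < MIN_WINDOW_SHELLS:
        raise ProfileError(
            f"fit window clipped at the grid boundary with only {n} shells remaining"
        )
    if clipped:
        warnings.warn("exponent fit window clipped at the profile grid boundary", stacklevel=2)
    x = r[usable]
    y = np.log(rho[usable])
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(-slope)


def _default_weighted_average(b_a: float, b_b: float) -> float:
    """Symmetric, scale-covariant average dominated by the smaller exponent:
    b_A b_B (b_A + b_B) / (b_A^2 + b_B^2).  Equals b when b_A = b_B and
    tends to b_A when b_A << b_B."""
    return b_a * b_b * (b_a + b_b) / (b_a * b_a + b_b * b_b)


def bond_gamma(
    b_a: float,
    b_b: float,
    weighted_average: Callable[[float, float], float] | None = None,
) -> float:
    """Manz-stretch exponent gamma0 from the two per-bond density decay
    exponents.

    The short-range-repulsion exponent of the Manz stretch, (5/3) gamma0,
    is (5/6) of a weighted average of b_A and b_B, i.e. gamma0 = Wavg/2.
    The weighted-average functional is a configurable slot; the default is
    documented in :func:`_default_weighted_average`.
    """
    if b_a <= 0 or b_b <= 0:
        raise ProfileError("decay exponents must be positive")
    wavg = (weighted_average or _default_weighted_average)(b_a, b_b)
    return 0.5 * wavg


def predict_morse_exponent(gamma0: float) -> float:
    """Morse exponent predicted from gamma0 by matching force constant and
    dissociation energy between the Morse and Manz stretch forms."""
    if gamma0 <= 0:
        raise ProfileError("gamma0 must be positive")
    return gamma0 * math.sqrt(5.0 / 6.0)


@dataclass(frozen=True)
class BondExponents:
    bond: tuple[int, int]
    crossing_a: float
    crossing_b: float
    b_a: float
    b_b: float
    gamma0: float
    gamma_morse_pred: float


def compute_bond_exponents(
    profiles: Sequence[RadialDensityProfile],
    system,
    bonds: Sequence[tuple[int, int]],
    weighted_average: Callable[[float, float], float] | None = None,
) -> list[BondExponents]:
    """Full per-bond pipeline: condition -> crossing -> window fit for both
    endpoints -> gamma0 -> predicted Morse exponent.

    The same atom can carry different b values for different bonds, because
    the crossing radius (and hence the fit window) is bond-specific.
    """
    sysb = system.to_bohr()
    by_atom = {p.atom_index: condition_profile(p) for p in profiles}
    missing = sorted(set(i for b in bonds for i in b) - set(by_atom))
    if missing:
        raise ProfileError(f"missing radial profiles for atom(s): {[i + 1 for i in missing]}")
    out = []
    for a, b in bonds:
        d = sysb.distance(a, b)
        try:
            da = crossing_radius(by_atom[a], by_atom[b], d)
            db = crossing_radius(by_atom[b], by_atom[a], d)
            _, ba = fit_decay_exponent(by_atom[a], da)
            _, bb = fit_decay_exponent(by_atom[b], db)
        except ProfileError as exc:
            raise ProfileError(f"bond {a + 1}-{b + 1}: {exc}") from exc
        g0 = bond_gamma(ba, bb, weighted_average)
        out.append(BondExponents((a, b), da, db, ba, bb, g0, predict_morse_exponent(g0)))
    return out
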