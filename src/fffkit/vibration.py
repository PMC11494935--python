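"""Harmonic normal-mode analysis and an anharmonic 1-D diatomic solver.

Normal modes come from diagonalizing the mass-weighted Hessian (MWH)

    H_mw[(A,i),(B,j)] = (m_A m_B)^(-1/2) d2U / dR_Ai dR_Bj

computed by central finite differences of the total potential energy.  Its
eigenvalues lambda are squared angular frequencies in atomic units; modes
with lambda below a relative threshold are rigid-body translations/rotations
(5 for a linear molecule, 6 for a nonlinear one).

Anharmonic diatomic levels come from the radial 1-D Schroedinger equation

    -(1/(2 mu)) phi'' + U(d) phi = eps phi,    mu = m_A m_B / (m_A + m_B)

discretized with central finite differences on a uniform grid with
Dirichlet boundaries.  The default grid mirrors the reference study:
d_eq - 1.5 bohr .. d_eq + 5.0 bohr with 0.001 bohr spacing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import eigh, eigh_tridiagonal

from .units import AMU_TO_ME, HARTREE_TO_INVCM

__all__ = [
    "DEFAULT_MASSES_AMU",
    "VibrationalResult",
    "mass_weighted_hessian",
    "normal_modes",
    "solve_vibrational_levels",
    "transition_table",
    "reduced_mass_amu",
]

# most-abundant-isotope masses, amu
DEFAULT_MASSES_AMU: dict[str, float] = {
    "H": 1.007825,
    "D": 2.014102,
    "T": 3.016049,
    "Li": 7.016003,
    "C": 12.000000,
    "N": 14.003074,
    "O": 15.994915,
    "F": 18.998403,
    "Si": 27.976927,
    "S": 31.972071,
    "Ca": 39.962591,
}

DEFAULT_FD_STEP = 2e-3  # bohr
ZERO_MODE_REL_THRESHOLD = 1e-8
# absolute floor: modes below this wavenumber are rigid-body residuals of
# the finite-difference Hessian (FD truncation leaves ~1 cm^-1 in the
# translation/rotation eigenvalues)
ZERO_MODE_WAVENUMBER_FLOOR = 10.0  # cm^-1


@dataclass
class VibrationalResult:
    wavenumbers: np.ndarray  # cm^-1, ascending (vibrational modes only)
    eigenvectors: np.ndarray | None = None  # mass-weighted, columns match wavenumbers
    zero_mode_count: int = 0
    imaginary_wavenumbers: np.ndarray = field(default_factory=lambda: np.zeros(0))
    levels: np.ndarray | None = None  # 1-D solver eigenvalues, hartree
    zpe: float | None = None  # hartree above the potential minimum
    metadata: dict = field(default_factory=dict)


def masses_for(elements, masses_amu: dict[str, float] | None = None) -> np.ndarray:
    table = DEFAULT_MASSES_AMU if masses_amu is None else {**DEFAULT_MASSES_AMU, **masses_amu}
    try:
        return np.array([table[e] for e in elements], dtype=float)
    except KeyError as exc:
        raise KeyError(f"no atomic mass configured for element {exc.args[0]!r}") from None


def reduced_mass_amu(m_a: float, m_b: float) -> float:
    return m_a * m_b / (m_a + m_b)


def mass_weighted_hessian(
    total_potential: Callable[[np.ndarray], float],
    geom: np.ndarray,
    masses_amu_arr: np.ndarray,
    fd_step: float = DEFAULT_FD_STEP,
    force_tolerance: float = 1e-6,
) -> np.ndarray:
    """Mass-weighted Hessian by central finite differences (atomic units).

    ``geom`` is (n, 3) in bohr and should be a stationary point of the
    potential; a residual-force check warns otherwise.  The matrix is
    symmetrized as (H + H^T)/2 before return.
    """
    geom = np.asarray(geom, dtype=float)
    n3 = geom.size
    flat = geom.ravel()

    def u(x: np.ndarray) -> float:
        return float(total_potential(x.reshape(geom.shape)))

    # stationary-point check with a finer step than the Hessian FD so the
    # O(h^2) truncation error of anharmonic terms does not masquerade as a
    # residual force
    h_chk = min(fd_step, 2e-4)
    grad = np.empty(n3)
    for i in range(n3):
        xp, xm = flat.copy(), flat.copy()
        xp[i] += h_chk
        xm[i] -= h_chk
        grad[i] = (u(xp) - u(xm)) / (2.0 * h_chk)
    max_force = float(np.abs(grad).max())
    if max_force > force_tolerance:
        warnings.warn(
            f"geometry is not a stationary point: max |force| = {max_force:.3e} hartree/bohr",
            stacklevel=2,
        )

    hess = np.empty((n3, n3))
    u0 = u(flat)
    for i in range(n3):
        for j in range(i, n3):
            if i == j:
                xp, xm = flat.copy(), flat.copy()
                xp[i] += fd_step
                xm[i] -= fd_step
                hess[i, i] = (u(xp) - 2.0 * u0 + u(xm)) / fd_step ** 2
            else:
                xpp, xpm, xmp, xmm = (flat.copy() for _ in range(4))
                xpp[[i, j]] += fd_step
                xmm[[i, j]] -= fd_step
                xpm[i] += fd_step
                xpm[j] -= fd_step
                xmp[i] -= fd_step
                xmp[j] += fd_step
                hess[i, j] = hess[j, i] = (u(xpp) - u(xpm) - u(xmp) + u(xmm)) / (4.0 * fd_step ** 2)

    m_me = np.repeat(masses_amu_arr * AMU_TO_ME, 3)
    inv_sqrt = 1.0 / np.sqrt(m_me)
    mwh = hess * np.outer(inv_sqrt, inv_sqrt)
    return 0.5 * (mwh + mwh.T)


def normal_modes(
    mwh: np.ndarray,
    linear: bool | None = None,
    zero_mode_threshold: float = ZERO_MODE_REL_THRESHOLD,
) -> VibrationalResult:
    """Diagonalize the MWH and convert vibrational eigenvalues to
    wavenumbers (cm^-1), sorted ascending.

    Negative eigenvalues beyond the zero-mode threshold are reported as
    imaginary modes rather than dropped.  If ``linear`` is given, the
    rigid-body count is checked against 5 (linear) / 6 (nonlinear).
    """
    mwh = np.asarray(mwh, dtype=float)
    vals, vecs = eigh(0.5 * (mwh + mwh.T))
    scale = float(np.abs(vals).max()) or 1.0
    thresh = max(zero_mode_threshold * scale, (ZERO_MODE_WAVENUMBER_FLOOR / HARTREE_TO_INVCM) ** 2)
    zero = np.abs(vals) < thresh
    imag = (vals < -thresh)
    vib = (~zero) & (~imag)

    # deterministic eigenvector sign: first component of largest magnitude
    # made positive
    for j in range(vecs.shape[1]):
        col = vecs[:, j]
        lead = col[np.argmax(np.abs(col))]
        if lead < 0:
            vecs[:, j] = -col

    wavenumbers = np.sqrt(vals[vib]) * HARTREE_TO_INVCM
    order = np.argsort(wavenumbers)
    result = VibrationalResult(
        wavenumbers=wavenumbers[order],
        eigenvectors=vecs[:, vib][:, order],
        zero_mode_count=int(zero.sum()),
        imaginary_wavenumbers=np.sqrt(-vals[imag]) * HARTREE_TO_INVCM,
    )
    if linear is not None:
        expected = 5 if linear else 6
        if result.zero_mode_count != expected:
            warnings.warn(
                f"expected {expected} rigid-body modes, found {result.zero_mode_count}",
                stacklevel=2,
            )
    return result


def solve_vibrational_levels(
    potential: Callable[[float], float],
    m_a_amu: float,
    m_b_amu: float,
    d_eq: float,
    grid: tuple[float, float, float] = (-1.5, 5.0, 0.001),
    n_levels: int = 25,
    convergence_check: bool = False,
) -> VibrationalResult:
    """Vibrational levels of a diatomic from a 1-D bond potential.

    ``potential`` maps bond length (bohr) to energy (hartree); ``grid`` is
    (lower offset, upper offset, spacing) about d_eq in bohr.  Returns level
    energies (hartree), ZPE above the grid minimum of U, and successive
    transition energies in cm^-1 via :func:`transition_table`.
    """
    lo, hi, h = grid
    mu = reduced_mass_amu(m_a_amu, m_b_amu) * AMU_TO_ME
    if mu <= 0:
        raise ValueError("reduced mass must be positive")

    def _levels(spacing: float):
        d0 = max(d_eq + lo, spacing)  # interior points only; U(d<=0) undefined
        npts = int(round((d_eq + hi - d0) / spacing)) + 1
        d = d0 + spacing * np.arange(npts)
        u = np.array([potential(x) for x in d])
        t = 1.0 / (2.0 * mu * spacing ** 2)
        diag = 2.0 * t + u
        off = np.full(npts - 1, -t)
        k = min(n_levels, npts - 1)
        vals, vecs = eigh_tridiagonal(diag, off, select="i", select_range=(0, k - 1))
        return vals, vecs / math.sqrt(spacing), float(u.min())

    vals, vecs, umin = _levels(h)
    if convergence_check:
        vals2, _, _ = _levels(h / 2.0)
        shift = float(np.abs(vals - vals2).max()) * HARTREE_TO_INVCM
        if shift > 0.1:
            warnings.warn(f"grid not converged: halving the spacing shifts levels by {shift:.2f} cm^-1")

    return VibrationalResult(
        wavenumbers=np.diff(vals) * HARTREE_TO_INVCM,
        eigenvectors=vecs,
        levels=vals,
        zpe=float(vals[0] - umin),
        metadata={"grid": grid, "reduced_mass_amu": reduced_mass_amu(m_a_amu, m_b_amu), "spacing": h},
    )


def transition_table(result: VibrationalResult) -> list[tuple[str, float]]:
    """Rows ("ZPE", value) then (str(v), eps_v - eps_{v-1}) in cm^-1."""
    if result.levels is None or len(result.levels) < 2:
        raise ValueError("transition table requires at least two 1-D levels")
    rows = [("ZPE", result.zpe * HARTREE_TO_INVCM)]
    diffs = np.diff(result.levels) * HARTREE_TO_INVCM
    rows += [(str(v + 1), float(x)) for v, x in enumerate(diffs)]
    return rows
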