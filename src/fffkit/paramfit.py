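"""Force-constant regression under the new and old separation schemes.

Under the new scheme every resting value equals the reference-geometry
equilibrium value, so the bonded energy is *linear* in the force constants:

    U_bonded(R) = sum_g k_g * g_g(R),   g_g = unit-force-constant term energy

and fitting is (optionally LASSO-regularized, box-constrained) linear least
squares of

    min_k  (1/2) sum_i w_i (X k - y)_i^2 + lambda * sum_g |k_g|

with X the design matrix of unit-force-constant term energies (and,
optionally, force components) and y the quantum-chemistry energy differences
relative to the reference geometry.  No intercept, no standardization.

Under the old scheme the stretch resting values are additional nonlinear
parameters and a raw (unwrapped) nonbonded model must be specified; the fit
is bounded trust-region nonlinear least squares with deterministic
multi-starts around the equilibrium values.

The public entry point follows the Model/Results idiom:
``ForceConstantModel(...).fit() -> ForceConstantResults`` with parameter
estimates, standard errors (unregularized fits), goodness of fit and a
``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, lsq_linear

from .chemsys import BondedTopology, MolecularSystem, bond_angle
from .nonbonded import NonbondedModel, assemble_nonbonded
from .potentials import (
    CROSS_KINDS,
    STRETCH_KINDS,
    FlexTerm,
    FlexibilityModel,
    term_energy,
    term_gradient_cartesian,
)
from .units import ANGSTROM_TO_BOHR, DEG_TO_RAD

__all__ = [
    "TrainingSet",
    "FitConfig",
    "FitResult",
    "build_displacement_training_set",
    "generate_validation_geometries",
    "design_matrix",
    "fit_linear",
    "fit_old_scheme",
    "r_squared",
    "ForceConstantModel",
    "ForceConstantResults",
]


@dataclass
class TrainingSet:
    """Geometries with energies relative to the reference geometry.

    ``geometries`` are (n_atoms, 3) bohr arrays; ``energies`` are
    Delta E = E(geometry) - E(reference) in hartree; optional per-geometry
    forces are (n_atoms, 3) hartree/bohr.  ``w_energy`` / ``w_force`` weight
    the energy and force residual blocks.
    """

    reference: MolecularSystem
    geometries: list[np.ndarray]
    energies: np.ndarray
    forces: list[np.ndarray] | None = None
    w_energy: float | np.ndarray = 1.0
    w_force: float = 0.0

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.geometries) != self.energies.size:
            raise ValueError("geometry and energy counts differ")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("training energies must be finite")
        if self.forces is not None and len(self.forces) != len(self.geometries):
            raise ValueError("forces, if present, must be shaped like geometries")

    @property
    def n_obs(self) -> int:
        return len(self.geometries)

    def energy_weights(self) -> np.ndarray:
        w = np.asarray(self.w_energy, dtype=float)
        return np.full(self.n_obs, float(w)) if w.ndim == 0 else w


@dataclass
class FitConfig:
    lasso_lambda: float = 0.0
    lower_bounds: np.ndarray | None = None  # default: >= 0 except cross terms
    upper_bounds: np.ndarray | None = None
    rel_tol: float = 1e-10
    max_iter: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.lasso_lambda < 0:
            raise ValueError("lasso lambda must be >= 0")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")


@dataclass
class FitResult:
    force_constants: np.ndarray
    r_squared_train: float
    loss: float
    n_nonzero: int
    r_squared_validation: float | None = None
    resting_values: np.ndarray | None = None
    unidentifiable: list[int] = field(default_factory=list)
    converged: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# geometry rosters
# ---------------------------------------------------------------------------

def _internal_signature(system: MolecularSystem, coords: np.ndarray, bonds) -> tuple:
    """Multiset signature of (element-pair, bond length) and
    (element-triple, angle) used to identify permutation-equivalent
    geometries."""
    els = system.elements
    sig_b = []
    for a, b in bonds:
        pair = tuple(sorted((els[a], els[b])))
        d = float(np.linalg.norm(coords[a] - coords[b]))
        sig_b.append((pair, round(d, 9)))
    adj: dict[int, list[int]] = {}
    for a, b in bonds:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    sig_a = []
    tmp = system.with_coords(coords)
    for center, nbrs in adj.items():
        nbrs = sorted(nbrs)
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                trip = tuple(sorted((els[nbrs[i]], els[nbrs[j]]))) + (els[center],)
                sig_a.append((trip, round(bond_angle(tmp, nbrs[i], center, nbrs[j]), 9)))
    return (tuple(sorted(sig_b)), tuple(sorted(sig_a)))


def _displace_bond(coords: np.ndarray, a: int, b: int, delta: float, move: int) -> np.ndarray:
    """Move atom ``move`` (one endpoint of bond a-b) along the bond axis so
    the bond length changes by ``delta`` (bohr); all other atoms rigid."""
    out = coords.copy()
    other = a if move == b else b
    v = coords[move] - coords[other]
    d = np.linalg.norm(v)
    if d + delta <= 0:
        raise ValueError(f"displacement {delta:.3f} bohr makes bond {a + 1}-{b + 1} non-positive")
    out[move] = coords[other] + v * (d + delta) / d
    return out


def _moving_atom(bonds, a, b) -> int:
    """Endpoint to move when stretching bond a-b: the one with fewer bonds
    (a terminal atom if possible), ties broken by larger index."""
    deg = {}
    for x, y in bonds:
        deg[x] = deg.get(x, 0) + 1
        deg[y] = deg.get(y, 0) + 1
    return b if deg.get(b, 0) <= deg.get(a, 0) else a


def build_displacement_training_set(
    system: MolecularSystem,
    bonds: Sequence[tuple[int, int]],
    bond_displacements_angstrom: Sequence[float] = (-0.14, -0.07, 0.0, 0.07, 0.14),
    angle_window_deg: float = 30.0,
    angle_scan: Sequence[tuple[float, float]] | None = None,
) -> tuple[list[np.ndarray], list[str]]:
    """Cartesian-product bond-displacement roster about the reference
    geometry, de-duplicated under permutational symmetry.

    Every bond is displaced independently over the given grid (angles held
    at equilibrium); the all-zero combination (the reference geometry
    itself) is excluded from the displaced count.  A symmetric triatomic
    with the 5-point grid yields 14 distinct displaced geometries; an
    asymmetric one yields 24.  ``angle_scan`` entries (theta_deg, energy)
    outside theta_eq +/- angle_window_deg are filtered out and reported via
    the labels; scan geometries themselves are built by the caller.
    """
    if system.ref_coords is None:
        raise ValueError("displacement roster requires a reference geometry")
    sysb = system.to_bohr()
    ref = sysb.ref_coords
    grids = [[d * ANGSTROM_TO_BOHR for d in bond_displacements_angstrom] for _ in bonds]
    seen: set[tuple] = set()
    geoms: list[np.ndarray] = []
    labels: list[str] = []

    def rec(i: int, coords: np.ndarray, deltas: list[float]):
        if i == len(bonds):
            if all(d == 0.0 for d in deltas):
                return
            sig = _internal_signature(sysb, coords, bonds)
            if sig in seen:
                return
            seen.add(sig)
            geoms.append(coords)
            labels.append("bonds " + ",".join(f"{d:+.3f}" for d in deltas))
            return
        a, b = bonds[i]
        move = _moving_atom(bonds, a, b)
        for delta in grids[i]:
            rec(i + 1, coords if delta == 0.0 else _displace_bond(coords, a, b, delta, move), deltas + [delta])

    rec(0, ref.copy(), [])

    if angle_scan is not None:
        # filtered scan labels; energies live in the caller's TrainingSet
        adj: dict[int, list[int]] = {}
        for a, b in bonds:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        center = next(c for c, ns in adj.items() if len(ns) >= 2)
        n1, n2 = sorted(adj[center])[:2]
        theta_eq = bond_angle(sysb.with_coords(ref), n1, center, n2) / DEG_TO_RAD
        for theta_deg, _e in angle_scan:
            if abs(theta_deg - theta_eq) <= angle_window_deg:
                labels.append(f"angle {theta_deg:.2f}")
    return geoms, labels


def triatomic_geometry(d1: float, d2: float, theta: float) -> np.ndarray:
    """Cartesian triatomic A-B-C (bohr): B at origin, A on +x, C in-plane."""
    return np.array(
        [
            [d1, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [d2 * math.cos(theta), d2 * math.sin(theta), 0.0],
        ]
    )


def generate_validation_geometries(
    system: MolecularSystem,
    n: int,
    bond_range_angstrom: float = 0.07,
    angle_range_deg: float = 30.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Random triatomic validation roster: independent uniform draws for
    each bond length (+/- bond_range) and the angle (+/- angle_range) about
    their equilibrium values; reproducible from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sysb = system.to_bohr()
    if sysb.ref_coords is None or sysb.n_atoms != 3:
        raise ValueError("validation generator expects a triatomic with a reference geometry")
    ref = sysb.with_coords(sysb.ref_coords)
    # central atom = the one bonded to both others (closest to both)
    dmat = np.linalg.norm(ref.coords[:, None] - ref.coords[None, :], axis=-1)
    center = int(np.argmin(dmat.sum(axis=1)))
    outer = [i for i in range(3) if i != center]
    d1 = float(dmat[center, outer[0]])
    d2 = float(dmat[center, outer[1]])
    theta_eq = bond_angle(ref, outer[0], center, outer[1])
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        dd1 = rng.uniform(-bond_range_angstrom, bond_range_angstrom) * ANGSTROM_TO_BOHR
        dd2 = rng.uniform(-bond_range_angstrom, bond_range_angstrom) * ANGSTROM_TO_BOHR
        dth = rng.uniform(-angle_range_deg, angle_range_deg) * DEG_TO_RAD
        theta = min(math.pi, max(1e-6, theta_eq + dth))
        g = triatomic_geometry(d1 + dd1, d2 + dd2, theta)
        # map back to the system's atom ordering
        coords = np.empty_like(g)
        coords[outer[0]] = g[0]
        coords[center] = g[1]
        coords[outer[1]] = g[2]
        out.append(coords)
    return out


# ---------------------------------------------------------------------------
# linear fitting
# ---------------------------------------------------------------------------

def design_matrix(
    flex_model: FlexibilityModel,
    training_set: TrainingSet,
    include_forces: bool | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, w): unit-force-constant features, targets, weights.

    Energy rows first; if force fitting is enabled (w_force > 0 or
    ``include_forces``), one extra row per geometry per Cartesian component
    holding the negative per-term gradient (model force) against the
    reference force.
    """
    if include_forces is None:
        include_forces = training_set.w_force > 0 and training_set.forces is not None
    unit_terms = [dataclasses.replace(t, force_constant=1.0) for t in flex_model.terms]
    rows, targets, weights = [], [], []
    we = training_set.energy_weights()
    for i, coords in enumerate(training_set.geometries):
        rows.append([term_energy(t, coords) for t in unit_terms])
        targets.append(training_set.energies[i])
        weights.append(we[i])
    if include_forces:
        if training_set.forces is None:
            raise ValueError("force fitting requested but the training set has no forces")
        for i, coords in enumerate(training_set.geometries):
            fcols = [-term_gradient_cartesian(t, coords).ravel() for t in unit_terms]
            fref = training_set.forces[i].ravel()
            for c in range(fref.size):
                rows.append([col[c] for col in fcols])
                targets.append(fref[c])
                weights.append(training_set.w_force)
    return np.asarray(rows, float), np.asarray(targets, float), np.asarray(weights, float)


def _default_bounds(terms: Sequence[FlexTerm]) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([-np.inf if t.kind in CROSS_KINDS else 0.0 for t in terms])
    hi = np.full(len(terms), np.inf)
    return lo, hi


def _clip(x, lo, hi):
    return min(max(x, lo), hi)


def fit_linear(
    design: np.ndarray,
    targets: np.ndarray,
    config: FitConfig | None = None,
    weights: np.ndarray | None = None,
    terms: Sequence[FlexTerm] | None = None,
    k0: np.ndarray | None = None,
) -> FitResult:
    """Box-constrained (LASSO-)penalized weighted linear least squares.

    lambda = 0 uses a bounded least-squares solve; lambda > 0 uses cyclic
    coordinate descent with soft-thresholding projected onto the bounds.
    ``k0`` warm-starts the descent (pass the solution of the previous,
    larger lambda when walking a regularization path -- ill-conditioned
    designs converge far faster that way).  All-zero design columns are
    reported as unidentifiable, not dropped.
    """
    config = config or FitConfig()
    X = np.asarray(design, float)
    y = np.asarray(targets, float)
    if X.size == 0 or X.shape[0] == 0:
        raise ValueError("empty design matrix")
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    if config.lower_bounds is not None:
        lo, hi = np.asarray(config.lower_bounds, float), np.asarray(config.upper_bounds, float)
    elif terms is not None:
        lo, hi = _default_bounds(terms)
    else:
        lo, hi = np.zeros(p), np.full(p, np.inf)
    col_sq = (Xw ** 2).sum(axis=0)
    unident = [j for j in range(p) if col_sq[j] == 0.0]

    lam = config.lasso_lambda
    if lam == 0.0:
        active = [j for j in range(p) if j not in unident]
        k = np.zeros(p)
        if active:
            sol = lsq_linear(Xw[:, active], yw, bounds=(lo[active], hi[active]), tol=config.rel_tol)
            k[active] = sol.x
            converged, message = bool(sol.success), str(sol.status)
        else:
            converged, message = True, "no identifiable columns"
    else:
        # cyclic coordinate descent on the Gram form: each update costs O(p)
        k = np.zeros(p) if k0 is None else np.clip(np.asarray(k0, float).copy(), lo, hi)
        converged, message = False, "max_iter reached"
        G = Xw.T @ Xw
        c = Xw.T @ yw
        yy = float(yw @ yw)
        gk = G @ k
        # objective-based stopping: on near-collinear designs coefficients
        # can creep along a flat valley long after the loss has converged
        obj_prev = 0.5 * (yy - 2.0 * float(c @ k) + float(k @ gk)) + lam * float(np.abs(k).sum())
        for _ in range(config.max_iter):
            for j in range(p):
                if col_sq[j] == 0.0:
                    continue
                rho = c[j] - gk[j] + col_sq[j] * k[j]
                # soft threshold, then project onto the box
                if rho > lam:
                    knew = (rho - lam) / col_sq[j]
                elif rho < -lam:
                    knew = (rho + lam) / col_sq[j]
                else:
                    knew = 0.0
                knew = _clip(knew, lo[j], hi[j])
                if knew != k[j]:
                    gk += G[:, j] * (knew - k[j])
                    k[j] = knew
            obj = 0.5 * (yy - 2.0 * float(c @ k) + float(k @ gk)) + lam * float(np.abs(k).sum())
            if abs(obj_prev - obj) <= config.rel_tol * max(1e-300, abs(obj)):
                converged, message = True, "coordinate descent converged"
                break
            obj_prev = obj

    resid = yw - Xw @ k
    loss = 0.5 * float(resid @ resid) + lam * float(np.abs(k).sum())
    pred = X @ k
    # R^2 over the energy-style targets (weighted residuals already applied)
    r2 = r_squared(pred, y)
    return FitResult(
        force_constants=k,
        r_squared_train=r2,
        loss=loss,
        n_nonzero=int(np.sum(np.abs(k) > 0)),
        unidentifiable=unident,
        converged=converged,
        message=message,
    )


def r_squared(predicted: np.ndarray, reference: np.ndarray) -> float:
    """R^2 = 1 - SSE/SST; NaN (undefined) when the reference has zero
    variance."""
    predicted = np.asarray(predicted, float)
    reference = np.asarray(reference, float)
    if reference.size < 2:
        raise ValueError("R^2 requires at least two observations")
    sst = float(((reference - reference.mean()) ** 2).sum())
    if sst == 0.0:
        return math.nan
    sse = float(((predicted - reference) ** 2).sum())
    return 1.0 - sse / sst


# ---------------------------------------------------------------------------
# old-scheme nonlinear fitting
# ---------------------------------------------------------------------------

def _old_scheme_energy(
    terms: list[FlexTerm],
    coords: np.ndarray,
    system: MolecularSystem,
    topology: BondedTopology,
    nonbonded: NonbondedModel,
) -> float:
    e = sum(term_energy(t, coords) for t in terms)
    enb, _ = assemble_nonbonded(system, topology, nonbonded, coords)
    return float(e + enb)


def fit_old_scheme(
    flex_model: FlexibilityModel,
    training_set: TrainingSet,
    nonbonded_model: NonbondedModel,
    topology: BondedTopology,
    config: FitConfig | None = None,
) -> FitResult:
    """Joint nonlinear fit of force constants and stretch resting values
    under the conventional separation scheme.

    The model energy difference is
    U_bonded(R; k, d_rest) - U_bonded(R_ref; k, d_rest)
      + U_nonbonded(R) - U_nonbonded(R_ref)
    with the raw (unwrapped) pairwise nonbonded sum.  Resting values are
    optimized for stretch-form terms (bond and Urey-Bradley); equilibrium
    angles stay fixed.  Five deterministic multi-starts displace the resting
    values by 0, +/-1%, +/-2% from equilibrium.
    """
    config = config or FitConfig()
    nb = dataclasses.replace(nonbonded_model, scheme="old") if nonbonded_model.scheme != "old" else nonbonded_model
    sysb = training_set.reference.to_bohr()
    ref_coords = sysb.ref_coords if sysb.ref_coords is not None else sysb.coords
    terms = flex_model.terms
    stretch_idx = [i for i, t in enumerate(terms) if t.kind in STRETCH_KINDS]
    nk, nr = len(terms), len(stretch_idx)
    lo_k, hi_k = _default_bounds(terms)
    enb_ref, _ = assemble_nonbonded(sysb, topology, nb, ref_coords)
    enb_geoms = [assemble_nonbonded(sysb, topology, nb, g)[0] for g in training_set.geometries]
    sw = np.sqrt(training_set.energy_weights())

    def build_terms(x):
        ks = x[:nk]
        rests = x[nk:]
        new_terms = []
        for i, t in enumerate(terms):
            kwargs = {"force_constant": float(ks[i])}
            if i in stretch_idx:
                kwargs["eq_value"] = float(rests[stretch_idx.index(i)])
            new_terms.append(dataclasses.replace(t, **kwargs))
        return new_terms

    def residuals(x):
        ts = build_terms(x)
        u_ref = sum(term_energy(t, ref_coords) for t in ts)
        out = np.empty(training_set.n_obs)
        for i, g in enumerate(training_set.geometries):
            u = sum(term_energy(t, g) for t in ts)
            model = (u - u_ref) + (enb_geoms[i] - enb_ref)
            out[i] = sw[i] * (model - training_set.energies[i])
        return out

    eq_rest = np.array([terms[i].eq_value for i in stretch_idx])
    k0_lin = fit_linear(*design_matrix(flex_model, training_set)[:2], config=FitConfig(), terms=terms).force_constants
    lo = np.concatenate([lo_k, np.full(nr, 1e-6)])
    hi = np.concatenate([hi_k, np.full(nr, np.inf)])
    best = None
    for frac in (0.0, 0.01, -0.01, 0.02, -0.02):
        x0 = np.concatenate([np.maximum(k0_lin, 1e-8), eq_rest * (1.0 + frac)])
        x0 = np.clip(x0, lo, hi)
        sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=config.rel_tol, ftol=config.rel_tol, max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    x = best.x
    ts = build_terms(x)
    u_ref = sum(term_energy(t, ref_coords) for t in ts)
    pred = np.array(
        [sum(term_energy(t, g) for t in ts) - u_ref + enb_geoms[i] - enb_ref for i, g in enumerate(training_set.geometries)]
    )
    return FitResult(
        force_constants=x[:nk],
        resting_values=x[nk:],
        r_squared_train=r_squared(pred, training_set.energies),
        loss=float(best.cost),
        n_nonzero=int(np.sum(np.abs(x[:nk]) > 1e-12)),
        converged=bool(best.success),
        message=str(best.message),
    )


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------

class ForceConstantModel:
    """Force-constant regression model.

    Parameters
    ----------
    flex_model : template flexibility model (term kinds, equilibrium values
        and exponents; force constants are the parameters to estimate).
    training_set : geometries and reference energy differences.
    scheme : "new" (linear; default) or "old" (nonlinear, needs nonbonded).
    nonbonded, topology : required for scheme="old"; optional for
        scheme="new", where attaching them subtracts the wrapped
        intracluster nonbonded energy from the targets (the full model) and
        omitting them fits the leading-order model.
    """

    def __init__(
        self,
        flex_model: FlexibilityModel,
        training_set: TrainingSet,
        scheme: str = "new",
        nonbonded: NonbondedModel | None = None,
        topology: BondedTopology | None = None,
    ):
        if scheme not in ("new", "old"):
            raise ValueError("scheme must be 'new' or 'old'")
        if scheme == "old" and (nonbonded is None or topology is None):
            raise ValueError(
                "the old scheme explicitly requires a nonbonded interaction model and topology"
            )
        self.flex_model = flex_model
        self.training_set = training_set
        self.scheme = scheme
        self.nonbonded = nonbonded
        self.topology = topology

    def fit(self, config: FitConfig | None = None) -> "ForceConstantResults":
        config = config or FitConfig()
        if self.scheme == "old":
            res = fit_old_scheme(self.flex_model, self.training_set, self.nonbonded, self.topology, config)
            return ForceConstantResults(self, res, config)
        X, y, w = design_matrix(self.flex_model, self.training_set)
        if self.nonbonded is not None and self.topology is not None:
            nb = dataclasses.replace(self.nonbonded, scheme="new")
            sysb = self.training_set.reference.to_bohr()
            y = y - np.array(
                [assemble_nonbonded(sysb, self.topology, nb, g)[0] for g in self.training_set.geometries]
            )
        res = fit_linear(X, y, config, weights=w, terms=self.flex_model.terms)
        return ForceConstantResults(self, res, config, design=(X, y, w))


class ForceConstantResults:
    """Estimates, uncertainties and diagnostics for a force-constant fit."""

    def __init__(self, model: ForceConstantModel, fit: FitResult, config: FitConfig, design=None):
        self.model = model
        self._fit = fit
        self.config = config
        self.params = fit.force_constants
        self.resting_values = fit.resting_values
        self.rsquared = fit.r_squared_train
        self.n_nonzero = fit.n_nonzero
        self.loss = fit.loss
        self.converged = fit.converged
        self.unidentifiable = fit.unidentifiable
        self.bse = None
        if design is not None and config.lasso_lambda == 0.0:
            X, y, w = design
            n, p = X.shape
            if n > p:
                Xw = X * np.sqrt(w)[:, None]
                resid = np.sqrt(w) * (y - X @ self.params)
                sigma2 = float(resid @ resid) / (n - p)
                try:
                    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
                    self.bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
                except np.linalg.LinAlgError:
                    pass

    def fitted_flex_model(self) -> FlexibilityModel:
        m = self.model.flex_model.with_force_constants(self.params)
        if self.resting_values is not None:
            idx = [i for i, t in enumerate(m.terms) if t.kind in STRETCH_KINDS]
            terms = list(m.terms)
            for j, i in enumerate(idx):
                terms[i] = dataclasses.replace(terms[i], eq_value=float(self.resting_values[j]))
            m = FlexibilityModel(terms, m.subdomain_label)
        return m

    def rsquared_validation(self, geometries: list[np.ndarray], energies: np.ndarray) -> float:
        fm = self.fitted_flex_model()
        pred = []
        for g in geometries:
            e = fm.energy(g)
            if self.model.scheme == "old" or (self.model.nonbonded is not None and self.model.topology is not None):
                nb = dataclasses.replace(self.model.nonbonded, scheme=self.model.scheme)
                sysb = self.model.training_set.reference.to_bohr()
                ref = sysb.ref_coords if sysb.ref_coords is not None else sysb.coords
                enb, _ = assemble_nonbonded(sysb, self.model.topology, nb, g)
                enb_ref, _ = assemble_nonbonded(sysb, self.model.topology, nb, ref)
                if self.model.scheme == "old":
                    e += enb - enb_ref
                    e -= fm.energy(ref)
                else:
                    e += enb
            pred.append(e)
        return r_squared(np.asarray(pred), np.asarray(energies, float))

    def summary(self) -> str:
        lines = [
            "Force-constant fit (%s scheme)" % self.model.scheme,
            "=" * 58,
            f"observations: {self.model.training_set.n_obs}    terms: {len(self.params)}",
            f"lambda: {self.config.lasso_lambda:g}    loss: {self.loss:.6e}",
            f"R-squared (training): {self.rsquared:.4f}    nonzero: {self.n_nonzero}",
            "-" * 58,
            f"{'term':<22}{'atoms':<12}{'k (hartree units)':>18}",
        ]
        for t, k in zip(self.model.flex_model.terms, self.params):
            atoms = "-".join(str(a + 1) for a in t.atoms)
            se = ""
            lines.append(f"{t.kind:<22}{atoms:<12}{k:>18.6f}{se}")
        if self.bse is not None:
            lines.append("-" * 58)
            lines.append("std. errors: " + ", ".join(f"{s:.2e}" for s in self.bse))
        if self.resting_values is not None:
            lines.append("resting values (bohr): " + ", ".join(f"{r:.4f}" for r in self.resting_values))
        if self.unidentifiable:
            lines.append("unidentifiable terms (all-zero design column): " + str([i + 1 for i in self.unidentifiable]))
        return "\n".join(lines)
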