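"""Bundled example systems and their fitted flexibility parameters.

These are small, fully specified inputs: CCSD/def2-TZVPD equilibrium
geometries of four triatomic molecules, force constants of the flexibility
models fitted to those molecules' bond-displacement and angle-scan energies,
quantum-derived Manz-stretch exponents (gamma-naught, bohr^-1) per bond, a
Morse surrogate of the fitted H2 stretch curve, and a B3LYP/def2-TZVPD
hexafluorobenzene geometry for the C-F stretch case study.  Everything here
is plain input data for the toolkit's computations, not computed results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chemsys import MolecularSystem
from .potentials import FlexTerm, FlexibilityModel
from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, DEG_TO_RAD, EV_TO_HARTREE

__all__ = [
    "triatomic_system",
    "TRIATOMIC_GEOMETRIES",
    "triatomic_flex_model",
    "FLEX_PARAMETERS_EV",
    "H2_MORSE_SURROGATE",
    "c6f6_system",
    "cf_sensitivity_study",
    "C6F6_CF_GAMMA0",
    "UFF_LJ",
    "ATOM_TYPING_RADII",
]

# equilibrium geometries: angle (deg), bond length(s) (angstrom); the two
# outer atoms are listed first and last, the central atom in the middle
TRIATOMIC_GEOMETRIES: dict[str, dict] = {
    "CaH2": {"elements": ("H", "Ca", "H"), "angle": 180.0, "lengths": (2.065, 2.065)},
    "CO2": {"elements": ("O", "C", "O"), "angle": 180.0, "lengths": (1.157, 1.157)},
    "HNO": {"elements": ("H", "N", "O"), "angle": 108.4, "lengths": (1.056, 1.201)},
    "H2O": {"elements": ("H", "O", "H"), "angle": 104.7, "lengths": (0.962, 0.962)},
    "Li2O": {"elements": ("Li", "O", "Li"), "angle": 180.0, "lengths": (1.619, 1.619)},
    "NO2": {"elements": ("O", "N", "O"), "angle": 135.0, "lengths": (1.185, 1.185)},
    "NS2": {"elements": ("S", "N", "S"), "angle": 154.1, "lengths": (1.543, 1.543)},
    "SF2": {"elements": ("F", "S", "F"), "angle": 97.7, "lengths": (1.586, 1.586)},
    "SiH2": {"elements": ("H", "Si", "H"), "angle": 92.4, "lengths": (1.515, 1.515)},
    "SO2": {"elements": ("O", "S", "O"), "angle": 119.4, "lengths": (1.426, 1.426)},
}

# flexibility-model force constants (eV-based units: stretch/UB eV bohr^-2,
# bend eV) and per-bond Manz exponents gamma0 (bohr^-1); "noub"/"ub" select
# models without / with a Urey-Bradley term between the outer atoms
FLEX_PARAMETERS_EV: dict[str, dict] = {
    "CO2": {
        "gamma_bond": 1.203,
        "gamma_outer": 1.257,
        "noub": {"k_stretch": (30.58, 30.58), "k_bend": 5.17},
        "ub": {"k_stretch": (27.26, 27.26), "k_bend": 5.03, "k_ub": 2.31},
    },
    "H2O": {
        "gamma_bond": 1.276,
        "gamma_outer": 1.129,
        "noub": {"k_stretch": (14.95, 14.95), "k_bend": 4.26},
        "ub": {"k_stretch": (14.87, 14.87), "k_bend": 4.11, "k_ub": 0.10},
    },
    "HNO": {
        "gamma_bond": (1.246, 1.251),
        "gamma_outer": 1.212,
        "noub": {"k_stretch": (8.97, 22.34), "k_bend": 8.07},
        "ub": {"k_stretch": (8.55, 21.89), "k_bend": 6.23, "k_ub": 0.61},
    },
    "SO2": {
        "gamma_bond": 1.079,
        "gamma_outer": 1.151,
        "noub": {"k_stretch": (20.34, 20.34), "k_bend": 11.60},
        "ub": {"k_stretch": (19.90, 19.90), "k_bend": 9.71, "k_ub": 0.46},
    },
}

# Morse surrogate of the fitted H2 bond-stretch curve (singlet ground
# state): force constant hartree/bohr^2, exponent bohr^-1, d_eq pm
H2_MORSE_SURROGATE = {"k": 0.401, "gamma": 1.068, "d_eq_pm": 74.199}

# quantum-derived Manz exponent for the C-F bond in hexafluorobenzene
C6F6_CF_GAMMA0 = 1.207  # bohr^-1

# UFF Lennard-Jones parameters (well-minimum distance in angstrom, well
# depth in kcal/mol) for the hexafluorobenzene study
UFF_LJ = {
    "dlj_angstrom": {"C": 3.851, "F": 3.364},
    "eps_kcal": {"C": 0.105, "F": 0.050},
}

# generous element atom-typing radii (angstrom) covering the bundled
# molecules; bonding uses d <= R_A + R_B
ATOM_TYPING_RADII = {
    "H": 0.41,
    "C": 0.85,
    "N": 0.80,
    "O": 0.76,
    "F": 0.72,
    "Si": 1.16,
    "S": 1.05,
    "Ca": 1.90,
    "Li": 1.45,
}


def triatomic_system(name: str) -> MolecularSystem:
    """Build a triatomic at its equilibrium geometry (atoms: outer, center,
    outer; the coordinates double as the reference geometry)."""
    spec = TRIATOMIC_GEOMETRIES[name]
    d1, d2 = spec["lengths"]
    theta = spec["angle"] * DEG_TO_RAD
    coords = np.array(
        [
            [d1, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [d2 * math.cos(theta), d2 * math.sin(theta), 0.0],
        ]
    )
    return MolecularSystem(spec["elements"], coords, "angstrom", ref_coords=coords.copy())


def triatomic_flex_model(
    name: str,
    include_ub: bool,
    stretch: str = "stretch_manz",
    force_constants: dict | None = None,
) -> FlexibilityModel:
    """Flexibility model for one bundled triatomic: two stretches, the
    tanh-regularized bend (nu = 2) and optionally a Manz Urey-Bradley term
    between the outer atoms.  Force constants default to the bundled fitted
    values; pass ``force_constants`` (same keys, eV units) to override."""
    geo = TRIATOMIC_GEOMETRIES[name]
    pars = FLEX_PARAMETERS_EV[name]
    fc = force_constants or pars["ub" if include_ub else "noub"]
    sysb = triatomic_system(name).to_bohr()
    d1 = sysb.distance(0, 1, use_ref=True)
    d2 = sysb.distance(1, 2, use_ref=True)
    theta_eq = geo["angle"] * DEG_TO_RAD
    if abs(theta_eq - math.pi) < 1e-12:
        theta_eq = math.pi
    g = pars["gamma_bond"]
    g1, g2 = g if isinstance(g, tuple) else (g, g)
    k1, k2 = fc["k_stretch"]
    terms = [
        FlexTerm(stretch, (0, 1), d1, k1 * EV_TO_HARTREE, exponent=g1 if stretch == "stretch_manz" else None),
        FlexTerm(stretch, (1, 2), d2, k2 * EV_TO_HARTREE, exponent=g2 if stretch == "stretch_manz" else None),
        FlexTerm("bend_new", (0, 1, 2), theta_eq, fc["k_bend"] * EV_TO_HARTREE, exponent=2.0),
    ]
    if include_ub:
        d_outer = sysb.distance(0, 2, use_ref=True)
        terms.append(
            FlexTerm(
                "urey_bradley",
                (0, 2),
                d_outer,
                fc["k_ub"] * EV_TO_HARTREE,
                exponent=pars["gamma_outer"] if stretch == "stretch_manz" else None,
            )
        )
    return FlexibilityModel(terms, subdomain_label=name)


def cf_sensitivity_study(
    k_true_ev: float = 12.06,
    generator_charge: float = 0.10,
    generator_lj: bool = True,
    noise_sigma: float = 0.0,
    seed: int = 0,
    charges: tuple[float, ...] = (0.0, 0.10, 0.62),
    lj_options: tuple[bool, ...] = (False, True),
) -> dict:
    """Desk-scale C-F bond-stretch sensitivity study on hexafluorobenzene.

    Synthesizes single-bond-displacement energies (one F moved along its C-F
    axis by -0.14, -0.07, +0.07, +0.14 angstrom) from a known Manz stretch
    plus a raw charge+LJ nonbonded sum, then refits the force constant under
    the new (linear) and old (nonlinear, resting value) separation schemes
    across a grid of nonbonded parameterizations.  Returns
    {"k_new_ev": [...], "k_old_ev": [...], "d_resting_angstrom": [...],
    "labels": [...], "k_true_ev": k, "d_eq_angstrom": d}.

    The point of the exercise: new-scheme force constants are nearly
    independent of the assumed nonbonded model, old-scheme ones are not.
    """
    from .chemsys import build_topology
    from .fixtures import FixtureSpec, generate_synthetic_surface
    from .nonbonded import NonbondedModel
    from .paramfit import ForceConstantModel, _displace_bond
    from .units import HARTREE_TO_EV

    sysb = c6f6_system().to_bohr()
    radii = {e: r * ANGSTROM_TO_BOHR for e, r in ATOM_TYPING_RADII.items()}
    topo = build_topology(sysb, radii, max_separation=3)
    d_eq = sysb.distance(0, 6)
    truth = FlexibilityModel(
        [FlexTerm("stretch_manz", (0, 6), d_eq, k_true_ev * EV_TO_HARTREE, exponent=C6F6_CF_GAMMA0)]
    )
    geoms = [
        _displace_bond(sysb.ref_coords, 0, 6, delta * ANGSTROM_TO_BOHR, 6)
        for delta in (-0.14, -0.07, 0.07, 0.14)
    ]

    def nb(q: float, lj: bool, scheme: str) -> NonbondedModel:
        qmap = {"C": q, "F": -q}
        if lj:
            return NonbondedModel.from_element_table(
                sysb.elements, qmap, UFF_LJ["eps_kcal"], UFF_LJ["dlj_angstrom"], scheme=scheme
            )
        return NonbondedModel.from_element_table(sysb.elements, qmap, scheme=scheme)

    ts, _ = generate_synthetic_surface(
        FixtureSpec("triatomic_surface", noise_sigma=noise_sigma, seed=seed),
        sysb,
        geoms,
        truth,
        nb(generator_charge, generator_lj, "old"),
        topo,
    )
    template = truth.with_force_constants([0.0])
    out = {
        "labels": [],
        "k_new_ev": [],
        "k_old_ev": [],
        "d_resting_angstrom": [],
        "k_true_ev": k_true_ev,
        "d_eq_angstrom": d_eq * BOHR_TO_ANGSTROM,
    }
    for q in charges:
        for lj in lj_options:
            rn = ForceConstantModel(template, ts, scheme="new", nonbonded=nb(q, lj, "new"), topology=topo).fit()
            ro = ForceConstantModel(template, ts, scheme="old", nonbonded=nb(q, lj, "old"), topology=topo).fit()
            out["labels"].append(f"q={q:.2f},lj={'UFF' if lj else 'none'}")
            out["k_new_ev"].append(float(rn.params[0]) * HARTREE_TO_EV)
            out["k_old_ev"].append(float(ro.params[0]) * HARTREE_TO_EV)
            out["d_resting_angstrom"].append(float(ro.resting_values[0]) * BOHR_TO_ANGSTROM)
    return out


def c6f6_system() -> MolecularSystem:
    """Planar hexafluorobenzene: C ring bond 1.389 angstrom, C-F bond
    1.332 angstrom, all angles 120 degrees.  Atoms 0-5 are carbons, 6-11
    the fluorine bonded to the same-index carbon."""
    r_cc = 1.389  # hexagon side == circumradius
    r_cf = r_cc + 1.332
    coords = []
    for i in range(6):
        a = math.pi / 3.0 * i
        coords.append([r_cc * math.cos(a), r_cc * math.sin(a), 0.0])
    for i in range(6):
        a = math.pi / 3.0 * i
        coords.append([r_cf * math.cos(a), r_cf * math.sin(a), 0.0])
    coords = np.array(coords)
    return MolecularSystem(("C",) * 6 + ("F",) * 6, coords, "angstrom", ref_coords=coords.copy())
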