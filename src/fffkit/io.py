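"""File formats: XYZ geometries, flexibility-model text, nonbonded parameter
tables, radial-density profiles and training sets.

All files use 1-based atom indices, angstrom lengths, degrees for angles and
eV for energies/force constants unless a column says otherwise; the readers
convert to the internal atomic units.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .chemsys import MolecularSystem
from .exponents import RadialDensityProfile
from .paramfit import TrainingSet
from .potentials import BEND_KINDS, FlexTerm, FlexibilityModel
from .units import (
    ANGSTROM_TO_BOHR,
    BOHR_TO_ANGSTROM,
    DEG_TO_RAD,
    EV_TO_HARTREE,
    HARTREE_TO_EV,
    KCALMOL_TO_HARTREE,
    RAD_TO_DEG,
)

__all__ = [
    "read_xyz",
    "write_xyz",
    "save_flexibility_model",
    "load_flexibility_model",
    "read_radial_profiles",
    "write_radial_profiles",
    "save_training_set",
    "load_training_set",
    "load_nonbonded_parameters",
    "RunConfig",
    "load_run_config",
]


class ParseError(ValueError):
    pass


def _parse_xyz_block(lines: list[str], start: int):
    try:
        n = int(lines[start].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"line {start + 1}: expected an atom count") from None
    if len(lines) < start + 2 + n:
        raise ParseError(f"line {start + 1}: atom count {n} exceeds remaining lines")
    comment = lines[start + 1].rstrip("\n")
    elements, coords = [], []
    for i in range(n):
        ln = start + 2 + i
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ParseError(f"line {ln + 1}: expected 'element x y z'")
        elements.append(parts[0])
        try:
            coords.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise ParseError(f"line {ln + 1}: non-numeric coordinate") from None
    return elements, np.array(coords), comment, start + 2 + n


def read_xyz(path) -> MolecularSystem:
    """Read a standard XYZ file (angstrom); the geometry doubles as its own
    reference geometry."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    elements, coords, _comment, _ = _parse_xyz_block(lines, 0)
    return MolecularSystem(tuple(elements), coords, "angstrom", ref_coords=coords.copy())


def write_xyz(system: MolecularSystem, path, comment: str = "") -> None:
    s = system.to_angstrom()
    with open(path, "w") as fh:
        fh.write(f"{s.n_atoms}\n{comment}\n")
        for el, (x, y, z) in zip(s.elements, s.coords):
            fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")


# ---------------------------------------------------------------------------
# flexibility model text format
# ---------------------------------------------------------------------------
# one term per line:
#   kind  atoms(1-based, comma)  eq=<value>  [eq2=<value>] [gamma=<bohr^-1>]
#   [nu=<x>] [m=<int>] k=<eV or eV/bohr^2>
# lengths in angstrom, angles in degrees, k in eV-based units.


def save_flexibility_model(model: FlexibilityModel, path) -> None:
    lines = [f"# flexibility model, subdomain {model.subdomain_label}", "# lengths angstrom, angles degrees, k eV-based"]
    for t in model.terms:
        atoms = ",".join(str(a + 1) for a in t.atoms)
        if t.kind in BEND_KINDS:
            eq = f"eq={t.eq_value * RAD_TO_DEG:.6f}"
        else:
            eq = f"eq={t.eq_value * BOHR_TO_ANGSTROM:.8f}"
        parts = [t.kind, atoms, eq]
        if t.eq_value2 is not None:
            parts.append(f"eq2={t.eq_value2 * BOHR_TO_ANGSTROM:.8f}")
        if t.exponent is not None:
            key = "nu" if t.kind == "bend_new" else "gamma"
            parts.append(f"{key}={t.exponent:.6f}")
        if t.basis_index is not None:
            parts.append(f"m={t.basis_index}")
        parts.append(f"k={t.force_constant * HARTREE_TO_EV:.8f}")
        lines.append("  ".join(parts))
    Path(path).write_text("\n".join(lines) + "\n")


def load_flexibility_model(path) -> FlexibilityModel:
    terms = []
    label = "ground"
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("# flexibility model, subdomain"):
            label = line.rsplit(" ", 1)[-1]
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"{path}:{ln}: malformed term line")
        kind = parts[0]
        atoms = tuple(int(a) - 1 for a in parts[1].split(","))
        kv = {}
        for p in parts[2:]:
            key, _, val = p.partition("=")
            kv[key] = float(val)
        if "eq" not in kv or "k" not in kv:
            raise ParseError(f"{path}:{ln}: term needs eq= and k=")
        if kind in BEND_KINDS:
            eq = kv["eq"] * DEG_TO_RAD
        else:
            eq = kv["eq"] * ANGSTROM_TO_BOHR
        terms.append(
            FlexTerm(
                kind=kind,
                atoms=atoms,
                eq_value=eq,
                eq_value2=kv["eq2"] * ANGSTROM_TO_BOHR if "eq2" in kv else None,
                exponent=kv.get("nu", kv.get("gamma")),
                basis_index=int(kv["m"]) if "m" in kv else None,
                force_constant=kv["k"] * EV_TO_HARTREE,
            )
        )
    return FlexibilityModel(terms, label)


# ---------------------------------------------------------------------------
# radial density profiles
# ---------------------------------------------------------------------------
# per-atom blocks: "atom <index>" header then two columns (radius bohr,
# density e/bohr^3); '#' lines ignored.


def read_radial_profiles(path) -> list[RadialDensityProfile]:
    profiles = []
    current: int | None = None
    radii: list[float] = []
    dens: list[float] = []

    def flush():
        if current is not None:
            profiles.append(RadialDensityProfile(current, np.array(radii), np.array(dens)))

    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().startswith("atom"):
            flush()
            current = int(line.split()[1]) - 1
            radii, dens = [], []
            continue
        parts = line.split()
        if len(parts) < 2 or current is None:
            raise ParseError(f"{path}:{ln}: expected 'radius density' inside an atom block")
        radii.append(float(parts[0]))
        dens.append(float(parts[1]))
    flush()
    return profiles


def write_radial_profiles(profiles, path) -> None:
    with open(path, "w") as fh:
        fh.write("# radial density profiles: radius (bohr), density (e/bohr^3)\n")
        for p in profiles:
            fh.write(f"atom {p.atom_index + 1}\n")
            for r, rho in zip(p.radii, p.densities):
                fh.write(f"{r:.6f} {rho:.10e}\n")


# ---------------------------------------------------------------------------
# training sets
# ---------------------------------------------------------------------------
# concatenated records: an XYZ block whose comment line is "dE_eV=<value>".


def save_training_set(ts: TrainingSet, path) -> None:
    ref = ts.reference.to_angstrom()
    with open(path, "w") as fh:
        for coords, e in zip(ts.geometries, ts.energies):
            ang = np.asarray(coords) * BOHR_TO_ANGSTROM
            fh.write(f"{ref.n_atoms}\ndE_eV={e * HARTREE_TO_EV:.10f}\n")
            for el, (x, y, z) in zip(ref.elements, ang):
                fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")


def load_nonbonded_parameters(path, elements) -> "NonbondedModel":
    """Nonbonded parameter table: one line per element (or 1-based atom
    index), columns `key charge eps_kcal dlj_angstrom`; '#' lines ignored.

    Element-keyed rows apply to every matching atom; numeric keys override
    single atoms.  Returns a NonbondedModel (scheme/cutoff set by config).
    """
    from .nonbonded import NonbondedModel

    n = len(elements)
    charges = np.zeros(n)
    eps = np.zeros(n)
    dlj = np.ones(n)
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"{path}:{ln}: expected 'key charge eps_kcal dlj_angstrom'")
        key, q, e, d = parts[0], *(float(p) for p in parts[1:])
        if key.isdigit():
            idx = [int(key) - 1]
            if idx[0] < 0 or idx[0] >= n:
                raise ParseError(f"{path}:{ln}: atom index {key} out of range 1..{n}")
        else:
            idx = [i for i, el in enumerate(elements) if el == key.capitalize()]
            if not idx:
                raise ParseError(f"{path}:{ln}: element {key!r} not present in the system")
        for i in idx:
            charges[i] = q
            eps[i] = e * KCALMOL_TO_HARTREE
            dlj[i] = d * ANGSTROM_TO_BOHR
    return NonbondedModel(charges, eps, dlj)


_RUN_CONFIG_KEYS = {
    "units": str,
    "scheme": str,
    "cutoff_angstrom": float,
    "exclusion_separation": int,
    "lasso_lambda": float,
    "seed": int,
    "hessian_fd_step_bohr": float,
    "output_precision": int,
}


class RunConfig(dict):
    """Validated flat key = value run configuration."""


def load_run_config(path) -> RunConfig:
    """Flat `key = value` configuration; unknown keys are rejected with
    their file location."""
    cfg = RunConfig()
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{ln}: expected 'key = value'")
        key, _, val = (p.strip() for p in line.partition("="))
        if key not in _RUN_CONFIG_KEYS:
            raise ParseError(f"{path}:{ln}: unknown configuration key {key!r}")
        try:
            cfg[key] = _RUN_CONFIG_KEYS[key](val)
        except ValueError:
            raise ParseError(f"{path}:{ln}: invalid value for {key!r}: {val!r}") from None
    if cfg.get("scheme") not in (None, "new", "old"):
        raise ParseError(f"{path}: scheme must be 'new' or 'old'")
    if cfg.get("units") not in (None, "angstrom", "bohr"):
        raise ParseError(f"{path}: units must be 'angstrom' or 'bohr'")
    return cfg


def load_training_set(path, reference: MolecularSystem) -> TrainingSet:
    lines = Path(path).read_text().splitlines()
    pos = 0
    geoms, energies = [], []
    while pos < len(lines) and lines[pos].strip():
        elements, coords, comment, pos = _parse_xyz_block(lines, pos)
        if not comment.startswith("dE_eV="):
            raise ParseError(f"{path}: record comment must be dE_eV=<value>")
        energies.append(float(comment.split("=", 1)[1]) * EV_TO_HARTREE)
        geoms.append(coords * ANGSTROM_TO_BOHR)
    return TrainingSet(reference, geoms, np.array(energies))
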