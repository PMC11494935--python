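"""Synthetic-fixture generators.

These stand in for quantum-chemistry reference data so every fitting and
exponent-extraction path can be exercised end to end: bond-scan /
displacement energy surfaces generated from a known composite model (ground
truth recorded alongside, for parameter-recovery tests) and near-exponential
atomic radial density profiles with optional polynomial contamination.
All randomness is drawn from a seeded generator recorded in the output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .chemsys import BondedTopology, MolecularSystem
from .exponents import RadialDensityProfile
from .nonbonded import NonbondedModel, assemble_nonbonded
from .paramfit import TrainingSet
from .potentials import FlexibilityModel

__all__ = [
    "FixtureSpec",
    "generate_synthetic_surface",
    "generate_synthetic_density_profile",
]


@dataclass(frozen=True)
class FixtureSpec:
    kind: str  # diatomic_surface | triatomic_surface | density_profile
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.kind not in ("diatomic_surface", "triatomic_surface", "density_profile"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def generate_synthetic_surface(
    spec: FixtureSpec,
    system: MolecularSystem,
    geometries: list[np.ndarray],
    truth_model: FlexibilityModel,
    nonbonded: NonbondedModel | None = None,
    topology: BondedTopology | None = None,
) -> tuple[TrainingSet, FlexibilityModel]:
    """Energies of the supplied geometry roster under a known composite
    model (bonded ground truth plus optional raw nonbonded sum), relative to
    the reference geometry, plus Gaussian noise.

    Returns the training set and the ground-truth model so recovery tests
    can compare fitted constants against the planted ones.
    """
    sysb = system.to_bohr()
    ref = sysb.ref_coords if sysb.ref_coords is not None else sysb.coords
    rng = np.random.default_rng(spec.seed)

    def total(coords):
        e = truth_model.energy(coords)
        if nonbonded is not None:
            nb = dataclasses.replace(nonbonded, scheme="old")
            e += assemble_nonbonded(sysb, topology, nb, coords)[0]
        return e

    e_ref = total(ref)
    energies = np.array([total(g) - e_ref for g in geometries])
    if spec.noise_sigma > 0:
        energies = energies + rng.normal(0.0, spec.noise_sigma, size=energies.size)
    return TrainingSet(system, list(geometries), energies), truth_model


def generate_synthetic_density_profile(
    a: float,
    b: float,
    r_max: float = 8.0,
    n_shells: int = 400,
    contamination_degree: int = 0,
    atom_index: int = 0,
) -> RadialDensityProfile:
    """Near-exponential radial profile rho(r) = r^p e^(a - b r) on a uniform
    shell grid (bohr), emulating a spherically averaged atom-in-material
    density; p = 0 is a pure exponential whose decay exponent the exponents
    pipeline recovers exactly."""
    if b <= 0:
        raise ValueError("decay exponent b must be positive")
    r = np.linspace(r_max / n_shells, r_max, n_shells)
    rho = r ** contamination_degree * np.exp(a - b * r)
    return RadialDensityProfile(atom_index, r, rho)
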