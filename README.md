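# fffkit

A toolkit for building nonreactive molecular force fields whose bonded force
constants can be fitted by **linear** regression, together with the model
potentials and vibrational analysis needed to validate them.

## Who this is for

Developers of quantum-mechanically-derived force fields (molecules, MOFs,
molecular crystals) who want to parameterize bond-stretch, angle-bend,
Urey–Bradley and cross terms against QM energies without the local-minimum
headaches of nonlinear fitting, and to check the result against vibrational
spectra.

## The core ideas

**Separation ansatz.** A cluster's intramolecular energy is split into bonded
and nonbonded parts so that the nonbonded part Φ satisfies, at the isolated
cluster's reference geometry ℛ⁰,

    Φ(ℛ⁰) = 0,   ∂Φ/∂R|_{ℛ⁰} = 0,   ∂²Φ/∂R²|_{ℛ⁰} = 0 .

Every "resting value" in the bonded terms then equals its QM equilibrium
value (d_ref = d_eq, θ_ref = θ_eq), the model is linear in the force
constants k_γ,

    U_bonded(ℛ) = Σ_γ k_γ g_γ(ℛ),

and fitting is ordinary (optionally LASSO-penalized, box-constrained) least
squares — convex, deterministic, and almost independent of whatever charges
and Lennard-Jones parameters one later attaches.  The conventional scheme
(raw pairwise nonbonded sums, resting values as free nonlinear parameters)
is implemented alongside for comparison.

**Model potentials.**  The Manz two-exponential stretch

    U(d) = (3k/5γ°²) [1 − (5/2)e^{−γ°Δd} + (3/2)e^{−(5/3)γ°Δd}],  Δd = d − d_eq,

has curvature k at d_eq and a finite dissociation limit 3k/(5γ°²); its
exponent γ° is *derived from the quantum-mechanical electron density*, not
fitted: per-bond decay exponents b_A, b_B of the spherically averaged atomic
densities (Chargemol-style radial profiles) are extracted by a
crossing-point + windowed log-linear fit, combined into γ°, and a Morse
exponent γ_M = γ°·√(5/6) can be predicted from it.  The tanh-regularized
angle bend

    U(θ) = 2k (cos θ − cos θ_eq)² / [ h(θ) (sin²θ + 3 sin²θ_eq) ],
    h(θ) = tanh(ν sin(θ/2)) / tanh(ν sin(θ_eq/2)),   ν = 2,

is infinitely differentiable including at θ = π, has curvature exactly k at
any θ_eq (even linear equilibria), zero force at θ = π, and diverges as
θ → 0 (Pauli repulsion).

**Vibrational validation.**  Harmonic normal modes from the
finite-difference mass-weighted Hessian, and anharmonic diatomic levels from
a 1-D finite-difference Schrödinger solver.

## Worked example

Normal modes of a CO₂ flexibility model (two Manz stretches
k = 30.58 eV bohr⁻², γ° = 1.203 bohr⁻¹; tanh-regularized bend k = 5.17 eV):

```python
from fffkit.examples import triatomic_system, triatomic_flex_model
from fffkit.vibration import masses_for, mass_weighted_hessian, normal_modes

sysb = triatomic_system("CO2").to_bohr()
model = triatomic_flex_model("CO2", include_ub=False)
mwh = mass_weighted_hessian(model.energy, sysb.ref_coords, masses_for(sysb.elements))
res = normal_modes(mwh, linear=True)
print(res.zero_mode_count, [round(w) for w in res.wavenumbers])
```

prints

```
5 [694, 694, 1363, 2609]
```

— five rigid-body modes (linear molecule), the doubly degenerate bend at
694 cm⁻¹, the symmetric stretch at 1363 cm⁻¹ and the asymmetric stretch at
2609 cm⁻¹ (experimentally 667, 1333 and 2349 cm⁻¹; the model carries no
coupling terms).  The same machinery drives the `fff freq` command.

Fitting, on synthetic data, is one Model/Results round trip:

```python
from fffkit.examples import cf_sensitivity_study
out = cf_sensitivity_study()          # hexafluorobenzene C–F bond study
print(out["labels"][2], out["k_new_ev"][2], out["k_old_ev"][2])
```

prints

```
q=0.10,lj=none 12.063540769436726 12.06544891696624
```

and across all six charge/LJ combinations the new-scheme constant spans
<0.01 % while the old-scheme one spans ~4 % — the point of the linear
ansatz.

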