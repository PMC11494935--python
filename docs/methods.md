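# Methods

This note documents the models implemented in fffkit, the numerical choices
behind them, what the synthetic-data generators emulate, and the known
limitations.  Internal units are Hartree atomic units throughout (bohr,
hartree, electron mass); file formats and user-facing APIs use angstrom,
degrees, eV/kcal mol⁻¹, amu and cm⁻¹ with the conversion constants
1 bohr = 0.52917721 Å, 1 hartree = 27.211386 eV = 219474.63 cm⁻¹ (as a
photon wavenumber), 1 amu = 1822.888486 mₑ.

## The separation ansatz

A nonreactive force field writes the potential energy as bonded flexibility
terms plus nonbonded pair terms.  The *scheme* is the rule that splits a
bonded cluster's intramolecular energy between the two.  fffkit implements
two:

* **old** — nonbonded energy is the raw sum of pairwise charge + 12-6
  Lennard-Jones interactions over all non-excluded pairs (exclusions: graph
  distance ≤ 2 or ≤ 3, configurable).  Because these pairs exert forces at
  the reference geometry, every stretch-type term needs a fitted *resting
  value* different from the equilibrium value, and the fit is nonlinear.
* **new** — every intracluster pair potential is *wrapped* so that its
  value, first derivative and second derivative vanish at the pair's
  equilibrium separation in the isolated cluster's reference geometry, and
  (with a finite cutoff) so the wrapped potential reaches zero with two
  continuous derivatives at the cutoff.  The intracluster nonbonded part
  then contributes nothing to the energy, forces or Hessian at the reference
  geometry; the bonded resting values equal their quantum-mechanical
  equilibrium values, and force constants are obtained by linear regression.

### The wrap

The published constraint set fixes the wrap's behavior at the equilibrium
separation and at the cutoff but leaves freedom in between.  fffkit uses a
Taylor-subtraction construction:

    Φ(d) = S(d) · [ U(d) − T₂(d)·w(d) ],

where T₂ is the second-order Taylor polynomial of the pair potential U about
d_eq, w is a smooth window with w(d_eq) = 1, w′(d_eq) = w″(d_eq) = 0 and
w → 0 at infinity, built from the smooth transition function
τ(s,t) = tanh(t/s − ½) as w = 1 − ẑ³ with
ẑ = (τ(d_eq, d) − τ(d_eq, d_eq))/(1 − τ(d_eq, d_eq)), and S is the C²
cutoff switch S(d) = (1 − (d/d_c)⁶)³ for d < d_c, zero beyond.  Each
boundary condition holds exactly by construction: the Taylor subtraction
kills orders 0–2 at d_eq, the cubic power of ẑ keeps the window flat there,
the window's decay restores Φ → 0 at infinity, and S and its first two
derivatives vanish continuously at the cutoff while S → 1 pointwise as
d_c → ∞ (so the finite-cutoff case tends to the infinite-cutoff case).
Intercluster pairs use Φ = S·U, the identity at infinite cutoff.  Only the
constraint set is contractual; any interior shape satisfying it yields the
same leading-order fits, which is what the test suite and the sensitivity
study check.

τ itself is pinned by its printed anchor τ²(s, 2s) = tanh²(3/2) ≈ 0.819,
is unit-free (a function of t/s only) and strictly increasing.

## Model potentials

All potentials are normalized to value 0, slope 0 and curvature exactly k at
their equilibrium internal coordinate, so k values are transferable between
forms and harmonic frequencies never depend on the anharmonicity parameters.

* **Harmonic stretch** ½k(d−d_eq)².
* **Morse** D(1−e^{−γΔd})², D = k/(2γ²).
* **Manz stretch** (3k/5γ°²)[1 − (5/2)e^{−γ°Δd} + (3/2)e^{−(5/3)γ°Δd}].
  The coefficients 5/2, 3/2 are the unique solution of the zero-energy and
  zero-force conditions at d_eq given the 1 : 5/3 exponent ratio; the
  dissociation limit is 3k/(5γ°²).  Equating force constant and dissociation
  energy with the Morse form gives the predicted Morse exponent
  γ_M = γ°√(5/6) (1.207 bohr⁻¹ → 1.102 bohr⁻¹ for the C–F bond example).
* **Urey–Bradley** — a stretch (harmonic or Manz form) between the outer
  atoms of a bonded angle, with its equilibrium distance read from the
  reference geometry.
* **Bond–bond cross** k(d_AB−d_AB^eq)(d_BC−d_BC^eq), sign-unconstrained.
* **Angle bends** — harmonic ½k(θ−θ_eq)², cosine k(1−cos(θ−θ_eq)),
  harmonic-cosine ½k(cosθ−cosθ_eq)² (curvature vanishes when θ_eq = π — the
  deficiency that motivates the new form), an MM3-style sextic polynomial
  behind a coefficient-injection argument, and the **tanh-regularized bend**

      U(θ) = 2k(cosθ−cosθ_eq)² / [h(θ)(sin²θ + 3 sin²θ_eq)],
      h(θ) = tanh(ν sin(θ/2)) / tanh(ν sin(θ_eq/2)).

  Because U is a function of cos θ alone it is smooth and even about θ = π
  (zero force there for any θ_eq); the 1:3 denominator weighting makes the
  curvature at θ_eq equal k for every θ_eq including π; h → 0 as θ → 0
  drives U → ∞, modelling Pauli repulsion.  ν defaults to 2 (energy-curve
  shapes for specific molecules can favour 0.5–5; ν is irrelevant when
  θ_eq = π since it only rescales h).  For θ_eq = π the implementation
  evaluates the algebraically reduced form 2k(1+cosθ)/[h(θ)(1−cosθ)] to
  avoid the 0/0 at θ = π.
* **g_m stretch basis** for series expansions of a bond energy.  Its
  contract: g_m(d_eq) = 0 with zero slope, g_m(∞) = 1, g_m(0) = (−1)^m.
  The closed form shipped here,
  g_m(x) = 1 − e^{−m x²(x−1)²} + (−1)^m[(1−x e^{1−x})e^{−x²}]^m with
  x = d/d_eq, is this package's own contract-complete choice; any basis
  with the same limits serves the same role (redundant-basis LASSO
  demonstrations).

Analytic derivatives are provided to order 2 in the internal coordinate;
Cartesian gradients use the standard chain rule (bend gradients are set to
zero at exactly linear triads, where the force vanishes by symmetry);
Cartesian per-term Hessian blocks use central differences of the analytic
gradients and are symmetrized.

Angles are computed as arccos of a cosine clamped to [−1, 1], so roundoff
near collinear triads can never produce NaN.  Reference angles collinear to
within 10⁻⁸ rad are stored as exactly π; genuinely bent near-linear
reference angles are never rounded.

## Density-decay exponents (γ°)

Inputs are per-atom spherically averaged radial density profiles (two-column
text, bohr vs e bohr⁻³), as printed by atoms-in-materials partitioning
codes.  Pipeline per bond A–B: (1) condition each profile to be monotone
non-increasing by an outermost-inward running maximum (idempotent, never
lowers a shell); (2) find the crossing radius D_A where B's conditioned
density, log-linearly interpolated at d_AB − r_A, overtakes A's on A's shell
grid — D_A is the average of the first shell where ρ̆_B > ρ̆_A and the last
where ρ̆_B < ρ̆_A; (3) fit ln ρ̆ = a − b·r by unweighted least squares over
the asymmetric window [D_A − 0.5, D_A + 2.5] bohr (emphasizing the outer
valence region; clipped at the grid edge with a warning when ≥ 4 shells
remain, an error otherwise; zero-density shells skipped with a warning);
(4) combine the two per-bond exponents into γ°.  The combination rule is a
configurable slot constrained by the requirement that the short-range
repulsion exponent (5/3)γ° equal 5/6 of a weighted average of b_A and b_B;
the default weighted average, b_A b_B (b_A+b_B)/(b_A²+b_B²), is symmetric,
homogeneous of degree one, equals b for equal exponents, and tends to the
smaller exponent when the two differ greatly (the slowly decaying density
dominates the overlap).  Because the crossing radius is bond-specific, one
atom legitimately carries different b values for different bonds
(e.g. covalent vs hydrogen-bond-like contacts).

## Fitting

The design matrix holds unit-force-constant term energies (rows =
geometries; optional force rows = negative per-term Cartesian gradients
against reference forces, weighted W_F; default W_E = 1, W_F = 0).  The
objective is ½Σw r² + λΣ|k| with **no intercept and no standardization**,
box constraints defaulting to k ≥ 0 for stretch/bend/Urey–Bradley and
unbounded cross terms.  λ = 0 uses a bounded least-squares solve (scipy's
trust-region `lsq_linear`); λ > 0 uses cyclic coordinate descent on the Gram
form with soft-thresholding projected onto the box, stopping when the
objective decrease falls below a relative tolerance (default 10⁻¹⁰), with an
optional warm start for regularization paths (tiny-λ fits on strongly
collinear designs converge orders of magnitude faster along a warm-started
path).  λ values are comparable to other conventions only qualitatively:
multiplying the loss by 1/n or using RMSE rescales λ.  All-zero design
columns (terms the training geometries never displace) are reported as
unidentifiable, never silently dropped.  Unregularized fits report standard
errors from σ²(XᵀWX)⁻¹ when the system is overdetermined.

The old-scheme fit optimizes force constants and stretch resting values
jointly by bounded trust-region nonlinear least squares, from five
deterministic multi-starts (resting values at d_eq, ±1 %, ±2 %) to guard
against local minima; equilibrium angles stay fixed.  When a molecule is
small enough that every pair is excluded (di-/triatomics at exclusion
separation 2), the old scheme provably reduces to the new one
(d_resting = d_eq), which the tests confirm.

Training rosters follow the displacement protocol: each bond displaced over
{−0.14, −0.07, 0, +0.07, +0.14} Å at fixed equilibrium angle, full Cartesian
product, equilibrium point excluded, de-duplicated under permutational
symmetry via an internal-coordinate multiset signature (element-labelled
bond lengths and angles rounded to 10⁻⁹) — 14 distinct geometries for a
symmetric triatomic, 24 for an asymmetric one; angle-scan points are
filtered to θ_eq ± 30°.  Validation rosters draw independent uniform bond
(±0.07 Å) and angle (±30°) displacements from a seeded generator; the seed
is recorded.

## Vibrational analysis

The mass-weighted Hessian is built by central finite differences of the
total potential with step 2×10⁻³ bohr (chosen so the O(h²) truncation
residual in the rigid-body eigenvalues stays ≈ 1 cm⁻¹ while roundoff remains
negligible) and symmetrized; a stationary-point check uses a finer 2×10⁻⁴
bohr gradient step so anharmonic truncation error is not mistaken for
residual force.  Eigenvalues below max(10⁻⁸·|λ|_max, λ(10 cm⁻¹)) are
classified rigid-body — the absolute 10 cm⁻¹ floor absorbs the
finite-difference residual; 5 such modes are expected for linear molecules,
6 otherwise, and mismatches warn rather than fail.  Negative eigenvalues
beyond the threshold are reported as imaginary modes.  Wavenumbers are
√λ·(219474.63 cm⁻¹ per hartree), ascending; eigenvector signs are fixed by
making the largest-magnitude component positive.

The 1-D diatomic solver discretizes −(1/2μ)φ″ + U(d)φ = εφ with central
differences and Dirichlet boundaries on the grid d_eq − 1.5 … d_eq + 5.0
bohr, spacing 0.001 bohr (clipped to d > 0 for short bonds, where the
potential wall makes the boundary irrelevant), solved as a symmetric
tridiagonal eigenproblem (LAPACK).  An optional self-check halves the
spacing and warns if any requested level shifts by more than 0.1 cm⁻¹.
Bundled default masses are most-abundant-isotope values (¹H 1.007825, ¹²C
12.0, ¹⁴N 14.003074, ¹⁶O 15.994915, ³²S 31.972071 amu, …), overridable
per run.

## Synthetic data: what it does and does not show

The generators replace quantum-chemistry reference data with energies
computed from a *known* composite model (planted bonded terms plus an
optional raw nonbonded sum) plus optional Gaussian noise, and radial density
profiles of the form r^p e^{a−br}.  They reproduce the *structure* of the
real problem — multicollinearity, the old/new-scheme asymmetry, the
nonbonded sensitivity pattern, exponent extraction — so passing tests show
the machinery is correct and well-conditioned.  They do not show that the
model potentials fit real Born–Oppenheimer surfaces (no electronic
anharmonicity beyond the planted forms, no hybridization shoulders, no
multi-state crossovers) nor that fitted constants match published
per-molecule values, which were derived from coupled-cluster data not
shipped here.  The bundled triatomic force constants and γ° values in
`fffkit.examples` are treated as *inputs*; the package's computed outputs
from them (normal-mode frequencies, the H₂ fundamental) are what the
acceptance script verifies.

## Scope and limitations

Dihedral/out-of-plane terms, periodic boundary conditions and Ewald
electrostatics, polarizable/multipole electrostatics, n ≥ 3-body nonbonded
terms (the pair-wrap API carries an `x` slot for multibody assignment but
only 2-body models are computed), and multi-subdomain (excited-state)
fitting are out of scope.  Bond detection uses element atom-typing radii
only (d ≤ R_A + R_B, inclusive); bond-order thresholds are an extension
point.  The data model carries one electronic ground-state subdomain per
flexibility model.
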