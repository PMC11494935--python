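import math

import numpy as np
import pytest

from fffkit.chemsys import build_topology
from fffkit.examples import cf_sensitivity_study, triatomic_flex_model, triatomic_system
from fffkit.fixtures import FixtureSpec, generate_synthetic_surface
from fffkit.nonbonded import NonbondedModel
from fffkit.paramfit import (
    FitConfig,
    ForceConstantModel,
    TrainingSet,
    build_displacement_training_set,
    design_matrix,
    fit_linear,
    generate_validation_geometries,
    r_squared,
)
from fffkit.potentials import FlexTerm, FlexibilityModel, gm_basis_energy
from fffkit.units import ANGSTROM_TO_BOHR, DEG_TO_RAD


def training_geometries(name, n=30, seed=7, angle_range=30.0):
    system = triatomic_system(name)
    return system, generate_validation_geometries(
        system, n, bond_range_angstrom=0.07, angle_range_deg=angle_range, seed=seed
    )


def exact_training_set(system, geometries, truth):
    sysb = system.to_bohr()
    e_ref = truth.energy(sysb.ref_coords)
    energies = np.array([truth.energy(g) - e_ref for g in geometries])
    return TrainingSet(system, list(geometries), energies)


class TestDisplacementRoster:
    def test_symmetric_triatomic_gives_14(self, water):
        geoms, _ = build_displacement_training_set(water, [(0, 1), (1, 2)])
        assert len(geoms) == 14

    def test_asymmetric_triatomic_gives_24(self):
        hno = triatomic_system("HNO")
        geoms, _ = build_displacement_training_set(hno, [(0, 1), (1, 2)])
        assert len(geoms) == 24

    def test_single_bond_four_point_protocol(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.332, 0.0, 0.0]])
        from fffkit.chemsys import MolecularSystem

        s = MolecularSystem(("C", "F"), coords, "angstrom", ref_coords=coords.copy())
        geoms, _ = build_displacement_training_set(
            s, [(0, 1)], bond_displacements_angstrom=(-0.14, -0.07, 0.07, 0.14)
        )
        assert len(geoms) == 4

    def test_angles_held_at_equilibrium(self, water):
        from fffkit.chemsys import bond_angle

        geoms, _ = build_displacement_training_set(water, [(0, 1), (1, 2)])
        wb = water.to_bohr()
        for g in geoms:
            assert bond_angle(wb.with_coords(g), 0, 1, 2) == pytest.approx(
                104.7 * DEG_TO_RAD, abs=1e-9
            )

    def test_non_positive_bond_rejected(self, water):
        with pytest.raises(ValueError):
            build_displacement_training_set(water, [(0, 1), (1, 2)], (-1.0,))


class TestValidationGeometries:
    def test_count_and_reproducibility(self, water):
        a = generate_validation_geometries(water, 9, seed=3)
        b = generate_validation_geometries(water, 9, seed=3)
        assert len(a) == 9
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        c = generate_validation_geometries(water, 9, seed=4)
        assert not np.array_equal(a[0], c[0])

    def test_draws_within_stated_intervals(self, water):
        from fffkit.chemsys import bond_angle

        wb = water.to_bohr()
        d_eq = wb.distance(0, 1, use_ref=True)
        theta_eq = 104.7 * DEG_TO_RAD
        geoms = generate_validation_geometries(water, 1000, 0.07, 30.0, seed=11)
        for g in geoms[:: 37]:
            s = wb.with_coords(g)
            for pair in ((0, 1), (1, 2)):
                assert abs(s.distance(*pair) - d_eq) <= 0.07 * ANGSTROM_TO_BOHR + 1e-12
            assert abs(bond_angle(s, 0, 1, 2) - theta_eq) <= 30.0 * DEG_TO_RAD + 1e-12


class TestDesignMatrix:
    def test_single_stretch_feature_value(self, water):
        wb = water.to_bohr()
        d_eq = wb.distance(0, 1, use_ref=True)
        term = FlexTerm("stretch_harmonic", (0, 1), d_eq, 0.0)
        g = wb.ref_coords.copy()
        g[0] = g[1] + (g[0] - g[1]) * (d_eq + 0.1) / d_eq
        ts = TrainingSet(water, [g], np.array([0.0]))
        X, y, w = design_matrix(FlexibilityModel([term]), ts)
        assert X[0, 0] == pytest.approx(0.5 * 0.1**2, rel=1e-9)

    def test_reference_geometry_row_is_zero(self, water):
        wb = water.to_bohr()
        model = triatomic_flex_model("H2O", include_ub=True)
        ts = TrainingSet(water, [wb.ref_coords.copy() + 0.0], np.array([0.0]))
        X, _, _ = design_matrix(model, ts)
        assert np.allclose(X, 0.0, atol=1e-14)

    def test_force_rows_are_negative_gradients_of_energy_features(self, water):
        wb = water.to_bohr()
        model = triatomic_flex_model("H2O", include_ub=False)
        g = generate_validation_geometries(water, 1, seed=5)[0]
        ts = TrainingSet(
            water, [g], np.array([0.0]), forces=[np.zeros((3, 3))], w_force=1.0
        )
        X, _, _ = design_matrix(model, ts, include_forces=True)
        h = 1e-6
        # FD of the energy feature wrt the first H x-coordinate vs force row
        unit = model.with_force_constants([1.0] * len(model.terms))
        for col, term in enumerate(unit.terms):
            gp, gm = g.copy(), g.copy()
            gp[0, 0] += h
            gm[0, 0] -= h
            from fffkit.potentials import term_energy

            fd = -(term_energy(term, gp) - term_energy(term, gm)) / (2 * h)
            assert X[1, col] == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestLinearFit:
    def test_exact_recovery_of_planted_constants(self, water):
        truth = triatomic_flex_model("H2O", include_ub=True)
        system, geoms = training_geometries("H2O")
        ts = exact_training_set(system, geoms, truth)
        template = truth.with_force_constants([0.0] * len(truth.terms))
        res = ForceConstantModel(template, ts).fit()
        expect = [t.force_constant for t in truth.terms]
        assert res.params == pytest.approx(expect, rel=1e-8)
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_large_lambda_shrinks_everything_to_zero(self):
        X = np.array([[1.0, 0.5], [0.3, 2.0], [0.7, 0.9]])
        y = np.array([1.0, 2.0, 1.5])
        res = fit_linear(X, y, FitConfig(lasso_lambda=1e6))
        assert np.allclose(res.force_constants, 0.0)

    def test_lasso_path_monotone_on_multicollinear_design(self):
        # redundant g_m basis columns on one bond scan, the embedded feature
        # selection setting
        d_eq = 1.4
        ds = np.linspace(0.9, 4.0, 25)
        ms = range(1, 9)
        X = np.array([[gm_basis_energy(d, d_eq, m) for m in ms] for d in ds])
        rng = np.random.default_rng(0)
        k_true = np.abs(rng.normal(0.1, 0.05, len(list(ms))))
        y = X @ k_true
        lams = [1e-1, 1e-2, 1e-3, 1e-4, 1e-6]
        rmse, l1, nnz = [], [], []
        k_prev = None
        for lam in lams:
            res = fit_linear(X, y, FitConfig(lasso_lambda=lam, max_iter=50_000), k0=k_prev)
            k_prev = res.force_constants
            resid = y - X @ res.force_constants
            rmse.append(float(np.sqrt(np.mean(resid**2))))
            l1.append(float(np.abs(res.force_constants).sum()))
            nnz.append(res.n_nonzero)
        assert all(b <= a + 1e-12 for a, b in zip(rmse, rmse[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(l1, l1[1:]))
        assert nnz[-1] >= nnz[0]

    def test_all_zero_column_reported_unidentifiable(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0]])
        y = np.array([1.0, 2.0])
        res = fit_linear(X, y)
        assert res.unidentifiable == [1]
        assert res.force_constants[1] == 0.0

    def test_noise_recovery_bias_small_and_rmse_scales(self, water):
        truth = triatomic_flex_model("H2O", include_ub=False)
        system, geoms = training_geometries("H2O", n=60)
        template = truth.with_force_constants([0.0] * len(truth.terms))
        errs = {}
        for sigma in (0.0, 1e-4):
            fits = []
            for seed in range(6):
                ts, _ = generate_synthetic_surface(
                    FixtureSpec("triatomic_surface", noise_sigma=sigma, seed=seed),
                    system,
                    geoms,
                    truth,
                )
                res = ForceConstantModel(template, ts).fit()
                fits.append(res.params)
            fits = np.array(fits)
            expect = np.array([t.force_constant for t in truth.terms])
            errs[sigma] = np.abs(fits - expect)
        assert errs[0.0].max() < 1e-9
        assert errs[1e-4].max() < 0.05 * max(t.force_constant for t in truth.terms)

    def test_new_scheme_leading_order_independent_of_nonbonded_model(self, water, radii_bohr):
        # attaching a nonbonded model is unnecessary for the leading-order
        # fit: with no retained intracluster pairs the results are identical
        truth = triatomic_flex_model("H2O", include_ub=False)
        system, geoms = training_geometries("H2O")
        ts = exact_training_set(system, geoms, truth)
        template = truth.with_force_constants([0.0] * len(truth.terms))
        topo = build_topology(system.to_bohr(), radii_bohr, max_separation=2)
        nb = NonbondedModel.from_element_table(system.elements, {"H": 0.4, "O": -0.8})
        bare = ForceConstantModel(template, ts).fit()
        attached = ForceConstantModel(template, ts, nonbonded=nb, topology=topo).fit()
        assert np.array_equal(bare.params, attached.params)


class TestOldScheme:
    def test_all_excluded_recovers_equilibrium_resting_values(self, water, radii_bohr):
        # triatomic: every pair is a 1-2 or 1-3 neighbor, so no intracluster
        # nonbonded interactions survive and d_resting = d_eq, k = new-scheme k
        truth = triatomic_flex_model("H2O", include_ub=False)
        system, geoms = training_geometries("H2O")
        ts = exact_training_set(system, geoms, truth)
        template = truth.with_force_constants([0.0] * len(truth.terms))
        topo = build_topology(system.to_bohr(), radii_bohr, max_separation=2)
        nb = NonbondedModel.from_element_table(system.elements, {"H": 0.4, "O": -0.8}, scheme="old")
        res_old = ForceConstantModel(template, ts, scheme="old", nonbonded=nb, topology=topo).fit()
        res_new = ForceConstantModel(template, ts).fit()
        wb = system.to_bohr()
        d_eq = wb.distance(0, 1, use_ref=True)
        assert res_old.resting_values[:2] == pytest.approx([d_eq, d_eq], rel=1e-6)
        assert res_old.params == pytest.approx(res_new.params, rel=1e-4)

    def test_sensitivity_study_new_stable_old_drifts(self):
        out = cf_sensitivity_study()
        k_new = np.array(out["k_new_ev"])
        k_old = np.array(out["k_old_ev"])
        spread_new = np.ptp(k_new) / k_new.mean()
        spread_old = np.ptp(k_old) / k_old.mean()
        assert spread_new < 0.005
        assert spread_old > spread_new
        # with strong charges the fitted resting value moves off equilibrium
        i62 = out["labels"].index("q=0.62,lj=none")
        assert abs(out["d_resting_angstrom"][i62] - out["d_eq_angstrom"]) > 1e-3


class TestRSquared:
    def test_perfect_mean_and_worse_than_mean(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(np.full(3, y.mean()), y) == 0.0
        assert r_squared(np.array([3.0, 1.0, -2.0]), y) < 0.0

    def test_zero_variance_reference_undefined(self):
        assert math.isnan(r_squared(np.array([1.0, 1.1]), np.array([2.0, 2.0])))


def test_summary_reports_fit(water):
    truth = triatomic_flex_model("H2O", include_ub=False)
    system, geoms = training_geometries("H2O", n=20)
    ts = exact_training_set(system, geoms, truth)
    template = truth.with_force_constants([0.0] * len(truth.terms))
    res = ForceConstantModel(template, ts).fit()
    text = res.summary()
    assert "R-squared" in text and "stretch_manz" in text
    val = generate_validation_geometries(system, 9, seed=1)
    e_val = np.array([truth.energy(g) - truth.energy(system.to_bohr().ref_coords) for g in val])
    assert res.rsquared_validation(val, e_val) == pytest.approx(1.0, abs=1e-8)
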