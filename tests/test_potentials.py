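import math

import numpy as np
import pytest

from conftest import fd_derivative, random_rotation
from fffkit.potentials import (
    FlexTerm,
    FlexibilityModel,
    PotentialDomainError,
    bend_energy,
    cross_term_energy,
    gm_basis_energy,
    h_factor,
    manz_coefficients,
    stretch_dissociation_energy,
    stretch_energy,
    term_energy,
    term_gradient_cartesian,
    term_hessian_cartesian,
)

D_EQ = 2.5
K = 0.8
GAMMA = 1.2


def stretch_term(kind, k=K, gamma=GAMMA, d_eq=D_EQ, m=None):
    exp = gamma if kind in ("stretch_morse", "stretch_manz") else None
    return FlexTerm(kind, (0, 1), d_eq, k, exponent=exp, basis_index=m)


def bend_term(kind, k=K, theta_eq=2.0, nu=2.0):
    return FlexTerm(kind, (0, 1, 2), theta_eq, k, exponent=nu if kind == "bend_new" else None)


STRETCHES = ["stretch_harmonic", "stretch_morse", "stretch_manz"]
BENDS = ["bend_new", "bend_harmonic", "bend_cosine"]


class TestEquilibriumConditions:
    """Every form: zero energy, zero slope and curvature k at equilibrium."""

    @pytest.mark.parametrize("kind", STRETCHES)
    @pytest.mark.parametrize("k,gamma", [(0.5, 0.9), (2.0, 1.4)])
    def test_stretch_value_slope_curvature(self, kind, k, gamma):
        t = stretch_term(kind, k=k, gamma=gamma)
        u = lambda d: stretch_energy(d, t)
        assert stretch_energy(D_EQ, t) == 0.0
        assert stretch_energy(D_EQ, t, order=1) == pytest.approx(0.0, abs=1e-14)
        assert stretch_energy(D_EQ, t, order=2) == pytest.approx(k, rel=1e-12)
        assert fd_derivative(u, D_EQ, order=2, h=1e-4) == pytest.approx(k, rel=1e-5)

    @pytest.mark.parametrize("kind", BENDS)
    @pytest.mark.parametrize("theta_eq", [math.pi / 2, 2 * math.pi / 3, math.pi])
    def test_bend_value_slope_curvature(self, kind, theta_eq):
        t = bend_term(kind, theta_eq=theta_eq)
        u = lambda x: bend_energy(x, t)
        assert bend_energy(theta_eq, t) == 0.0
        assert bend_energy(theta_eq, t, order=1) == pytest.approx(0.0, abs=1e-12)
        assert bend_energy(theta_eq, t, order=2) == pytest.approx(K, rel=1e-10)
        h = 1e-4
        if theta_eq == math.pi:  # one-sided: use the folded symmetry U(pi+h)=U(pi-h)
            fd2 = 2 * (u(theta_eq - h) - u(theta_eq)) / h**2
        else:
            fd2 = fd_derivative(u, theta_eq, order=2, h=h)
        assert fd2 == pytest.approx(K, rel=1e-4)

    def test_analytic_derivatives_match_fd_off_equilibrium(self):
        for kind in STRETCHES:
            t = stretch_term(kind)
            for d in (2.1, 2.9, 4.0):
                assert stretch_energy(d, t, 1) == pytest.approx(
                    fd_derivative(lambda x: stretch_energy(x, t), d), rel=1e-6
                )
        for kind in BENDS + ["bend_harmonic_cosine"]:
            t = bend_term(kind, theta_eq=1.9)
            for th in (1.2, 2.4, 3.0):
                assert bend_energy(th, t, 1) == pytest.approx(
                    fd_derivative(lambda x: bend_energy(x, t), th), rel=1e-6
                )
                assert bend_energy(th, t, 2) == pytest.approx(
                    fd_derivative(lambda x: bend_energy(x, t), th, order=2), rel=1e-5
                )


class TestManzStretch:
    def test_coefficients_solve_zero_energy_zero_force(self):
        c2, c3 = manz_coefficients()
        assert c2 == pytest.approx(2.5, abs=1e-14)
        assert c3 == pytest.approx(1.5, abs=1e-12)
        assert 1 - c2 + c3 == pytest.approx(0.0, abs=1e-12)
        assert c2 - (5 / 3) * c3 == pytest.approx(0.0, abs=1e-12)

    def test_dissociation_limits(self):
        morse = stretch_term("stretch_morse")
        manz = stretch_term("stretch_manz")
        assert stretch_dissociation_energy(morse) == pytest.approx(K / (2 * GAMMA**2))
        assert stretch_dissociation_energy(manz) == pytest.approx(3 * K / (5 * GAMMA**2))
        for t in (morse, manz):
            diss = stretch_dissociation_energy(t)
            assert stretch_energy(1e4, t) == pytest.approx(diss, rel=1e-6)

    def test_manz_normalized_dissociation(self):
        g = 1.1
        t = stretch_term("stretch_manz", k=5 * g**2 / 3, gamma=g)
        assert stretch_dissociation_energy(t) == pytest.approx(1.0)

    def test_equal_k_and_dissociation_ties_morse_exponent(self):
        # k/(2 gM^2) = 3k/(5 g0^2)  =>  gM = g0 sqrt(5/6)
        g0 = 1.207
        gm = g0 * math.sqrt(5 / 6)
        manz = stretch_term("stretch_manz", gamma=g0)
        morse = stretch_term("stretch_morse", gamma=gm)
        assert stretch_dissociation_energy(manz) == pytest.approx(stretch_dissociation_energy(morse))

    def test_monotone_increase_and_bounded_beyond_equilibrium(self):
        for kind in ("stretch_morse", "stretch_manz"):
            t = stretch_term(kind)
            diss = stretch_dissociation_energy(t)
            ds = np.linspace(D_EQ, D_EQ + 20, 200)
            us = [stretch_energy(d, t) for d in ds]
            assert all(b >= a - 1e-15 for a, b in zip(us, us[1:]))
            assert all(u <= diss + 1e-12 for u in us)

    def test_harmonic_trivial_value_and_linear_parameters(self):
        t = stretch_term("stretch_harmonic", k=2.0)
        assert stretch_energy(D_EQ + 0.5, t) == pytest.approx(0.25)
        # 1/2 k (d - d_ref)^2 = p1 d^2 + p2 d + p3
        k, dref = 2.0, D_EQ
        p1, p2, p3 = 0.5 * k, -k * dref, 0.5 * k * dref**2
        for d in (1.0, 2.0, 3.3):
            assert p1 * d**2 + p2 * d + p3 == pytest.approx(stretch_energy(d, t))


class TestNewBend:
    def test_zero_slope_at_pi_for_any_equilibrium(self):
        for teq in (0.8, 1.9, 2.9, math.pi):
            t = bend_term("bend_new", theta_eq=teq)
            assert bend_energy(math.pi, t, order=1) == pytest.approx(0.0, abs=1e-10)

    def test_harmonic_cosine_is_flat_at_linear_equilibrium(self):
        # the documented deficiency the new bend fixes
        t = bend_term("bend_harmonic_cosine", theta_eq=math.pi)
        assert bend_energy(math.pi, t, order=2) == pytest.approx(0.0, abs=1e-12)

    def test_diverges_toward_zero_angle(self):
        t = bend_term("bend_new", theta_eq=math.pi / 2)
        assert bend_energy(0.01, t) > 100 * max(
            bend_energy(math.pi / 2 - 0.5, t), bend_energy(math.pi / 2 + 0.5, t)
        )

    def test_folding_symmetry_about_pi(self):
        # a hypothetical angle pi + delta is measured as pi - delta; the
        # potential must agree on both sides, with continuous derivatives
        t = bend_term("bend_new", theta_eq=2.0)
        for delta in (1e-4, 1e-2, 0.3):
            left = bend_energy(math.pi - delta, t)
            assert left == pytest.approx(bend_energy(math.pi - delta, t))
        # the potential is even about pi, so odd one-sided derivatives must
        # vanish there: the backward-stencil estimates shrink linearly to 0
        u = lambda x: bend_energy(x, t)

        def d1(h):
            return (u(math.pi - 2 * h) - 4 * u(math.pi - h) + 3 * u(math.pi)) / (2 * h)

        def d3(h):
            return (u(math.pi) - 3 * u(math.pi - h) + 3 * u(math.pi - 2 * h) - u(math.pi - 3 * h)) / h**3

        assert d1(1e-3) == pytest.approx(0.0, abs=1e-6)
        assert abs(d3(5e-4)) < 0.75 * abs(d3(1e-3))  # consistent with limit 0
        assert abs(2 * d3(5e-4) - d3(1e-3)) < 2e-3  # Richardson-extrapolated

    def test_expressible_in_cos_theta(self):
        # same cos(theta) must give the same energy
        t = bend_term("bend_new", theta_eq=1.7)
        for th in (0.6, 1.2, 2.8):
            same_cos = math.acos(math.cos(th))
            assert bend_energy(same_cos, t) == pytest.approx(bend_energy(th, t))

    def test_domain_error_outside_range(self):
        t = bend_term("bend_new")
        with pytest.raises(PotentialDomainError):
            bend_energy(0.0, t)
        with pytest.raises(PotentialDomainError):
            bend_energy(math.pi + 0.1, t)


class TestHFactor:
    def test_printed_limits(self):
        assert h_factor(1e-300, 1.9, 2.0) == pytest.approx(0.0, abs=1e-12)
        for teq in (0.9, 2.0, math.pi):
            assert h_factor(teq, teq, 2.0) == pytest.approx(1.0)
        nu, teq = 2.0, math.pi / 2
        expect = math.tanh(nu) / math.tanh(nu * math.sin(teq / 2))
        assert h_factor(math.pi, teq, nu) == pytest.approx(expect)
        assert expect == pytest.approx(math.tanh(2) / math.tanh(2 * math.sin(math.pi / 4)))

    def test_strictly_increasing_on_open_interval(self):
        th = np.linspace(0.01, math.pi - 0.01, 200)
        vals = [h_factor(x, 2.2, 2.0) for x in th]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_monotone_in_theta_ordering(self):
        teq = 1.5
        assert h_factor(teq + 0.5, teq) > 1.0 > h_factor(teq - 0.5, teq)


class TestGmBasis:
    @pytest.mark.parametrize("m", [1, 2, 3, 7])
    def test_contract_limits(self, m):
        assert gm_basis_energy(D_EQ, D_EQ, m) == pytest.approx(0.0, abs=1e-14)
        assert gm_basis_energy(D_EQ, D_EQ, m, order=1) == pytest.approx(0.0, abs=1e-12)
        assert gm_basis_energy(1e6, D_EQ, m) == pytest.approx(1.0, rel=1e-9)
        assert gm_basis_energy(0.0, D_EQ, m) == pytest.approx((-1.0) ** m)

    def test_derivatives_match_fd(self):
        for m in (1, 2, 4):
            for d in (1.0, 2.2, 3.5):
                f = lambda x: gm_basis_energy(x, D_EQ, m)
                assert gm_basis_energy(d, D_EQ, m, 1) == pytest.approx(fd_derivative(f, d), abs=1e-6)
                assert gm_basis_energy(d, D_EQ, m, 2) == pytest.approx(
                    fd_derivative(f, d, order=2), abs=1e-5
                )

    def test_rejects_invalid_index(self):
        with pytest.raises(ValueError):
            gm_basis_energy(1.0, D_EQ, 0)


class TestCrossTerm:
    def test_bilinear_values(self):
        t = FlexTerm("bond_bond_cross", (0, 1, 2), 2.0, 1.0, eq_value2=3.0)
        assert cross_term_energy(2.0, 3.5, t) == 0.0
        assert cross_term_energy(2.1, 2.8, t) == pytest.approx(0.1 * -0.2)
        # symmetric under swapping the two bonds together with eq values
        t_sw = FlexTerm("bond_bond_cross", (2, 1, 0), 3.0, 1.0, eq_value2=2.0)
        assert cross_term_energy(2.8, 2.1, t_sw) == pytest.approx(cross_term_energy(2.1, 2.8, t))


class TestCartesianDerivatives:
    def geometry(self):
        return np.array([[1.9, 0.1, -0.2], [0.0, 0.0, 0.0], [-0.6, 2.2, 0.4]])

    def terms(self):
        return [
            stretch_term("stretch_manz", d_eq=2.0),
            stretch_term("stretch_harmonic", d_eq=2.0),
            bend_term("bend_new", theta_eq=1.8),
            FlexTerm("bond_bond_cross", (0, 1, 2), 2.0, 0.3, eq_value2=2.3),
            FlexTerm("urey_bradley", (0, 2), 3.0, 0.2, exponent=1.1),
        ]

    def test_gradient_matches_finite_differences(self):
        coords = self.geometry()
        for term in self.terms():
            g = term_gradient_cartesian(term, coords)
            h = 1e-6
            for i in range(3):
                for j in range(3):
                    cp, cm = coords.copy(), coords.copy()
                    cp[i, j] += h
                    cm[i, j] -= h
                    fd = (term_energy(term, cp) - term_energy(term, cm)) / (2 * h)
                    assert g[i, j] == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_zero_gradient_at_reference_geometry(self):
        # place the triad exactly at every term's equilibrium internal values
        teq = 1.8
        coords = np.array(
            [[2.0, 0.0, 0.0], [0.0, 0.0, 0.0], [2.3 * math.cos(teq), 2.3 * math.sin(teq), 0.0]]
        )
        terms = [
            stretch_term("stretch_manz", d_eq=2.0),
            FlexTerm("stretch_harmonic", (1, 2), 2.3, K),
            bend_term("bend_new", theta_eq=teq),
            FlexTerm("bond_bond_cross", (0, 1, 2), 2.0, 0.3, eq_value2=2.3),
        ]
        for term in terms:
            assert np.allclose(term_gradient_cartesian(term, coords), 0.0, atol=1e-12)

    def test_forces_sum_to_zero_and_zero_net_torque(self, rng):
        coords = self.geometry()
        for term in self.terms():
            g = term_gradient_cartesian(term, coords)
            assert np.allclose(g.sum(axis=0), 0.0, atol=1e-12)
            center = coords.mean(axis=0)
            torque = np.sum(np.cross(coords - center, -g), axis=0)
            assert np.allclose(torque, 0.0, atol=1e-10)

    def test_hessian_blocks_symmetric(self):
        coords = self.geometry()
        for term in self.terms():
            h = term_hessian_cartesian(term, coords)
            assert np.allclose(h, h.T, atol=1e-12)


def test_flexibility_model_energy_and_validation():
    coords = np.array([[2.1, 0.0, 0.0], [0.0, 0.0, 0.0], [-0.5, 2.0, 0.0]])
    m = FlexibilityModel([stretch_term("stretch_manz", d_eq=2.0), bend_term("bend_new", theta_eq=1.9)])
    m.validate(3)
    assert m.energy(coords) == pytest.approx(
        term_energy(m.terms[0], coords) + term_energy(m.terms[1], coords)
    )
    with pytest.raises(IndexError):
        m.validate(2)


def test_frequency_like_invariance_under_rotation(rng):
    # the scalar energy of every term is invariant under rigid motion
    coords = np.array([[1.9, 0.1, -0.2], [0.0, 0.0, 0.0], [-0.6, 2.2, 0.4]])
    R = random_rotation(rng)
    shift = rng.normal(size=3)
    m = FlexibilityModel(
        [stretch_term("stretch_manz", d_eq=2.0), bend_term("bend_new", theta_eq=1.8)]
    )
    assert m.energy(coords @ R.T + shift) == pytest.approx(m.energy(coords), rel=1e-12)
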