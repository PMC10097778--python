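"""Constitutive model: active factor, invariants, energies, stresses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emimech.materials import (ActiveTransient, MaterialParams,
                               active_deformation, invariants, make_state,
                               strain_energy, stresses)


class TestActiveDeformation:
    def test_identity_at_zero(self):
        assert np.allclose(active_deformation(0.0), np.eye(3))

    def test_closed_form_at_019(self):
        Fa = active_deformation(0.19)
        assert Fa[0, 0] == pytest.approx(0.81)
        assert Fa[1, 1] == pytest.approx(0.81 ** -0.5)
        assert Fa[2, 2] == pytest.approx(0.81 ** -0.5)
        assert np.linalg.det(Fa) == pytest.approx(1.0, abs=1e-14)

    @given(st.floats(min_value=0.0, max_value=0.499))
    @settings(deadline=None, max_examples=50)
    def test_always_volume_preserving(self, gamma):
        assert np.linalg.det(active_deformation(gamma)) == pytest.approx(
            1.0, abs=1e-12)

    def test_singular_activation_rejected(self):
        with pytest.raises(ValueError):
            active_deformation(1.0)
        with pytest.raises(ValueError):
            active_deformation(-0.1)


class TestInvariants:
    def test_reference(self):
        J, I1, I4 = invariants(np.eye(3), active_deformation(0.0))
        assert (J, I1, I4) == pytest.approx((1.0, 3.0, 1.0))

    def test_isochoric_uniaxial(self):
        lam = 1.1
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        J, I1, I4 = invariants(F, active_deformation(0.0))
        assert J == pytest.approx(1.0)
        assert I1 == pytest.approx(lam ** 2 + 2 / lam)
        assert I4 == pytest.approx(lam ** 2)

    def test_pure_activation_shifts_elastic_invariants(self):
        g = 0.1
        J, I1, I4 = invariants(np.eye(3), active_deformation(g))
        assert J == pytest.approx(1.0)
        assert I1 == pytest.approx(0.9 ** -2 + 2 * 0.9)
        assert I4 == pytest.approx(0.9 ** -2)

    def test_inverted_state_rejected(self):
        with pytest.raises(ValueError):
            invariants(-np.eye(3), active_deformation(0.0))


class TestStrainEnergy:
    def test_zero_at_reference(self, table3_params):
        st_ = make_state(np.eye(3))
        assert strain_energy(st_, table3_params, "intracellular") == 0.0
        assert strain_energy(st_, table3_params, "extracellular") == 0.0

    def test_fiber_term_inactive_under_compression(self, table3_params):
        lam = 0.95                      # fiber shortening, I4f < 1
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        st_ = make_state(F)
        assert st_.I4f < 1.0
        with_fiber = strain_energy(st_, table3_params, "intracellular")
        no_fiber = strain_energy(
            st_, MaterialParams(a_i=table3_params.a_i, b_i=table3_params.b_i,
                                a_if=0.0, b_if=1.0, a_e=1.0, b_e=1.0),
            "intracellular")
        assert with_fiber == pytest.approx(no_fiber, rel=1e-14)

    def test_against_independent_arithmetic(self, table3_params):
        # independent evaluation of the exponential energy at I1 = 3.1,
        # I4f = 1.21 with the averaged fitted parameters
        st_ = make_state(np.eye(3))
        st_.I1, st_.I4f = 3.1, 1.21
        got = strain_energy(st_, table3_params, "intracellular")
        p = table3_params
        expected = (p.a_i / (2 * p.b_i) * math.expm1(p.b_i * 0.1)
                    + p.a_if / (2 * p.b_if)
                    * math.expm1(p.b_if * 0.21 ** 2))
        assert got == pytest.approx(expected, rel=1e-12)
        got_e = strain_energy(st_, table3_params, "extracellular")
        assert got_e == pytest.approx(
            p.a_e / (2 * p.b_e) * math.expm1(p.b_e * 0.1), rel=1e-12)

    def test_b_to_zero_limit_is_continuous(self):
        st_ = make_state(np.diag([1.1, 1.1 ** -0.5, 1.1 ** -0.5]))
        tiny = MaterialParams(a_i=2.0, b_i=1e-13, a_if=0.0, b_if=1.0,
                              a_e=2.0, b_e=1e-13)
        lim = 0.5 * 2.0 * (st_.I1 - 3.0)
        assert strain_energy(st_, tiny, "intracellular") == pytest.approx(
            lim, rel=1e-6)
        small = MaterialParams(a_i=2.0, b_i=1e-6, a_if=0.0, b_if=1.0,
                               a_e=2.0, b_e=1e-6)
        assert strain_energy(st_, small, "intracellular") == pytest.approx(
            lim, rel=1e-5)

    def test_nonnegative_on_random_states(self, table3_params):
        rng = np.random.default_rng(7)
        for _ in range(50):
            F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
            if np.linalg.det(F) < 0.3:
                continue
            st_ = make_state(F, gamma=rng.uniform(0, 0.25))
            assert strain_energy(st_, table3_params,
                                 "intracellular") >= -1e-12
            assert strain_energy(st_, table3_params,
                                 "extracellular") >= -1e-12


class TestStresses:
    def test_zero_at_reference(self, table3_params):
        P, sig, E = stresses(make_state(np.eye(3)), table3_params,
                             "intracellular", p=0.0)
        assert np.allclose(P, 0) and np.allclose(sig, 0) and \
            np.allclose(E, 0)

    def test_simple_shear_green_lagrange(self, table3_params):
        k = 0.3
        F = np.eye(3)
        F[0, 1] = k
        _, _, E = stresses(make_state(F), table3_params, "extracellular")
        assert E[0, 1] == pytest.approx(k / 2)
        assert E[1, 1] == pytest.approx(k ** 2 / 2)
        assert E[0, 0] == pytest.approx(0.0, abs=1e-14)

    def test_piola_matches_energy_gradient(self, table3_params):
        """Analytic P vs central FD of psi + p(J-1) on >=100 random states."""

        def psi_star(F, gamma, p, sub):
            s = make_state(F, gamma, p)
            return strain_energy(s, table3_params, sub) \
                + p * (np.linalg.det(F) - 1.0)

        rng = np.random.default_rng(11)
        checked = 0
        h = 1e-6
        while checked < 120:
            F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
            if np.linalg.det(F) < 0.4:
                continue
            gamma = rng.uniform(0, 0.3)
            p = rng.normal()
            sub = "intracellular" if checked % 2 else "extracellular"
            P, sig, _ = stresses(make_state(F, gamma), table3_params, sub, p)
            Pfd = np.empty((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp = F.copy(); Fp[i, j] += h
                    Fm = F.copy(); Fm[i, j] -= h
                    Pfd[i, j] = (psi_star(Fp, gamma, p, sub)
                                 - psi_star(Fm, gamma, p, sub)) / (2 * h)
            scale = max(1.0, np.abs(P).max())
            assert np.abs(P - Pfd).max() / scale < 1e-5
            assert np.abs(sig - sig.T).max() < 1e-9 * max(
                1.0, np.abs(sig).max())
            checked += 1

    def test_inverted_state_rejected(self, table3_params):
        st_ = make_state(np.eye(3))
        st_.J = -1.0
        with pytest.raises(ValueError):
            stresses(st_, table3_params, "intracellular")


class TestActiveTransient:
    def test_parametric_shape(self):
        tr = ActiveTransient()
        assert tr(0.0) == 0.0
        assert tr(138.0) == pytest.approx(0.2)
        assert tr(500.0) == pytest.approx(0.0, abs=1e-12)
        t = np.linspace(0, 500, 201)
        g = tr(t)
        assert np.all((g >= 0) & (g < 1))
        assert g.max() == pytest.approx(0.2, abs=1e-3)   # grid near t_peak

    def test_tabulated_round_trip(self, tmp_path):
        tr = ActiveTransient(gamma_max=0.15, t_peak=100.0, t_end=400.0)
        path = tmp_path / "gamma.csv"
        tr.to_csv(path, n=81)
        back = ActiveTransient.from_csv(path)
        t = np.linspace(0, 400, 57)
        assert np.allclose(back(t), tr(t), atol=2e-3)

    def test_invalid_samples_rejected(self):
        with pytest.raises(ValueError):
            ActiveTransient(samples=np.array([[0.0, 0.2], [10.0, 0.1]]))
        with pytest.raises(ValueError):
            ActiveTransient(samples=np.array([[0.0, 0.0], [10.0, 1.2]]))
        with pytest.raises(ValueError):
            ActiveTransient(gamma_max=1.5)
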