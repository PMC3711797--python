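"""Unit and property tests of the ODE right-hand side and its Jacobian."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ifnosc import (KnockoutSpec, ParameterSet, StateVector, apply_knockout,
                    hill_activation, jacobian, phosphorylation_flux, rhs)
from ifnosc.errors import (InvalidParameterError, InvalidStateError,
                           UsageError)
from conftest import random_states


class TestHillActivation:
    @pytest.mark.parametrize("k,h", [(100.0, 1), (4680.0, 4), (1.0, 3)])
    def test_half_maximal_at_threshold(self, k, h):
        assert hill_activation(k, k, h) == pytest.approx(0.5)

    def test_anchor_values(self):
        assert hill_activation(0.0, 100.0, 3) == 0.0
        assert hill_activation(200.0, 100.0, 1) == pytest.approx(2.0 / 3.0)

    @given(ratio=st.floats(0.0, 1e2), k=st.floats(1e-3, 1e6),
           h=st.integers(1, 6))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_and_monotone(self, ratio, k, h):
        x = ratio * k
        v = hill_activation(x, k, h)
        assert 0.0 <= v < 1.0
        assert hill_activation(x * 1.5 + k / 10.0, k, h) > v

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            hill_activation(1.0, 0.0, 2)
        with pytest.raises(InvalidParameterError):
            hill_activation(1.0, 10.0, 0)


class TestPhosphorylationFlux:
    def test_zero_substrate_or_receptor(self, p):
        assert phosphorylation_flux(0.0, 1000.0, 5.0, p) == 0.0
        assert phosphorylation_flux(1e5, 0.0, 5.0, p) == 0.0

    def test_hand_evaluation_at_reference_state(self, p):
        # direct arithmetic with the published constants:
        # b_ph*S*(A/k_A) / (1 + A/k_A + (R/k_I)^q)
        a_over_k = 1e5 / 4680.0
        expected = 1.3e3 * 1000.0 * a_over_k / (1.0 + a_over_k + (1.0 / 82680.0) ** 4)
        assert phosphorylation_flux(1e5, 1000.0, 1.0, p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.3e6 * (21.368 / 22.368), rel=1e-3)

    def test_socs1_knockout_removes_R_dependence(self, p, rng):
        _, ko = apply_knockout(p, "socs1")
        for _ in range(20):
            A, S, R = rng.uniform(0, 1e5, 3)
            assert (phosphorylation_flux(A, S, R, p, ko)
                    == phosphorylation_flux(A, S, 0.0, p, ko))

    def test_monotone_in_each_argument(self, p, rng):
        # non-increasing in the inhibitor R, non-decreasing in S and A
        for _ in range(50):
            A, S, R = rng.uniform(0, 2e5, 3)
            f0 = phosphorylation_flux(A, S, R, p)
            assert phosphorylation_flux(A, S, R * 2 + 1, p) <= f0
            assert phosphorylation_flux(A, S * 2 + 1, R, p) >= f0
            assert phosphorylation_flux(A * 2 + 1, S, R, p) >= f0

    def test_negative_input_rejected(self, p):
        with pytest.raises(InvalidStateError):
            phosphorylation_flux(-1.0, 10.0, 0.0, p)


class TestRhs:
    def test_absorbing_origin(self):
        p = ParameterSet(b_S=0.0, B_STAT=0.0)
        dy = rhs(0.0, np.zeros(9), p)
        assert np.all(dy == 0.0)

    def test_receptor_decay_component_at_reference_state(self, p, y0):
        dy = rhs(0.0, y0.to_array(), p)
        assert dy[0] == pytest.approx(-0.0229 * 1000.0)

    def test_stat1_mass_bookkeeping_identity(self, p, rng):
        # dA + dApc + dApn = b_A*a - lam_STAT*(A+Apc+Apn): the
        # phosphorylation, import/export and dephosphorylation fluxes all
        # cancel in the total-protein balance.
        for y in random_states(rng, 100):
            dy = rhs(0.0, y, p)
            lhs = dy[1] + dy[2] + dy[3]
            expect = p.b_A * y[8] - p.lam_STAT * (y[1] + y[2] + y[3])
            assert lhs == pytest.approx(expect, rel=1e-12, abs=1e-9)

    def test_irf1_knockout_makes_stat1_transcription_constitutive(self, p, rng):
        _, ko = apply_knockout(p, "irf1")
        for y in random_states(rng, 10):
            da = rhs(0.0, y, p, ko)[8]
            assert da == pytest.approx(p.b_a - p.lam_a * y[8] + p.B_STAT)

    def test_clamp_freezes_receptor(self, p, y0):
        assert rhs(0.0, y0.to_array(), p, clamp_S=True)[0] == 0.0

    def test_nonfinite_state_names_species(self, p, y0):
        y = y0.to_array()
        y[5] = np.nan
        with pytest.raises(Exception, match="R"):
            rhs(0.0, y, p)


class TestJacobian:
    @staticmethod
    def finite_difference(y, p, ko=KnockoutSpec()):
        # step balances truncation against roundoff from the ~1e6-size flux
        J = np.zeros((9, 9))
        for j in range(9):
            h = max(1e-5 * abs(y[j]), 1e-3)
            yp, ym = y.copy(), y.copy()
            yp[j] += h
            ym[j] -= h
            J[:, j] = (rhs(0.0, yp, p, ko) - rhs(0.0, ym, p, ko)) / (2 * h)
        return J

    def test_matches_finite_differences_at_reference_state(self, p, y0):
        y = y0.to_array()
        J = jacobian(y, p)
        Jfd = self.finite_difference(y, p)
        denom = np.maximum(np.abs(Jfd), 1e-8 * np.abs(Jfd).max())
        assert np.max(np.abs(J - Jfd) / denom) < 1e-5

    def test_matches_finite_differences_at_random_states(self, p, rng):
        worst = 0.0
        for y in random_states(rng, 20):
            y = y + 1.0  # keep away from the non-smooth origin
            J = jacobian(y, p)
            Jfd = self.finite_difference(y, p)
            denom = np.maximum(np.abs(Jfd), 1e-6 * np.abs(Jfd).max())
            worst = max(worst, np.max(np.abs(J - Jfd) / denom))
        assert worst < 1e-4

    def test_socs1_knockout_zeroes_R_coupling(self, p, rng):
        _, ko = apply_knockout(p, "socs1")
        for y in random_states(rng, 5):
            J = jacobian(y, p, ko)
            assert J[1, 5] == 0.0 and J[2, 5] == 0.0

    def test_clamped_shape_and_content(self, p, y0):
        y = y0.to_array()
        Jc = jacobian(y, p, clamp_S=True)
        assert Jc.shape == (8, 8)
        assert np.allclose(Jc, jacobian(y, p)[1:, 1:])

    def test_socs1_mrna_row(self, p, y0):
        from ifnosc.model_core import hill_derivative
        y = y0.to_array()
        J = jacobian(y, p)
        assert J[4, 4] == -p.lam_r
        assert J[4, 3] == pytest.approx(p.b_r * hill_derivative(y[3], p.k_r, p.n))


class TestDomainTypes:
    def test_reference_parameter_values(self, p):
        assert (p.b_ph, p.k_A, p.q, p.lam_S) == (1.3e3, 4680.0, 4, 0.0229)
        assert (p.k_I, p.b_imp, p.b_exp, p.lam_STAT) == (82680.0, 0.013, 0.048, 0.0007)

    def test_reference_initial_conditions(self, y0):
        assert (y0.A, y0.S, y0.Apn, y0.Apc) == (1e5, 1000.0, 1.0, 10.0)
        assert (y0.a, y0.f, y0.r, y0.F, y0.R) == (1.0,) * 5

    def test_invalid_values_rejected(self):
        with pytest.raises(InvalidParameterError):
            ParameterSet(lam_S=-0.1)
        with pytest.raises(InvalidParameterError):
            ParameterSet(q=0)
        with pytest.raises(InvalidParameterError):
            ParameterSet(k_A=0.0)
        with pytest.raises(InvalidStateError):
            StateVector.default_initial().replace(A=-5.0)

    def test_apply_knockout(self, p):
        assert apply_knockout(p, "none")[1] == KnockoutSpec()
        p2, ko = apply_knockout(p, "socs1")
        assert p2 == p and ko.socs1_feedback_off and not ko.irf1_feedback_off
        with pytest.raises(UsageError):
            apply_knockout(p, "stat3")
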