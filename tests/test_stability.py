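"""Clamped steady states, eigenvalue classification, 2D scans."""

import numpy as np
import pytest

from ifnosc import (clamped_steady_state,
                    classify_regime, stability_scan_2d, transient_peak_count)
from ifnosc.errors import UsageError
from ifnosc.model_core import KnockoutSpec, rhs


class TestClampedSteadyState:
    def test_unstimulated_cell_matches_hand_algebra(self, p):
        # With S = 0 the phosphorylation flux vanishes, every activated
        # branch drains to zero, and the remaining linear chain solves by
        # hand: a = B_STAT/lam_a, A = b_A*a/lam_STAT.
        ss = clamped_steady_state(p, S_fixed=0.0)
        a_expect = p.B_STAT / p.lam_a
        assert ss.Apc == pytest.approx(0.0, abs=1e-6)
        assert ss.Apn == pytest.approx(0.0, abs=1e-6)
        assert ss.r == pytest.approx(0.0, abs=1e-6)
        assert ss.f == pytest.approx(0.0, abs=1e-6)
        assert ss.a == pytest.approx(a_expect, rel=1e-8)
        assert ss.A == pytest.approx(p.b_A * a_expect / p.lam_STAT, rel=1e-8)

    def test_residual_below_tolerance(self, p):
        ss = clamped_steady_state(p, S_fixed=1000.0)
        res = rhs(0.0, ss.to_array(), p, clamp_S=True)[1:]
        scale = np.maximum(np.abs(ss.to_array()[1:]), 1.0)
        assert np.all(np.abs(res) < 1e-8 * scale + 1e-10)

    def test_root_unique_across_perturbed_seeds(self, p):
        ss1 = clamped_steady_state(p, S_fixed=1000.0)
        seed = ss1.to_array()[1:]
        ss2 = clamped_steady_state(p, S_fixed=1000.0, seed_state=seed * 2.0)
        assert np.allclose(ss1.to_array(), ss2.to_array(), rtol=1e-6)

    def test_negative_receptor_rejected(self, p):
        with pytest.raises(UsageError):
            clamped_steady_state(p, S_fixed=-1.0)


class TestClassifyRegime:
    def test_basal_point_is_oscillatory(self, p):
        res = classify_regime(p, S_fixed=1000.0)
        assert res.classification == "oscillatory"
        # eigenfrequency ~2*pi/|Im| of roughly three hours, matching the
        # observed spacing between the two pSTAT1 peaks
        period = 2 * np.pi / abs(res.leading_eigenvalue.imag)
        assert 120.0 < period < 260.0

    def test_very_fast_dephosphorylation_is_non_oscillatory(self, p):
        res = classify_regime(p.replace(b_deph=p.b_deph * 3000.0))
        assert res.classification == "non_oscillatory"

    def test_classification_invariant_to_im_tol(self, p):
        for tol in (1e-6, 1e-5, 1e-4):
            assert classify_regime(p, im_tol=tol).classification == "oscillatory"

    def test_eigenvalues_match_finite_difference_jacobian(self, p):
        from ifnosc.stability import _fast_jac, _fast_rhs, _fast_steady_state
        A_tot = 100011.0
        y4 = _fast_steady_state(p, 1000.0, A_tot, KnockoutSpec())
        J = _fast_jac(y4, p, 1000.0, A_tot, KnockoutSpec())
        Jfd = np.zeros((4, 4))
        for j in range(4):
            h = max(1e-5 * abs(y4[j]), 1e-4)
            yp, ym = y4.copy(), y4.copy()
            yp[j] += h
            ym[j] -= h
            Jfd[:, j] = (_fast_rhs(yp, p, 1000.0, A_tot, KnockoutSpec())
                         - _fast_rhs(ym, p, 1000.0, A_tot, KnockoutSpec())) / (2 * h)
        ev = np.sort_complex(np.linalg.eigvals(J))
        ev_fd = np.sort_complex(np.linalg.eigvals(Jfd))
        assert np.max(np.abs(ev - ev_fd) / np.maximum(np.abs(ev_fd), 1e-12)) < 1e-4

    def test_full_method_reports_slow_spectator_mode(self, p):
        # the full clamped system's leading eigenvalue is the slow real
        # STAT1-protein drift; the oscillatory pair sits deeper in the
        # spectrum (documented limitation of that construction)
        res = classify_regime(p, method="full")
        assert res.leading_eigenvalue.imag == pytest.approx(0.0, abs=1e-8)
        assert res.leading_eigenvalue.real == pytest.approx(-p.lam_STAT, rel=0.05)
        assert np.any(np.abs(res.eigenvalues.imag) > 0.01)

    def test_unknown_method_rejected(self, p):
        with pytest.raises(UsageError):
            classify_regime(p, method="spectral")


class TestStabilityScan:
    def test_degenerate_single_cell_reproduces_point_classification(self, p):
        smap = stability_scan_2d(p, "b_ph", "b_deph", resolution=1)
        assert smap.oscillatory.shape == (1, 1)
        assert bool(smap.oscillatory[0, 0])

    def test_basal_cell_oscillatory_in_both_planes(self, p):
        for px, py in (("b_ph", "b_deph"), ("b_imp", "b_exp")):
            smap = stability_scan_2d(p, px, py, resolution=5)
            i = np.argmin(np.abs(np.log(smap.x_values / smap.basal_point[0])))
            j = np.argmin(np.abs(np.log(smap.y_values / smap.basal_point[1])))
            assert smap.converged.all()
            assert bool(smap.oscillatory[i, j])

    def test_transport_imbalance_is_overdamped(self, p):
        smap = stability_scan_2d(p, "b_imp", "b_exp", resolution=5)
        # high export with low import: the oscillatory pair vanishes
        assert not smap.oscillatory[0, -1]
        # high import with low export: the ringing slows and weakens (the
        # pair's frequency drops well below basal) and the transient loses
        # its second peak
        i_b = np.argmin(np.abs(np.log(smap.x_values / smap.basal_point[0])))
        j_b = np.argmin(np.abs(np.log(smap.y_values / smap.basal_point[1])))
        assert smap.im_abs[-1, 0] < 0.5 * smap.im_abs[i_b, j_b]
        p_corner = p.replace(b_imp=float(smap.x_values[-1]),
                             b_exp=float(smap.y_values[0]))
        assert transient_peak_count(p_corner) <= 1

    def test_unknown_parameter_rejected(self, p):
        with pytest.raises(UsageError):
            stability_scan_2d(p, "b_ph", "k_bogus")

    def test_long_form_table_covers_grid(self, p):
        smap = stability_scan_2d(p, "b_imp", "b_exp", resolution=4)
        frame = smap.to_frame()
        assert len(frame) == 16
        assert set(frame["classification"]) <= {"oscillatory", "non_oscillatory",
                                                "unresolved"}


class TestTimeDomainConsistency:
    def test_confident_cells_match_transient_phenotype(self, p):
        # cells far from the classification boundary behave as classified
        # in the full decaying-receptor transient
        smap = stability_scan_2d(p, "b_imp", "b_exp", resolution=5)
        cells = [(i, j) for i in range(5) for j in range(5) if smap.converged[i, j]]
        osc = sorted((c for c in cells if smap.oscillatory[c]),
                     key=lambda c: -smap.im_abs[c])[:3]
        non = [c for c in cells if not smap.oscillatory[c]][:3]
        for i, j in osc:
            pij = p.replace(b_imp=float(smap.x_values[i]),
                            b_exp=float(smap.y_values[j]))
            assert transient_peak_count(pij) >= 2
        for i, j in non:
            pij = p.replace(b_imp=float(smap.x_values[i]),
                            b_exp=float(smap.y_values[j]))
            assert transient_peak_count(pij) <= 1
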