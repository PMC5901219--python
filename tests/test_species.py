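"""Growth-rate machinery: divergence, a_d(t), integrals, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize

from riparia import (InfeasibleCalibrationError, SpeciesParams,
                     calibrate_sensitivity, divergence, growth_rate,
                     sensitivity, sensitivity_integral)


class TestDivergence:
    def test_zero_at_favorable_level(self):
        assert divergence(83.03, 83.03) == 0.0

    def test_quadratic_penalty(self):
        assert divergence(84.0, 83.0) == pytest.approx(1.0)

    @given(st.floats(-5, 5), st.floats(0, 3))
    @settings(deadline=None)
    def test_symmetric_about_eta(self, eta, delta):
        assert divergence(eta + delta, eta) == pytest.approx(
            divergence(eta - delta, eta))


class TestGrowthRate:
    def test_formative_maximum_at_favorable_level(self, birch):
        assert growth_rate(83.03, 0.5, birch, eta=83.03) == pytest.approx(3.24)

    def test_decline_zero_at_favorable_level(self, birch):
        assert growth_rate(83.03, 10.0, birch, eta=83.03) == 0.0

    def test_decline_negative_for_positive_sensitivity(self, birch):
        # a_d > 0 early in the decline stage
        assert sensitivity(2.0, birch) > 0
        assert growth_rate(84.0, 2.0, birch, eta=83.03) < 0

    def test_stage_boundary_closed_on_the_left(self, birch):
        # at t = T_f the formative branch applies
        r = growth_rate(84.0, birch.T_f, birch, eta=83.03)
        assert r == pytest.approx(birch.lam
                                  - birch.a_f * divergence(84.0, 83.03))

    def test_rejects_nonpositive_time(self, birch):
        with pytest.raises(ValueError):
            growth_rate(83.0, 0.0, birch, eta=83.03)

    @given(st.floats(80, 86))
    @settings(deadline=None)
    def test_maximized_at_eta_in_both_stages(self, birch, h):
        eta = 83.03
        for t in (0.5, 5.0):
            assert growth_rate(h, t, birch, eta) <= growth_rate(eta, t,
                                                                birch, eta)


class TestSensitivity:
    def test_continuity_with_formative_sensitivity_at_one_year(self, birch):
        # a_d(1) = A + B + C e^D = 0.48973, within rounding of a_f = 0.49
        assert sensitivity(1.0, birch) == pytest.approx(0.48973, abs=5e-6)
        assert sensitivity(1.0, birch) == pytest.approx(birch.a_f, abs=1e-3)

    def test_stationary_point_location(self, birch):
        # root of B/t^2 = C D e^{D t}, bracketed independently
        der = lambda t: -birch.B / t ** 2 + birch.C * birch.D * np.exp(
            birch.D * t)
        t_star = optimize.brentq(der, 10.0, 100.0)
        assert t_star == pytest.approx(49.9, abs=0.1)
        h = 1e-4
        assert (sensitivity(t_star - h, birch) > sensitivity(t_star, birch)
                < sensitivity(t_star + h, birch))

    def test_constant_profile_when_b_and_c_vanish(self, birch):
        sp = birch.with_(B=0.0, C=0.0, A=0.2)
        ts = np.linspace(0.5, 80, 50)
        assert np.allclose(sensitivity(ts, sp), 0.2)

    def test_eventually_increasing_after_inflection(self, birch):
        ts = np.linspace(55, 200, 100)
        assert np.all(np.diff(sensitivity(ts, birch)) > 0)

    def test_rejects_nonpositive_time(self, birch):
        with pytest.raises(ValueError):
            sensitivity(0.0, birch)


class TestSensitivityIntegral:
    def test_degenerate_interval_is_zero(self, birch):
        assert sensitivity_integral(2.0, 2.0, birch, power=1) == 0.0
        assert sensitivity_integral(2.0, 2.0, birch, power=2) == 0.0

    def test_constant_profile_closed_forms(self, birch):
        sp = birch.with_(B=0.0, C=0.0, A=0.2)
        assert sensitivity_integral(1.0, 11.0, sp, 1) == pytest.approx(2.0)
        assert sensitivity_integral(1.0, 11.0, sp, 2) == pytest.approx(0.4)

    def test_closed_form_matches_quadrature(self, birch):
        # int_1^60 a_d dt: analytic antiderivative vs adaptive quadrature
        closed = sensitivity_integral(1.0, 60.0, birch, power=1)
        quad, _ = integrate.quad(lambda s: sensitivity(s, birch), 1.0, 60.0,
                                 epsabs=1e-12, limit=500)
        assert closed == pytest.approx(quad, abs=1e-8)

    def test_rejects_nonpositive_lower_limit(self, birch):
        with pytest.raises(ValueError):
            sensitivity_integral(0.0, 1.0, birch)


class TestCalibrateSensitivity:
    @staticmethod
    def _constraints_from(sp):
        der = lambda t: -sp.B / t ** 2 + sp.C * sp.D * np.exp(sp.D * t)
        t_ip = optimize.brentq(der, 10.0, 100.0)
        return dict(a_f=sensitivity(sp.T_f, sp), T_f=sp.T_f, t_ip=t_ip,
                    ad_min=sensitivity(t_ip, sp), t_maxage=60.0,
                    ad_max=sensitivity(60.0, sp))

    def test_round_trip_recovers_coefficients(self, birch):
        cons = self._constraints_from(birch)
        A, B, C, D = calibrate_sensitivity(**cons)
        assert A == pytest.approx(birch.A, rel=1e-4)
        assert B == pytest.approx(birch.B, rel=1e-4)
        assert C == pytest.approx(birch.C, rel=1e-4)
        assert D == pytest.approx(birch.D, rel=1e-4)

    def test_solution_satisfies_all_constraints(self, birch):
        cons = self._constraints_from(birch)
        A, B, C, D = calibrate_sensitivity(**cons)
        ad = lambda t: A + B / t + C * np.exp(D * t)
        assert ad(cons["T_f"]) == pytest.approx(cons["a_f"], abs=1e-8)
        assert ad(cons["t_ip"]) == pytest.approx(cons["ad_min"], abs=1e-8)
        assert ad(cons["t_maxage"]) == pytest.approx(cons["ad_max"], abs=1e-8)

    def test_flat_profile_is_infeasible(self):
        # ad_min must lie strictly below a_f (precondition)
        with pytest.raises((ValueError, InfeasibleCalibrationError)):
            calibrate_sensitivity(a_f=0.5, T_f=1.0, t_ip=30.0, ad_min=0.5,
                                  t_maxage=60.0, ad_max=0.5)

    def test_perturbing_ad_max_keeps_solvability(self, birch):
        cons = self._constraints_from(birch)
        cons["ad_max"] *= 0.9  # 10% change, still above ad_min
        if not cons["ad_min"] < min(cons["a_f"], cons["ad_max"]):
            pytest.fail("perturbed instance violated its own precondition")
        A, B, C, D = calibrate_sensitivity(**cons)
        ad = lambda t: A + B / t + C * np.exp(D * t)
        assert ad(cons["t_maxage"]) == pytest.approx(cons["ad_max"], abs=1e-8)


class TestSpeciesParams:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="n_e"):
            SpeciesParams.birch(n_e=0.2, eps=0.05)

    def test_age_ordering_enforced(self):
        with pytest.raises(ValueError, match="t_ip"):
            SpeciesParams.birch(t_ip=70.0, t_maxage=60.0)
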