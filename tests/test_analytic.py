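"""Closed-form stage laws: moments, V1-V3, continuity, PDFs, mean abundance."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import expit, logit

from riparia import (abundance_pdf, continuity_constant, decline_moments,
                     formative_moments, mean_abundance, sensitivity)
from riparia.analytic import DegenerateDistributionError

PLOT1 = dict(eta_prime=-0.23, sigma=0.58)


class TestFormativeMoments:
    def test_initial_condition(self, birch):
        m = formative_moments(0.0, birch, **PLOT1)
        assert m.mean == pytest.approx(logit(0.05), abs=1e-10)
        assert m.variance == 0.0

    def test_worked_values_at_stage_boundary(self, birch):
        # M = 0.23^2 + 0.58^2 = 0.38930; mean = logit(.05) + (3.24-0.49M)
        m = formative_moments(1.0, birch, **PLOT1)
        assert m.M == pytest.approx(0.38930, abs=1e-5)
        assert m.mean == pytest.approx(0.1049, abs=2e-4)
        assert m.variance == pytest.approx(0.01709, abs=2e-5)
        assert m.transform == "logit"

    def test_white_noise_variance_is_v1_alone(self, birch):
        m = formative_moments(0.7, birch, **PLOT1)
        assert m.V2 == 0.0 and m.V3 == 0.0
        assert m.variance == pytest.approx(
            4 * birch.a_f ** 2 * m.Sigma ** 2 * 0.7)

    def test_correlation_time_vanishing_limit(self, birch):
        # V2, V3 -> 0 as tau_h -> 0; total variance -> V1
        m0 = formative_moments(1.0, birch, **PLOT1)
        extra_prev = np.inf
        for tau in (1e-2, 1e-4, 1e-6, 1e-8):
            m = formative_moments(1.0, birch, tau_h=tau, **PLOT1)
            extra = m.V2 + m.V3
            assert 0 < extra < extra_prev
            extra_prev = extra
        assert m.variance == pytest.approx(m0.variance, rel=1e-6)

    def test_correlation_time_inflates_variance_not_mean(self, birch):
        m0 = formative_moments(1.0, birch, **PLOT1)
        for tau in (0.5, 2.0, 10.0):
            m = formative_moments(1.0, birch, tau_h=tau, **PLOT1)
            assert m.mean == m0.mean
            assert m.variance > m0.variance

    def test_sign_of_drift_decides_expansion(self, birch):
        # mean increases iff lam - a_f M > 0
        for ep in (0.0, 0.5, 1.5, 2.5, 3.0):
            m = formative_moments(1.0, birch, eta_prime=ep, sigma=0.58)
            drift = birch.lam - birch.a_f * m.M
            assert (m.mean > logit(birch.eps)) == (drift > 0) or drift == 0

    def test_symmetric_roles_of_divergence_and_deviation(self, birch):
        # swapping (eta', sigma) preserves (M, Sigma^2), hence the law
        a = formative_moments(1.0, birch, eta_prime=-0.23, sigma=0.58)
        b = formative_moments(1.0, birch, eta_prime=0.58, sigma=0.23)
        assert a.mean == pytest.approx(b.mean)
        assert a.variance == pytest.approx(b.variance)

    def test_outside_stage_rejected(self, birch):
        with pytest.raises(ValueError):
            formative_moments(1.5, birch, **PLOT1)


class TestContinuityConstant:
    def test_degenerate_variance_limit(self, birch):
        # with sigma = 0 and eta' chosen so the mean is 0.1049 the law is a
        # point mass: c2 = log(invlogit(0.1049)) = log(0.52620)
        ep = math.sqrt((birch.lam - (0.1049 - logit(0.05))) / birch.a_f)
        c2 = continuity_constant(birch, eta_prime=ep, sigma=0.0)
        assert c2 == pytest.approx(math.log(0.52620), abs=1e-4)

    def test_large_mean_limit_is_zero(self, birch):
        sp = birch.with_(lam=30.0)
        c2 = continuity_constant(sp, eta_prime=0.0, sigma=0.1)
        assert -1e-6 < c2 <= 0.0

    def test_matches_monte_carlo(self, birch, rng):
        from riparia.analytic import formative_moments as fm
        m = fm(birch.T_f, birch, **PLOT1)
        draws = rng.normal(m.mean, math.sqrt(m.variance), size=1_000_000)
        mc = np.mean(-np.logaddexp(0.0, -draws))
        se = np.std(-np.logaddexp(0.0, -draws)) / 1000.0
        c2 = continuity_constant(birch, **PLOT1)
        assert abs(c2 - mc) < 3 * se


class TestDeclineMoments:
    def test_continuity_at_stage_boundary(self, birch):
        c2 = continuity_constant(birch, **PLOT1)
        m = decline_moments(1.0 + 1e-9, birch, c2=c2, **PLOT1)
        assert m.mean == pytest.approx(c2, abs=1e-6)
        assert m.variance == pytest.approx(0.0, abs=1e-6)

    def test_constant_sensitivity_closed_form(self, birch):
        sp = birch.with_(B=0.0, C=0.0, A=0.2)
        m = decline_moments(11.0, sp, c2=-0.1, **PLOT1)
        M = 0.23 ** 2 + 0.58 ** 2
        S2 = (0.23 * 0.58) ** 2
        assert m.mean == pytest.approx(-0.1 - M * 0.2 * 10.0)
        assert m.variance == pytest.approx(4 * S2 * 0.04 * 10.0)

    def test_matches_refined_trapezoid_quadrature(self, birch):
        m = decline_moments(30.0, birch, c2=-0.644, **PLOT1)
        ts = np.linspace(1.0, 30.0, 2_000_001)
        ad = sensitivity(ts, birch)
        i1 = np.trapezoid(ad, ts)
        i2 = np.trapezoid(ad ** 2, ts)
        assert m.mean == pytest.approx(-0.644 - m.M * i1, abs=1e-8)
        assert m.variance == pytest.approx(4 * m.Sigma ** 2 * i2, abs=1e-8)

    def test_inside_formative_stage_rejected(self, birch):
        with pytest.raises(ValueError):
            decline_moments(0.5, birch, c2=0.0, **PLOT1)


class TestAbundancePdf:
    def test_logit_normal_normalizes_to_one(self, birch):
        m = formative_moments(1.0, birch, **PLOT1)
        val, _ = integrate.quad(lambda n: abundance_pdf(n, m), 0.0, 1.0,
                                epsabs=1e-10, limit=500)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_small_variance_concentrates_at_half(self, birch):
        m = formative_moments(1.0, birch, **PLOT1)
        tight = type(m)(**{**m.__dict__, "mean": 0.0, "variance": 1e-6})
        assert abundance_pdf(0.5, tight) > abundance_pdf(0.45, tight) * 1e6

    def test_log_normal_closed_form_point(self, birch):
        c2 = -0.644
        m = decline_moments(5.0, birch, c2=c2, **PLOT1)
        n0 = math.exp(m.mean)
        expected = 1.0 / (n0 * math.sqrt(2 * math.pi * m.variance))
        assert abundance_pdf(n0, m) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_is_signalled(self, birch):
        m = formative_moments(0.0, birch, **PLOT1)
        with pytest.raises(DegenerateDistributionError):
            abundance_pdf(0.5, m)

    def test_support_is_open_unit_interval(self, birch):
        m = formative_moments(1.0, birch, **PLOT1)
        with pytest.raises(ValueError):
            abundance_pdf(1.0, m)


class TestMeanAbundance:
    def test_degenerate_limit_is_inverse_logit_of_mean(self, birch):
        val = mean_abundance(1.0, birch, eta_prime=0.5, sigma=0.0)
        m = formative_moments(1.0, birch, eta_prime=0.5, sigma=0.0)
        assert val == pytest.approx(float(expit(m.mean)))

    def test_peaks_at_zero_divergence(self, birch):
        grid = np.linspace(-1.0, 1.0, 21)
        vals = [mean_abundance(1.0, birch, ep, 0.58) for ep in grid]
        assert int(np.argmax(vals)) == 10  # eta' = 0

    def test_increases_with_correlation_time(self, birch):
        # inverse-logit is convex below 0, so while the mean of logit n is
        # negative (early formative stage) the extra colored-noise variance
        # lifts both the mean and the variance of n itself
        import math

        from scipy import integrate

        def n_moments(tau):
            m = formative_moments(0.5, birch, tau_h=tau, **PLOT1)
            sd = math.sqrt(m.variance)
            mom = []
            for p in (1, 2):
                val, _ = integrate.quad(
                    lambda z: expit(m.mean + sd * z) ** p
                    * math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi),
                    -np.inf, np.inf)
                mom.append(val)
            return mom[0], mom[1] - mom[0] ** 2

        means, variances = zip(*(n_moments(tau) for tau in (0.0, 0.5, 2.0)))
        assert means[0] < means[1] < means[2]
        assert variances[0] < variances[1] < variances[2]

    def test_matches_ensemble_mean(self, plot1):
        ens = plot1.simulate(t_max=1.0, n_paths=10_000, seed=5)
        mc = ens.n[-1].mean()
        se = ens.n[-1].std(ddof=1) / 100.0
        assert abs(plot1.mean_abundance(1.0) - mc) < 3 * se
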