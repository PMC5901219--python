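"""Closed-form solution of the stage-switched stochastic cohort dynamics.

Under Stratonovich calculus the transformed abundance is Gaussian in each
stage: ``logit n(t)`` during the formative stage and ``log n(t)`` during the
decline stage.  With the mean divergence ``eta' = mu - eta`` and the
substitutions ``M = eta'^2 + sigma^2`` and ``Sigma = eta' * sigma``:

formative (t <= T_f), white-noise forcing::

    mean     m1(t) = logit(eps) + (lambda - a_f M) t
    variance V1(t) = 4 a_f^2 Sigma^2 t

formative, O-U forcing with rate ``alpha = 1/tau_h`` adds two terms::

    V2(t) = (8 a_f^2 Sigma^2 / alpha^2) (alpha t - 1 + e^{-alpha t})
    V3(t) = (a_f^2 sigma^4 / alpha^2) (2 alpha t - 1 + e^{-2 alpha t})

decline (t > T_f), white-noise treatment (timescale separation)::

    mean     m2(t) = c2 - M * int_{T_f}^t a_d(s) ds
    variance v2(t) = 4 Sigma^2 * int_{T_f}^t a_d(s)^2 ds

``c2 = E[log n(T_f)]`` carries distribution-level continuity across the
stage boundary.  The abundance ``n`` itself is logit-normal, transitioning
to log-normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import expit, logit

from .species import SpeciesParams, sensitivity_integral

__all__ = [
    "StageMoments",
    "formative_moments",
    "decline_moments",
    "continuity_constant",
    "abundance_pdf",
    "mean_abundance",
    "DegenerateDistributionError",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


class DegenerateDistributionError(ValueError):
    """Zero-variance stage law: the distribution is a point mass."""


@dataclass(frozen=True)
class StageMoments:
    """Gaussian law of the transformed abundance at one time point.

    ``transform`` is ``"logit"`` (formative stage) or ``"log"`` (decline
    stage); ``mean``/``variance`` refer to the transformed variable.  The
    intermediates M (m^2), Sigma (m^2), c1/c2 (initial and continuity
    constants) and the variance decomposition V1, V2, V3 are carried for
    inspection.
    """

    stage: str
    transform: str
    t: float
    mean: float
    variance: float
    M: float
    Sigma: float
    c1: float | None = None
    c2: float | None = None
    V1: float | None = None
    V2: float | None = None
    V3: float | None = None


def _mh_substitutions(eta_prime: float, sigma: float) -> tuple[float, float]:
    return eta_prime ** 2 + sigma ** 2, eta_prime * sigma


def formative_moments(t: float, sp: SpeciesParams, eta_prime: float,
                      sigma: float, tau_h: float = 0.0) -> StageMoments:
    """Mean and variance of logit n(t) in the formative stage.

    For ``tau_h = 0`` the variance is V1 alone; for ``tau_h > 0`` the
    correlation time adds V2 (through Sigma) and V3 (through sigma only).
    The mean is unaffected by ``tau_h``.
    """
    if not 0 <= t <= sp.T_f:
        raise ValueError(f"formative stage requires 0 <= t <= T_f={sp.T_f}")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if tau_h < 0:
        raise ValueError("tau_h must be >= 0")
    M, Sigma = _mh_substitutions(eta_prime, sigma)
    c1 = float(logit(sp.eps))
    mean = c1 + (sp.lam - sp.a_f * M) * t
    V1 = 4.0 * sp.a_f ** 2 * Sigma ** 2 * t
    if tau_h == 0.0:
        V2 = V3 = 0.0
    else:
        alpha = 1.0 / tau_h
        at = alpha * t
        V2 = (8.0 * sp.a_f ** 2 * Sigma ** 2 / alpha ** 2
              * (at - 1.0 + math.exp(-at)))
        V3 = (sp.a_f ** 2 * sigma ** 4 / alpha ** 2
              * (2.0 * at - 1.0 + math.exp(-2.0 * at)))
    return StageMoments(stage="formative", transform="logit", t=float(t),
                        mean=float(mean), variance=float(V1 + V2 + V3),
                        M=M, Sigma=Sigma, c1=c1, V1=V1, V2=V2, V3=V3)


def continuity_constant(sp: SpeciesParams, eta_prime: float, sigma: float,
                        tau_h: float = 0.0, epsabs: float = 1e-10) -> float:
    """Continuity constant c2 = E[log n(T_f)] across the stage boundary.

    Computed by adaptive quadrature of ``log(invlogit(x))`` against the
    Gaussian law of ``logit n(T_f)``, on the standard-normal scale to avoid
    endpoint singularities.  ``log(invlogit(x)) = -log(1 + e^{-x})`` is
    evaluated stably via logaddexp.
    """
    fm = formative_moments(sp.T_f, sp, eta_prime, sigma, tau_h)
    m, v = fm.mean, fm.variance
    if v == 0.0:
        return float(-np.logaddexp(0.0, -m))
    sd = math.sqrt(v)

    def integrand(z: float) -> float:
        return (-np.logaddexp(0.0, -(m + sd * z))
                * math.exp(-0.5 * z * z) / _SQRT2PI)

    val, err = integrate.quad(integrand, -np.inf, np.inf, epsabs=epsabs,
                              limit=500)
    if not math.isfinite(val) or err > 1e-6:
        raise RuntimeError(f"c2 quadrature did not converge (err={err:.2g})")
    return float(val)


def decline_moments(t: float, sp: SpeciesParams, eta_prime: float,
                    sigma: float, c2: float | None = None,
                    tau_h_formative: float = 0.0) -> StageMoments:
    """Mean and variance of log n(t) in the decline stage (t > T_f).

    The mean drifts as ``c2 - M * int a_d`` (downward whenever a_d > 0) and
    the variance grows as ``4 Sigma^2 * int a_d^2``.  The decline stage is
    treated under white noise regardless of ``tau_h`` (timescale
    separation); ``tau_h_formative`` only affects ``c2`` when it is not
    supplied.
    """
    if not t > sp.T_f:
        raise ValueError(f"decline stage requires t > T_f={sp.T_f}")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    M, Sigma = _mh_substitutions(eta_prime, sigma)
    if c2 is None:
        c2 = continuity_constant(sp, eta_prime, sigma, tau_h_formative)
    mean = c2 - M * sensitivity_integral(sp.T_f, t, sp, power=1)
    var = 4.0 * Sigma ** 2 * sensitivity_integral(sp.T_f, t, sp, power=2)
    return StageMoments(stage="decline", transform="log", t=float(t),
                        mean=float(mean), variance=float(var),
                        M=M, Sigma=Sigma, c2=float(c2))


def stage_moments(t: float, sp: SpeciesParams, eta_prime: float,
                  sigma: float, tau_h: float = 0.0,
                  c2: float | None = None) -> StageMoments:
    """Moments of the active stage at time t (formative on [0, T_f])."""
    if t <= sp.T_f:
        return formative_moments(t, sp, eta_prime, sigma, tau_h)
    return decline_moments(t, sp, eta_prime, sigma, c2=c2,
                           tau_h_formative=tau_h)


def abundance_pdf(n, moments: StageMoments):
    """Density of the normalized abundance n under the stage law.

    Logit-normal for the formative stage, log-normal for the decline stage
    (not truncated to (0, 1]; the decline law assigns vanishing mass above
    the stage-boundary abundance).
    """
    n_arr = np.asarray(n, dtype=float)
    if np.any((n_arr <= 0) | (n_arr >= 1)):
        raise ValueError("abundance density is evaluated on 0 < n < 1")
    if moments.variance <= 0:
        raise DegenerateDistributionError(
            "zero-variance stage law is a point mass; density undefined")
    m, sd = moments.mean, math.sqrt(moments.variance)
    if moments.transform == "logit":
        x = logit(n_arr)
        jac = 1.0 / (n_arr * (1.0 - n_arr))
    elif moments.transform == "log":
        x = np.log(n_arr)
        jac = 1.0 / n_arr
    else:  # pragma: no cover - constructor controls the tag
        raise ValueError(f"unknown transform {moments.transform!r}")
    dens = np.exp(-0.5 * ((x - m) / sd) ** 2) / (sd * _SQRT2PI) * jac
    return float(dens) if dens.ndim == 0 else dens


def mean_abundance(t: float, sp: SpeciesParams, eta_prime: float,
                   sigma: float, tau_h: float = 0.0,
                   c2: float | None = None, epsabs: float = 1e-10) -> float:
    """Expected abundance E[n(t)] under the active stage law.

    Adaptive quadrature against the stage PDF on the Gaussian scale:
    ``E[invlogit(m + sd Z)]`` (formative) or ``E[e^{m + sd Z}]`` (decline).
    """
    mom = stage_moments(t, sp, eta_prime, sigma, tau_h, c2=c2)
    m, v = mom.mean, mom.variance
    if mom.transform == "logit":
        if v == 0.0:
            return float(expit(m))
        sd = math.sqrt(v)
        val, _ = integrate.quad(
            lambda z: expit(m + sd * z) * math.exp(-0.5 * z * z) / _SQRT2PI,
            -np.inf, np.inf, epsabs=epsabs, limit=500)
    else:
        if v == 0.0:
            return float(math.exp(m))
        sd = math.sqrt(v)
        val, _ = integrate.quad(
            lambda z: math.exp(m + sd * z - 0.5 * z * z) / _SQRT2PI,
            -np.inf, np.inf, epsabs=epsabs, limit=500)
    return float(val)
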