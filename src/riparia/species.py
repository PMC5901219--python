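"""Species-specific growth-rate machinery.

A same-aged cohort grows logistically during its formative stage (age up to
``T_f``) and decays exponentially afterwards.  The growth rate responds to
the water table ``h`` through a quadratic divergence penalty
``D(h - eta) = (h - eta)^2`` around the plot's favorable level ``eta``:

    r(h, t) = lambda - a_f * D(h - eta)      for t <= T_f,
    r(h, t) = -a_d(t) * D(h - eta)           for t >  T_f,

where the decline-stage sensitivity is time-varying,

    a_d(t) = A + B/t + C * exp(D * t),

combining a 1/t decrease as individuals grow taller with an exponential
increase as they senesce.  ``A`` pins continuity ``a_d(T_f) = a_f``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "SpeciesParams",
    "InfeasibleCalibrationError",
    "divergence",
    "growth_rate",
    "sensitivity",
    "sensitivity_integral",
    "calibrate_sensitivity",
]

ArrayLike = Union[float, np.ndarray]


class InfeasibleCalibrationError(RuntimeError):
    """The sensitivity constraint system admits no (A, B, C, D) solution."""


@dataclass(frozen=True)
class SpeciesParams:
    """All species-specific constants of the cohort model.

    Units: ``lam`` (yr^-1), ``a_f``/``A``/``C`` (yr^-1 m^-2), ``B`` (m^-2),
    ``D`` (yr^-1), ``T_f``/``t_ip``/``t_maxage`` (yr); ``eps`` (initial
    abundance) and ``n_e`` (extinction threshold) are dimensionless with
    ``0 < n_e < eps < 1``.
    """

    lam: float
    a_f: float
    A: float
    B: float
    C: float
    D: float
    T_f: float = 1.0
    eps: float = 0.05
    n_e: float = 0.01
    t_ip: float | None = None
    t_maxage: float | None = None

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lam (maximum growth rate) must be > 0")
        if not self.a_f > 0:
            raise ValueError("a_f (formative sensitivity) must be > 0")
        if not self.T_f > 0:
            raise ValueError("T_f (formative duration) must be > 0")
        if not self.D > 0:
            raise ValueError("D (senescence rate) must be > 0")
        if not (0.0 < self.n_e < self.eps < 1.0):
            raise ValueError("need 0 < n_e < eps < 1")
        if self.t_ip is not None and self.t_maxage is not None:
            if not (self.T_f < self.t_ip < self.t_maxage):
                raise ValueError("need T_f < t_ip < t_maxage")

    @classmethod
    def birch(cls, **overrides) -> "SpeciesParams":
        """A white-birch parameter set calibrated for a sandy riparian plot.

        ``T_f = 1`` yr is inferred from continuity (``a_d(1) = 0.4897`` is
        within rounding of ``a_f = 0.49``); ``t_ip`` and ``t_maxage`` are
        inferred life-history defaults, not measured values.
        """
        base = dict(lam=3.24, a_f=0.49, A=-0.024, B=0.513, C=7e-4, D=0.04,
                    T_f=1.0, eps=0.05, n_e=0.01, t_ip=49.9, t_maxage=60.0)
        base.update(overrides)
        return cls(**base)

    def with_(self, **changes) -> "SpeciesParams":
        return replace(self, **changes)


def divergence(h: ArrayLike, eta: float) -> ArrayLike:
    """Quadratic divergence penalty D(h - eta) = (h - eta)^2 (m^2)."""
    d = np.square(np.asarray(h, dtype=float) - eta)
    return float(d) if d.ndim == 0 else d


def sensitivity(t: ArrayLike, sp: SpeciesParams) -> ArrayLike:
    """Decline-stage sensitivity a_d(t) = A + B/t + C e^{D t} (yr^-1 m^-2)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("sensitivity is undefined for t <= 0 (1/t term)")
    a = sp.A + sp.B / t + sp.C * np.exp(sp.D * t)
    return float(a) if a.ndim == 0 else a


def growth_rate(h: ArrayLike, t: float, sp: SpeciesParams,
                eta: float) -> ArrayLike:
    """Stage-switched growth rate r(h, t) (yr^-1).

    The formative branch applies on ``(0, T_f]`` (closed on the left at the
    stage boundary); the decline branch on ``(T_f, inf)``.
    """
    if t <= 0:
        raise ValueError("growth_rate requires t > 0")
    d = divergence(h, eta)
    if t <= sp.T_f:
        return sp.lam - sp.a_f * d
    return -sensitivity(t, sp) * d


def sensitivity_integral(t0: float, t1: float, sp: SpeciesParams,
                         power: int = 1) -> float:
    """Integral of a_d (power=1, closed form) or a_d^2 (power=2, quadrature).

    power=1:  A (t1-t0) + B ln(t1/t0) + (C/D)(e^{D t1} - e^{D t0}).
    power=2:  adaptive quadrature, absolute tolerance 1e-10 (the cross terms
    have no elementary antiderivative).
    """
    if not 0 < t0 <= t1:
        raise ValueError("need 0 < t0 <= t1")
    if t0 == t1:
        return 0.0
    if power == 1:
        return (sp.A * (t1 - t0) + sp.B * np.log(t1 / t0)
                + (sp.C / sp.D) * (np.exp(sp.D * t1) - np.exp(sp.D * t0)))
    if power == 2:
        val, _ = integrate.quad(lambda s: sensitivity(s, sp) ** 2, t0, t1,
                                epsabs=1e-10, limit=500)
        return float(val)
    raise ValueError("power must be 1 or 2")


def _solve_abc_given_d(d: float, a_f: float, T_f: float, t_ip: float,
                       ad_min: float, t_maxage: float,
                       ad_max: float) -> tuple[float, float, float]:
    """Solve the three value constraints, linear in (A, B, C), at fixed D."""
    ts = np.array([T_f, t_ip, t_maxage])
    mat = np.column_stack([np.ones(3), 1.0 / ts, np.exp(d * ts)])
    rhs = np.array([a_f, ad_min, ad_max])
    a, b, c = np.linalg.solve(mat, rhs)
    return float(a), float(b), float(c)


def calibrate_sensitivity(a_f: float, T_f: float, t_ip: float, ad_min: float,
                          t_maxage: float, ad_max: float,
                          d_max: float = 2.0,
                          residual_tol: float = 1e-8
                          ) -> tuple[float, float, float, float]:
    """Solve the four-constraint system for the a_d(t) coefficients.

    Constraints: continuity ``a_d(T_f) = a_f``; growth inflection
    ``a_d'(t_ip) = 0``; minimum sensitivity ``a_d(t_ip) = ad_min``; maximum
    sensitivity ``a_d(t_maxage) = ad_max``.

    At fixed ``D`` the three value constraints are linear in (A, B, C), so
    the system reduces to a bracketed 1-D root-find on the inflection
    residual ``-B/t_ip^2 + C D e^{D t_ip}`` over ``D in (0, d_max]``.
    Raises :class:`InfeasibleCalibrationError` when no root exists.
    """
    if not (T_f < t_ip < t_maxage):
        raise ValueError("need T_f < t_ip < t_maxage")
    if not ad_min < min(a_f, ad_max):
        raise ValueError("need ad_min < min(a_f, ad_max)")

    def inflection_residual(d: float) -> float:
        _, b, c = _solve_abc_given_d(d, a_f, T_f, t_ip, ad_min, t_maxage,
                                     ad_max)
        return -b / t_ip ** 2 + c * d * np.exp(d * t_ip)

    d_grid = np.geomspace(1e-6, d_max, 400)
    vals = np.array([inflection_residual(d) for d in d_grid])
    finite = np.isfinite(vals)
    d_grid, vals = d_grid[finite], vals[finite]
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise InfeasibleCalibrationError(
            "no (A, B, C, D) profile satisfies the four constraints "
            f"(a_f={a_f}, ad_min={ad_min}, ad_max={ad_max})")
    i = sign_change[0]
    d_root = optimize.brentq(inflection_residual, d_grid[i], d_grid[i + 1],
                             xtol=1e-14, rtol=8.9e-16)
    a, b, c = _solve_abc_given_d(d_root, a_f, T_f, t_ip, ad_min, t_maxage,
                                 ad_max)
    # verify all four constraints
    ad = lambda t: a + b / t + c * np.exp(d_root * t)
    resid = max(abs(ad(T_f) - a_f), abs(ad(t_ip) - ad_min),
                abs(ad(t_maxage) - ad_max),
                abs(-b / t_ip ** 2 + c * d_root * np.exp(d_root * t_ip)))
    if not resid < residual_tol:
        raise InfeasibleCalibrationError(
            f"constraint residual {resid:.3g} exceeds {residual_tol}")
    return a, b, c, float(d_root)
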