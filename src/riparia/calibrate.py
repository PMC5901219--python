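"""Calibration of species parameters from multi-plot abundance samples.

During the formative stage ``logit n`` is Gaussian with linear mean, so an
ordinary least-squares slope ``v_i`` of ``logit n`` against time in plot
``i`` estimates ``lambda - a_f * M_i`` with ``M_i = eta'_i^2 + sigma^2``.
Plots share ``lambda`` and ``a_f`` while the favorable levels differ by the
known altitude offsets, ``eta_i - eta_j = ALT_i - ALT_j``, so three or more
plots at distinct altitudes identify ``(lambda, a_f, eta'_1)`` from the
nonlinear system

    lambda - a_f ((eta'_1 - d_i)^2 + sigma^2) = v_i,   d_i = ALT_i - ALT_1,

solved by bounded nonlinear least squares with multi-start (the quadratic
system is non-convex and can carry a mirrored local optimum, which is
reported when present).  ``sigma`` comes from the independently estimated
flow regime (two-stage procedure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .flow import FlowRegime
from .species import SpeciesParams

__all__ = ["PlotSite", "CalibrationResult", "SpeciesCalibration",
           "fit_plot_slopes", "solve_species_params",
           "generate_calibration_fixture"]


@dataclass(frozen=True)
class PlotSite:
    """A sample plot on the transect.

    ``eta`` (favorable water level, m) may be unknown prior to calibration;
    the divergence against a regime is ``eta' = mu - eta``.
    """

    id: str
    x: float
    altitude: float
    eta: float | None = None

    def eta_prime(self, regime: FlowRegime) -> float:
        if self.eta is None:
            raise ValueError(f"plot {self.id}: eta is not set")
        return regime.mu - self.eta


@dataclass
class CalibrationResult:
    """Estimates from the multi-plot slope system.

    ``eta`` differences across plots equal the altitude differences by
    construction; ``alternatives`` lists any distinct local optimum of
    comparable residual (mirror solution of the quadratic system).
    """

    lam: float
    a_f: float
    eta_prime: np.ndarray
    eta: np.ndarray
    slopes: np.ndarray
    plot_ids: list
    resid_norm: float
    alternatives: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Species calibration (formative-stage slope system)",
            "=" * 52,
            f"lambda (max growth rate)      {self.lam:12.6g}  1/yr",
            f"a_f    (formative sensitivity){self.a_f:12.6g}  1/(yr m^2)",
            f"residual norm                 {self.resid_norm:12.3e}",
            "-" * 52,
            f"{'plot':>8} {'slope v_i':>12} {'eta_prime':>12} {'eta':>10}",
        ]
        for pid, v, ep, e in zip(self.plot_ids, self.slopes,
                                 self.eta_prime, self.eta):
            lines.append(f"{pid:>8} {v:12.6g} {ep:12.6g} {e:10.6g}")
        if self.alternatives:
            lines.append("-" * 52)
            lines.append(f"note: {len(self.alternatives)} alternative "
                         "local optimum(s) of comparable residual exist")
        return "\n".join(lines)


def fit_plot_slopes(samples: pd.DataFrame, T_f: float | None = None
                    ) -> pd.DataFrame:
    """OLS slopes of logit(n) against t, per plot.

    ``samples`` needs columns ``plot_id``, ``t``, ``n`` with all abundances
    in (0, 1) and at least two time points per plot; if ``T_f`` is given,
    samples outside the formative window are rejected.
    Returns a frame (plot_id, slope, intercept, stderr).
    """
    req = {"plot_id", "t", "n"}
    if not req.issubset(samples.columns):
        raise ValueError(f"samples must have columns {sorted(req)}")
    n = samples["n"].to_numpy(dtype=float)
    if np.any((n <= 0) | (n >= 1)):
        raise ValueError("abundances must lie strictly in (0, 1)")
    if T_f is not None and np.any(samples["t"].to_numpy() > T_f):
        raise ValueError(f"samples beyond the formative window T_f={T_f}")
    rows = []
    for pid, grp in samples.groupby("plot_id", sort=True):
        t = grp["t"].to_numpy(dtype=float)
        if t.size < 2 or np.unique(t).size < 2:
            raise ValueError(f"plot {pid}: need >= 2 distinct time points")
        y = logit(grp["n"].to_numpy(dtype=float))
        if t.size == 2:
            slope = (y[1] - y[0]) / (t[1] - t[0])
            rows.append({"plot_id": pid, "slope": float(slope),
                         "intercept": float(y[0] - slope * t[0]),
                         "stderr": np.nan})
        else:
            res = stats.linregress(t, y)
            rows.append({"plot_id": pid, "slope": float(res.slope),
                         "intercept": float(res.intercept),
                         "stderr": float(res.stderr)})
    return pd.DataFrame(rows)


def solve_species_params(v, plots, regime: FlowRegime, n_starts: int = 24,
                         resid_tol: float = 1e-8) -> CalibrationResult:
    """Solve the slope system for (lambda, a_f, eta'_1) and plot-wise eta.

    ``v`` are the per-plot formative slopes (aligned with ``plots``); at
    least three plots with distinct altitudes are required.  Multi-start
    bounded least squares enforces ``a_f > 0``; with exactly three plots and
    consistent data the residual is ~0.
    """
    v = np.asarray(v, dtype=float)
    if len(plots) < 3:
        raise ValueError("need at least 3 plots to identify (lambda, a_f, eta)")
    if v.size != len(plots):
        raise ValueError("one slope per plot required")
    alts = np.array([p.altitude for p in plots], dtype=float)
    if np.unique(alts).size < len(plots):
        raise ValueError("plot altitudes must be distinct (system rank)")
    d = alts - alts[0]
    sig2 = regime.sigma ** 2

    def resid(theta):
        lam, a_f, ep1 = theta
        return lam - a_f * ((ep1 - d) ** 2 + sig2) - v

    spread = max(1.0, float(np.ptp(d)))
    starts = []
    for ep0 in np.linspace(-2.0 * spread, 2.0 * spread, n_starts):
        starts.append((float(np.max(v)) + 0.5, 0.5, float(ep0)))
    solutions = []
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=([-np.inf, 1e-12, -np.inf],
                                   [np.inf, np.inf, np.inf]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        solutions.append((float(np.linalg.norm(sol.fun)), sol.x))
    if not solutions:
        raise RuntimeError("least-squares solver failed from every start")
    solutions.sort(key=lambda s: s[0])
    best_norm, best = solutions[0]
    if len(plots) == 3 and best_norm > resid_tol * max(1.0, np.abs(v).max()):
        raise RuntimeError("3-plot system did not reach a consistent "
                           f"solution (residual {best_norm:.3g})")
    # collect distinct alternative optima of comparable residual
    alternatives = []
    for norm, x in solutions[1:]:
        if norm <= max(10 * best_norm, 1e-10) and \
                not any(np.allclose(x, a, atol=1e-6) for _, a in
                        [(best_norm, best)] + [(0, a) for a in alternatives]):
            alternatives.append(np.asarray(x))
    lam, a_f, ep1 = best
    eta_prime = ep1 - d
    return CalibrationResult(
        lam=float(lam), a_f=float(a_f), eta_prime=eta_prime,
        eta=regime.mu - eta_prime, slopes=v,
        plot_ids=[p.id for p in plots], resid_norm=best_norm,
        alternatives=alternatives)


class SpeciesCalibration:
    """Model object for the two-stage species calibration.

    Built from per-plot formative-stage samples (or pre-computed slopes),
    plot metadata and an independently estimated flow regime; ``fit()``
    returns a :class:`CalibrationResult`.
    """

    def __init__(self, slopes, plots, regime: FlowRegime):
        self.slopes = np.asarray(slopes, dtype=float)
        self.plots = list(plots)
        self.regime = regime

    @classmethod
    def from_samples(cls, samples: pd.DataFrame, plots, regime: FlowRegime,
                     T_f: float | None = None) -> "SpeciesCalibration":
        sl = fit_plot_slopes(samples, T_f=T_f).set_index("plot_id")
        order = [p.id for p in plots]
        missing = [pid for pid in order if pid not in sl.index]
        if missing:
            raise ValueError(f"no samples for plot(s) {missing}")
        return cls(sl.loc[order, "slope"].to_numpy(), plots, regime)

    def fit(self, n_starts: int = 24) -> CalibrationResult:
        return solve_species_params(self.slopes, self.plots, self.regime,
                                    n_starts=n_starts)


def generate_calibration_fixture(sp: SpeciesParams, plots, regime: FlowRegime,
                                 noise_sd: float = 0.0, n_times: int = 10,
                                 seed=0) -> pd.DataFrame:
    """Synthetic formative-stage samples for calibration recovery tests.

    Sampling times are evenly spread over (0, T_f]; abundances follow the
    analytic formative law's mean with additive Gaussian noise of standard
    deviation ``noise_sd`` on the logit scale (``noise_sd = 0`` gives exact
    logit-linear samples).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.linspace(sp.T_f / n_times, sp.T_f, n_times)
    c1 = float(logit(sp.eps))
    rows = []
    for p in plots:
        ep = p.eta_prime(regime)
        slope = sp.lam - sp.a_f * (ep ** 2 + regime.sigma ** 2)
        y = c1 + slope * times + noise_sd * rng.standard_normal(n_times)
        for t, n in zip(times, expit(y)):
            rows.append({"plot_id": p.id, "t": float(t), "n": float(n)})
    return pd.DataFrame(rows)
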