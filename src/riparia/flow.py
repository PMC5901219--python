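"""Stochastic flood water-table process.

The water table ``h(t)`` seen by a riparian plot is modelled as a stationary
Gaussian process with mean ``mu``, standard deviation ``sigma`` and
correlation time ``tau_h``.  ``tau_h > 0`` gives an Ornstein--Uhlenbeck (O-U)
process with rate ``alpha = 1/tau_h``; ``tau_h = 0`` encodes the
white-Gaussian-noise (W.G.N.) limit, i.e. fluctuation much faster than the
vegetation it drives.  Nonstationary flow regimes are approximated by a
sequence of stationary segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FlowRegime",
    "SegmentedRegime",
    "FlowSeries",
    "NormalityTest",
    "sample_water_table",
    "estimate_regime",
    "gaussian_fit_test",
    "make_drifting_regime",
]

#: relative tolerance for the uniform-grid check on time series
_GRID_RTOL = 1e-9


@dataclass(frozen=True)
class FlowRegime:
    """Stationary water-table statistics for one time segment.

    Parameters
    ----------
    mu : float
        Mean water level (m).
    sigma : float
        Standard deviation of the level (m).  ``sigma = 0`` is the
        deterministic (noise-off) degenerate case, useful for limit checks.
    tau_h : float
        Correlation time (yr); ``0`` encodes the white-noise limit.
    """

    mu: float
    sigma: float
    tau_h: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma >= 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not self.tau_h >= 0:
            raise ValueError(f"tau_h must be >= 0, got {self.tau_h}")

    @property
    def alpha(self) -> float:
        """O-U relaxation rate 1/tau_h (1/yr); defined only for tau_h > 0."""
        if self.tau_h <= 0:
            raise ValueError("alpha is defined only for tau_h > 0 (O-U regime)")
        return 1.0 / self.tau_h

    def eta_prime(self, eta: float) -> float:
        """Divergence mu - eta of the mean level from a favorable level."""
        return self.mu - eta

    @classmethod
    def from_series(cls, series: "FlowSeries", **kwargs) -> "FlowRegime":
        """Estimate (mu, sigma, tau_h) from a hydrology record."""
        return estimate_regime(series, **kwargs)


@dataclass(frozen=True)
class SegmentedRegime:
    """Piecewise-stationary flow regime: ordered (t_start, t_end, FlowRegime).

    Segments must be contiguous and non-overlapping; together they cover
    ``[t_start of first, t_end of last)``.
    """

    segments: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b), r) for a, b, r in self.segments)
        if not segs:
            raise ValueError("SegmentedRegime needs at least one segment")
        for a, b, r in segs:
            if not a < b:
                raise ValueError(f"segment ({a}, {b}) must have t_start < t_end")
            if not isinstance(r, FlowRegime):
                raise TypeError("third element of each segment must be a FlowRegime")
        for (a0, b0, _), (a1, _, _) in zip(segs, segs[1:]):
            if not math.isclose(b0, a1, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(f"segments not contiguous at t={b0} vs {a1}")
        object.__setattr__(self, "segments", segs)

    @property
    def t_start(self) -> float:
        return self.segments[0][0]

    @property
    def t_end(self) -> float:
        return self.segments[-1][1]

    def covers(self, t0: float, t1: float) -> bool:
        return self.t_start <= t0 and t1 <= self.t_end + 1e-12

    def regime_at(self, t: float) -> FlowRegime:
        """The stationary segment active at time ``t`` (right-open intervals)."""
        if not self.t_start <= t <= self.t_end + 1e-12:
            raise ValueError(f"t={t} outside segmented horizon "
                             f"[{self.t_start}, {self.t_end}]")
        for a, b, r in self.segments:
            if t < b:
                return r
        return self.segments[-1][2]


@dataclass(frozen=True)
class FlowSeries:
    """Uniformly sampled water-level record (times in yr, levels in m)."""

    times: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.levels, dtype=float)
        if t.ndim != 1 or h.ndim != 1 or t.size != h.size:
            raise ValueError("times and levels must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("a FlowSeries needs at least 2 points")
        steps = np.diff(t)
        if steps[0] <= 0 or not np.allclose(steps, steps[0],
                                            rtol=_GRID_RTOL, atol=0.0):
            raise ValueError("time grid must be uniform and increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "levels", h)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size


class NormalityTest(NamedTuple):
    """Result of the Gaussian goodness-of-fit test on water levels."""

    statistic: float
    pvalue: float
    method: str


def _check_uniform_grid(tgrid: np.ndarray) -> np.ndarray:
    t = np.asarray(tgrid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be 1-D with at least 2 points")
    d = np.diff(t)
    if d[0] <= 0 or not np.allclose(d, d[0], rtol=_GRID_RTOL, atol=0.0):
        raise ValueError("time grid must be uniform and increasing")
    return t


def sample_water_table(regime: FlowRegime, tgrid: Sequence[float],
                       seed) -> FlowSeries:
    """Draw one water-table realization on a uniform time grid.

    For ``tau_h > 0`` the exact stationary O-U update is used,

    ``h_{k+1} = mu + (h_k - mu) e^{-alpha dt} + sigma sqrt(1 - e^{-2 alpha dt}) Z_k``

    with ``h_0`` drawn from the stationary law N(mu, sigma^2).  For
    ``tau_h = 0`` the levels are i.i.d. N(mu, sigma^2) per grid point — a
    discrete stand-in for white Gaussian noise, intended for visualisation
    and estimation fixtures only.  ``sigma = 0`` degenerates to the constant
    level ``mu``.  Identical ``(regime, tgrid, seed)`` give identical output.
    """
    t = _check_uniform_grid(tgrid)
    if regime.sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    n = t.size
    if regime.sigma == 0.0:
        return FlowSeries(t, np.full(n, regime.mu))
    if regime.tau_h == 0.0:
        h = regime.mu + regime.sigma * rng.standard_normal(n)
        return FlowSeries(t, h)
    dt = float(t[1] - t[0])
    rho = math.exp(-regime.alpha * dt)
    innov_sd = regime.sigma * math.sqrt(max(0.0, 1.0 - rho * rho))
    z = rng.standard_normal(n)
    h = np.empty(n)
    h[0] = regime.mu + regime.sigma * z[0]
    for k in range(1, n):
        h[k] = regime.mu + (h[k - 1] - regime.mu) * rho + innov_sd * z[k]
    return FlowSeries(t, h)


def estimate_regime(series: FlowSeries, max_lag: int | None = None,
                    min_points: int = 50) -> FlowRegime:
    """Estimate (mu, sigma, tau_h) from a uniformly sampled level record.

    mu-hat and sigma-hat are the sample mean and standard deviation.  The
    correlation time is fitted by a through-origin log-linear regression of
    the empirical autocorrelation ``log rho_L ~ -(L dt)/tau`` over lags up to
    the first non-positive autocorrelation (at most ``max_lag``); if the
    lag-1 autocorrelation is non-positive, ``tau_h`` is clamped to 0
    (white-noise limit).
    """
    from statsmodels.tsa.stattools import acf

    h = series.levels
    if len(series) < min_points:
        raise ValueError(f"need at least {min_points} points to estimate a "
                         f"regime, got {len(series)}")
    mu = float(np.mean(h))
    sd = float(np.std(h, ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mu)):
        raise ValueError("constant series: regime parameters are not identifiable")
    nlags = max_lag if max_lag is not None else min(100, len(series) // 10)
    nlags = max(1, min(nlags, len(series) - 2))
    rho = acf(h, nlags=nlags, fft=True)
    if rho[1] <= 0:
        return FlowRegime(mu=mu, sigma=sd, tau_h=0.0)
    # initial run of strictly positive autocorrelations
    pos_end = 1
    while pos_end < len(rho) and rho[pos_end] > 0:
        pos_end += 1
    lags = np.arange(1, pos_end) * series.dt
    logr = np.log(rho[1:pos_end])
    # through-origin log-linear fit log rho = -lag/tau, weighted by rho^2 so
    # the noisy small-autocorrelation tail does not bias tau upward
    w = rho[1:pos_end] ** 2
    beta = -float(np.dot(w * lags, logr) / np.dot(w * lags, lags))
    tau = 1.0 / beta if beta > 0 else 0.0
    return FlowRegime(mu=mu, sigma=sd, tau_h=tau)


def gaussian_fit_test(series: FlowSeries) -> NormalityTest:
    """Omnibus Gaussianity test of the level values.

    Uses the D'Agostino--Pearson K^2 statistic (skewness + kurtosis); the
    choice of test is recorded in the result's ``method`` field.
    """
    h = series.levels
    if h.size < 20:
        raise ValueError("need at least 20 points for the normality test")
    if np.std(h) == 0.0:
        raise ValueError("zero-variance series: normality test undefined")
    stat, p = stats.normaltest(h)
    return NormalityTest(float(stat), float(p), "dagostino-pearson-k2")


def make_drifting_regime(base: FlowRegime, mean_amplitude: float,
                         sd_amplitude: float, period: float, horizon: float,
                         n_segments: int) -> SegmentedRegime:
    """Piecewise-stationary approximation of a sinusoidally drifting regime.

    Segment ``k`` (equal widths over ``[0, horizon]``) takes

    ``mu_k = mu + mean_amplitude * sin(2 pi t_k / period)``,
    ``sigma_k = sigma + sd_amplitude * sin(2 pi t_k / period)``,

    evaluated at the segment midpoint ``t_k``.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if period <= 0 or horizon <= 0:
        raise ValueError("period and horizon must be positive")
    if sd_amplitude >= base.sigma and sd_amplitude > 0:
        raise ValueError("sd_amplitude must be smaller than sigma "
                         "(would produce a non-positive segment sigma)")
    edges = np.linspace(0.0, horizon, n_segments + 1)
    segs = []
    for a, b in zip(edges[:-1], edges[1:]):
        tm = 0.5 * (a + b)
        phase = math.sin(2.0 * math.pi * tm / period)
        segs.append((float(a), float(b),
                     FlowRegime(mu=base.mu + mean_amplitude * phase,
                                sigma=base.sigma + sd_amplitude * phase,
                                tau_h=base.tau_h)))
    return SegmentedRegime(tuple(segs))
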