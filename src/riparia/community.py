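"""Multi-cohort age-structure simulation.

Every year each plot germinates one new same-aged cohort at abundance
``eps``; cohorts then evolve independently on their own age clocks
(formative up to age ``T_f``, decline with ``a_d(age)`` after) under the
shared, possibly piecewise-stationary, flow regime.  A cohort is removed
once its (ensemble-mean) abundance drops below ``n_e``.  There is no
inter-cohort competition: plot totals are plain sums over living cohorts
and are reported in "cohort units" (they may exceed 1).

Cross-plot noise draws are independent; within a plot all cohorts see the
same regime segment in any year.  Only white-noise segments (``tau_h = 0``)
are supported here — the multi-annual community clock sits far above the
intermonthly water-table fluctuation, which is the regime in which the
white-noise treatment of the decline stage is justified in the first place.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .flow import FlowRegime, SegmentedRegime
from .species import SpeciesParams, sensitivity

__all__ = ["AgeStructureRecord", "AgeStructureSummary", "simulate_community",
           "age_structure_summary", "suitability_signal",
           "cross_correlation_lag", "abundance_suitability_lag"]

_LOG_FLOOR = math.log(1e-300)


@dataclass
class AgeStructureRecord:
    """Per-plot cohort bookkeeping over the simulation horizon.

    ``abundance[plot_id]`` is a (years, years) matrix: row ``y-1`` holds the
    end-of-year-``y`` abundance of each cohort indexed by birth year (0 for
    unborn or extinct cohorts).  Totals are exact row sums.
    """

    plot_ids: list
    years: np.ndarray
    birth_years: np.ndarray
    abundance: dict
    regime_trace: pd.DataFrame
    seed: int

    def totals(self) -> pd.DataFrame:
        rows = []
        for pid in self.plot_ids:
            tot = self.abundance[pid].sum(axis=1)
            for y, v in zip(self.years, tot):
                rows.append({"plot_id": pid, "year": int(y),
                             "total_abundance": float(v)})
        return pd.DataFrame(rows)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for pid in self.plot_ids:
            mat = self.abundance[pid]
            for i, y in enumerate(self.years):
                for j, b in enumerate(self.birth_years):
                    if mat[i, j] > 0:
                        rows.append({"plot_id": pid, "year": int(y),
                                     "cohort_birth_year": int(b),
                                     "abundance": float(mat[i, j])})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AgeStructureSummary:
    """Cohort-age abundance shares of one plot in one calendar year."""

    year: int
    ages: np.ndarray
    shares: np.ndarray
    evenness: float
    empty: bool


def _as_segmented(regime, years: float) -> SegmentedRegime:
    if isinstance(regime, FlowRegime):
        return SegmentedRegime(((0.0, float(years), regime),))
    if isinstance(regime, SegmentedRegime):
        if not regime.covers(0.0, years):
            raise ValueError("segmented regime does not cover the horizon "
                             f"[0, {years}]")
        return regime
    raise TypeError("regime must be a FlowRegime or SegmentedRegime")


def simulate_community(sp: SpeciesParams, plots, regime, years: int, seed=0,
                       paths_per_cohort: int = 100, dt: float = 0.01,
                       germination_years: int | None = None
                       ) -> AgeStructureRecord:
    """Simulate annual cohort recruitment and decay for each plot.

    Each cohort is represented by the mean over ``paths_per_cohort``
    exact transformed-space sample paths (``paths_per_cohort = 1`` gives a
    single stochastic realization).  Deterministic given ``seed``: each
    plot's noise stream is keyed by (seed, plot id), so a plot with the
    same id and favorable level reproduces identically across runs, while
    differently named plots draw independently.

    ``germination_years`` restricts recruitment to the first that many
    years (``None`` germinates every year).
    """
    if years <= 0:
        raise ValueError("years must be positive")
    seg = _as_segmented(regime, years)
    for _, _, r in seg.segments:
        if r.tau_h != 0.0:
            raise NotImplementedError(
                "community simulation supports white-noise segments only "
                "(tau_h = 0); model colored noise at the single-cohort "
                "level with simulate_cohort(mode='ou_pathwise')")
    n_sub = round(1.0 / dt)
    if abs(n_sub * dt - 1.0) > 1e-9 or dt > 0.01 + 1e-12:
        raise ValueError("dt must divide one year and be <= 0.01")
    if abs(sp.T_f / dt - round(sp.T_f / dt)) > 1e-6:
        raise ValueError("T_f must be a multiple of dt for the community "
                         "age clock")

    years = int(years)
    birth_years = np.arange(years)
    year_index = np.arange(1, years + 1)
    sqdt = math.sqrt(dt)
    abundance = {}
    for plot in plots:
        if plot.eta is None:
            raise ValueError(f"plot {plot.id}: eta must be set")
        rng = np.random.default_rng(
            [int(seed), zlib.crc32(str(plot.id).encode())])
        mat = np.zeros((years, years))
        state = np.zeros((0, paths_per_cohort))  # transformed abundance
        formative = np.zeros(0, dtype=bool)
        births: list[int] = []
        alive = np.zeros(0, dtype=bool)
        for y in range(years):
            # annual germination: one new cohort at n = eps
            if germination_years is None or y < germination_years:
                births.append(y)
                state = np.vstack([state,
                                   np.full((1, paths_per_cohort),
                                           float(logit(sp.eps)))])
                formative = np.append(formative, True)
                alive = np.append(alive, True)
            barr = np.asarray(births, dtype=float)
            for j in range(n_sub):
                tt = y + j * dt
                r = seg.regime_at(min(tt, seg.t_end - 1e-9))
                ep = r.mu - plot.eta
                M = ep * ep + r.sigma * r.sigma
                absS = abs(ep * r.sigma)
                live = np.nonzero(alive)[0]
                if live.size == 0:
                    continue
                age = tt - barr[live]
                conv = formative[live] & (age >= sp.T_f - 1e-9)
                if conv.any():
                    rows = live[conv]
                    state[rows] = -np.logaddexp(0.0, -state[rows])
                    formative[rows] = False
                z = rng.standard_normal((live.size, paths_per_cohort))
                fm = formative[live]
                if fm.any():
                    rows = live[fm]
                    state[rows] += ((sp.lam - sp.a_f * M) * dt
                                    + 2.0 * sp.a_f * absS * sqdt * z[fm])
                dc = ~fm
                if dc.any():
                    rows = live[dc]
                    ad = sensitivity(np.maximum(age[dc], sp.T_f), sp)
                    drift = (-ad * M * dt)[:, None]
                    diff = (2.0 * absS * np.abs(ad) * sqdt)[:, None]
                    state[rows] = np.clip(state[rows] + drift
                                          + diff * z[dc], _LOG_FLOOR, 0.0)
            # end-of-year bookkeeping
            live = np.nonzero(alive)[0]
            for idx in live:
                vals = (expit(state[idx]) if formative[idx]
                        else np.exp(state[idx]))
                m = float(np.mean(vals))
                if m < sp.n_e:
                    alive[idx] = False
                else:
                    mat[y, births[idx]] = m
        abundance[plot.id] = mat

    trace_rows = []
    for y in year_index:
        r = seg.regime_at(min(y - 0.5, seg.t_end - 1e-9))
        trace_rows.append({"year": int(y), "mu": r.mu, "sigma": r.sigma,
                           "tau_h": r.tau_h})
    return AgeStructureRecord(plot_ids=[p.id for p in plots],
                              years=year_index, birth_years=birth_years,
                              abundance=abundance,
                              regime_trace=pd.DataFrame(trace_rows),
                              seed=int(seed))


def age_structure_summary(record: AgeStructureRecord, plot_id,
                          year: int) -> AgeStructureSummary:
    """Abundance share by cohort age, with a normalized-entropy evenness.

    Evenness is Shannon entropy of the shares divided by ``ln(k)`` over the
    ``k`` living cohorts (0 for a single cohort, 1 for equal shares).
    """
    if year not in record.years:
        raise ValueError(f"year {year} outside the record horizon")
    row = record.abundance[plot_id][int(year) - 1]
    mask = row > 0
    total = float(row.sum())
    if total == 0.0:
        return AgeStructureSummary(year=int(year), ages=np.array([]),
                                   shares=np.array([]), evenness=0.0,
                                   empty=True)
    ages = (year - record.birth_years[mask]).astype(float)
    shares = row[mask] / total
    k = shares.size
    if k == 1:
        evenness = 0.0
    else:
        evenness = float(-(shares * np.log(shares)).sum() / math.log(k))
    order = np.argsort(ages)
    return AgeStructureSummary(year=int(year), ages=ages[order],
                               shares=shares[order], evenness=evenness,
                               empty=False)


def suitability_signal(regime, eta: float, years: int) -> np.ndarray:
    """Yearly flow-suitability signal -(mu(t) - eta)^2 at year midpoints."""
    seg = _as_segmented(regime, years)
    out = np.empty(int(years))
    for y in range(int(years)):
        r = seg.regime_at(min(y + 0.5, seg.t_end - 1e-9))
        out[y] = -((r.mu - eta) ** 2)
    return out


def abundance_suitability_lag(record: AgeStructureRecord, plot_id,
                              regime, eta: float, max_lag: int = 15,
                              detrend: bool = True) -> int:
    """Years by which a plot's total abundance trails its flow suitability.

    Annual recruitment with multi-decade lifespans makes the total ramp
    roughly linearly over the horizon; both series are linearly detrended
    by default so the cross-correlation sees the fluctuation response, not
    the accumulation trend.
    """
    tot = record.abundance[plot_id].sum(axis=1)
    suit = suitability_signal(regime, eta, record.years.size)
    if detrend:
        x = np.arange(tot.size)
        tot = tot - np.polyval(np.polyfit(x, tot, 1), x)
        suit = suit - np.polyval(np.polyfit(x, suit, 1), x)
    return cross_correlation_lag(tot, suit, max_lag)


def cross_correlation_lag(response, driver, max_lag: int) -> int:
    """Lag (in samples) at which corr(response[t], driver[t - lag]) peaks.

    Both series are standardized; only non-negative lags are scanned.  A
    strictly positive result means the response trails the driver.
    """
    a = np.asarray(response, dtype=float)
    b = np.asarray(driver, dtype=float)
    if a.size != b.size:
        raise ValueError("series must share a length")
    best_lag, best_c = 0, -np.inf
    for lag in range(0, max_lag + 1):
        x = a[lag:]
        y = b[:b.size - lag] if lag else b
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            continue
        c = float(np.corrcoef(x, y)[0, 1])
        if c > best_c:
            best_c, best_lag = c, lag
    return best_lag
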