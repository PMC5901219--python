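"""Monte-Carlo integration of the stochastic cohort dynamics.

Two first-class modes:

``wgn_exact``
    Realizes the white-noise solution process exactly in transformed space:
    additive-noise Gaussian updates of ``logit n`` (formative) and ``log n``
    (decline, with the sensitivity a_d frozen per step).  Because the noise
    is additive after the transform, the Stratonovich and Ito readings
    coincide and no Milstein-type correction is needed.

``ou_pathwise``
    Samples a literal Ornstein--Uhlenbeck water-table path and integrates
    the random ODE ``d logit n / dt = lambda - a_f (eta'^2 + h'^2 +
    2 eta' h')`` by cumulative trapezoid (second order in dt).  This is the
    formula-free oracle for the colored-noise variance terms: it makes no
    use of the V1+V2+V3 formula it is meant to check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .flow import FlowRegime, SegmentedRegime
from .species import SpeciesParams, sensitivity

__all__ = ["Ensemble", "FirstPassage", "simulate_cohort", "stopping_times"]

#: floor for n in transformed space (log n >= log(1e-300))
_LOG_FLOOR = math.log(1e-300)


@dataclass
class Ensemble:
    """Trajectory matrix of a simulated cohort.

    ``n`` has shape ``(len(t), n_paths)`` with all entries in (0, 1];
    identical inputs and seed reproduce the ensemble bit for bit.
    """

    t: np.ndarray
    n: np.ndarray
    seed: int
    mode: str
    species: SpeciesParams
    eta: float
    meta: dict = field(default_factory=dict)

    @property
    def n_paths(self) -> int:
        return self.n.shape[1]


@dataclass(frozen=True)
class FirstPassage:
    """Per-path first-passage (extinction) times below a threshold.

    ``times`` holds the first recorded time with ``n < threshold``; censored
    paths (no crossing within the horizon) carry the horizon time and are
    flagged in ``censored``.
    """

    times: np.ndarray
    censored: np.ndarray
    threshold: float

    @property
    def censored_fraction(self) -> float:
        return float(np.mean(self.censored))


def _regime_lookup(regime, eta):
    """Return a function t -> (eta_prime, sigma, tau_h) valid at time t."""
    if isinstance(regime, FlowRegime):
        trip = (regime.mu - eta, regime.sigma, regime.tau_h)
        return lambda t: trip
    if isinstance(regime, SegmentedRegime):
        def lookup(t):
            r = regime.regime_at(t)
            return (r.mu - eta, r.sigma, r.tau_h)
        return lookup
    raise TypeError("regime must be a FlowRegime or SegmentedRegime")


def _check_tgrid(tgrid, regime) -> tuple[np.ndarray, float]:
    t = np.asarray(tgrid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("tgrid must be 1-D with at least 2 points")
    if abs(t[0]) > 1e-12:
        raise ValueError("tgrid must start at 0 (cohort germination)")
    d = np.diff(t)
    if d[0] <= 0 or not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
        raise ValueError("tgrid must be uniform and increasing")
    dt = float(d[0])
    regimes = ([regime] if isinstance(regime, FlowRegime)
               else [r for _, _, r in regime.segments])
    for r in regimes:
        limit = 0.01 * min(1.0, r.tau_h) if r.tau_h > 0 else 0.01
        if dt > limit * (1.0 + 1e-9):
            raise ValueError(
                f"grid step {dt} too coarse: need dt <= {limit} "
                f"(0.01 * min(1, tau_h) with tau_h={r.tau_h})")
    return t, dt


def _sample_ou_deviation(sigma_tau, tgrid, rng, n_paths):
    """O-U deviation paths h'(t), shape (len(tgrid), n_paths).

    ``sigma_tau`` maps t -> (sigma, tau_h); parameters may switch at segment
    boundaries, in which case the recursion continues from the running
    deviation (no re-draw), rescaled to the new stationary spread.
    """
    nt = tgrid.size
    dt = float(tgrid[1] - tgrid[0])
    h = np.empty((nt, n_paths))
    sig0, tau0 = sigma_tau(tgrid[0])
    if tau0 <= 0:
        raise ValueError("ou_pathwise requires tau_h > 0 in every segment")
    h[0] = sig0 * rng.standard_normal(n_paths)
    prev_sig = sig0
    for k in range(1, nt):
        sig, tau = sigma_tau(tgrid[k - 1])
        if tau <= 0:
            raise ValueError("ou_pathwise requires tau_h > 0 in every segment")
        if sig != prev_sig:
            h[k - 1] = h[k - 1] * (sig / prev_sig)
            prev_sig = sig
        rho = math.exp(-dt / tau)
        innov = sig * math.sqrt(1.0 - rho * rho)
        h[k] = h[k - 1] * rho + innov * rng.standard_normal(n_paths)
    return h


def simulate_cohort(sp: SpeciesParams, regime, eta: float, tgrid,
                    n_paths: int, seed, mode: str = "wgn_exact",
                    record_stride: int = 1) -> Ensemble:
    """Simulate a same-aged cohort from germination (n(0) = eps).

    Parameters
    ----------
    regime : FlowRegime or SegmentedRegime
        Flow forcing; segment parameters are looked up at the left end of
        each step and the divergence ``eta' = mu - eta`` is recomputed per
        segment.
    tgrid : array
        Uniform grid starting at 0 with step ``dt <= 0.01 * min(1, tau_h)``
        (``0.01`` yr in the white-noise case).
    mode : {"wgn_exact", "ou_pathwise"}
        See the module docstring.
    record_stride : int
        Keep every ``record_stride``-th grid point (plus the last) in the
        returned ensemble; the dynamics always run at the full grid.
    """
    t, dt = _check_tgrid(tgrid, regime)
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    if record_stride < 1:
        raise ValueError("record_stride must be >= 1")
    lookup = _regime_lookup(regime, eta)
    rng = np.random.default_rng(seed)

    keep = np.arange(0, t.size, record_stride)
    if keep[-1] != t.size - 1:
        keep = np.append(keep, t.size - 1)
    keep_set = {int(k): i for i, k in enumerate(keep)}
    out = np.empty((keep.size, n_paths))

    if mode == "wgn_exact":
        _run_wgn(sp, lookup, t, dt, n_paths, rng, keep_set, out)
    elif mode == "ou_pathwise":
        _run_ou(sp, lookup, t, n_paths, rng, keep_set, out)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return Ensemble(t=t[keep], n=out, seed=seed, mode=mode, species=sp,
                    eta=eta, meta={"record_stride": record_stride,
                                   "dt": dt, "regime": regime})


def _record(out, keep_set, k, y, stage):
    i = keep_set.get(k)
    if i is not None:
        out[i] = expit(y) if stage == "formative" else np.exp(y)


def _run_wgn(sp, lookup, t, dt, n_paths, rng, keep_set, out) -> None:
    y = np.full(n_paths, float(logit(sp.eps)))
    stage = "formative"
    sqdt = math.sqrt(dt)
    _record(out, keep_set, 0, y, stage)
    for k in range(t.size - 1):
        tk, tk1 = t[k], t[k + 1]
        ep, sig, _ = lookup(tk)
        M = ep * ep + sig * sig
        absS = abs(ep * sig)
        z = rng.standard_normal(n_paths)
        if stage == "formative" and tk1 <= sp.T_f + 1e-12:
            y += (sp.lam - sp.a_f * M) * dt + 2.0 * sp.a_f * absS * sqdt * z
        elif stage == "formative":
            # step straddles the stage boundary: split at T_f
            d1 = sp.T_f - tk
            if d1 > 0:
                z1 = z
                y += ((sp.lam - sp.a_f * M) * d1
                      + 2.0 * sp.a_f * absS * math.sqrt(d1) * z1)
                z = rng.standard_normal(n_paths)
            y = -np.logaddexp(0.0, -y)  # log n = log(invlogit(logit n))
            stage = "decline"
            d2 = tk1 - sp.T_f
            if d2 > 0:
                ad = sensitivity(sp.T_f, sp)
                y += -ad * M * d2 + 2.0 * absS * abs(ad) * math.sqrt(d2) * z
            np.clip(y, _LOG_FLOOR, 0.0, out=y)
        else:
            ad = sensitivity(tk, sp)
            y += -ad * M * dt + 2.0 * absS * abs(ad) * sqdt * z
            np.clip(y, _LOG_FLOOR, 0.0, out=y)
        if stage == "formative" and abs(tk1 - sp.T_f) <= 1e-12:
            y = -np.logaddexp(0.0, -y)
            stage = "decline"
        _record(out, keep_set, k + 1, y, stage)


def _run_ou(sp, lookup, t, n_paths, rng, keep_set, out) -> None:
    ep_sig_tau = lookup
    h = _sample_ou_deviation(lambda s: ep_sig_tau(s)[1:], t, rng, n_paths)
    dt = float(t[1] - t[0])
    eta_p = np.array([ep_sig_tau(s)[0] for s in t])[:, None]
    if t[-1] > sp.T_f + 1e-12:
        k_f = int(np.argmin(np.abs(t - sp.T_f)))
        if abs(t[k_f] - sp.T_f) > 1e-9:
            raise ValueError("ou_pathwise requires T_f on the time grid when "
                             "the horizon crosses the stage boundary")
    else:
        k_f = t.size - 1
    # formative: d logit n / dt = lam - a_f (eta'^2 + h'^2 + 2 eta' h')
    quad = eta_p ** 2 + h ** 2 + 2.0 * eta_p * h
    f = sp.lam - sp.a_f * quad[:k_f + 1]
    y = float(logit(sp.eps)) + np.concatenate(
        [np.zeros((1, n_paths)),
         np.cumsum(0.5 * (f[1:] + f[:-1]) * dt, axis=0)])
    for k in range(k_f + 1):
        i = keep_set.get(k)
        if i is not None:
            out[i] = expit(y[k])
    if k_f == t.size - 1:
        return
    # decline: d log n / dt = -a_d(t) (eta'^2 + h'^2 + 2 eta' h')
    ad = sensitivity(np.maximum(t[k_f:], sp.T_f), sp)[:, None]
    g = -ad * quad[k_f:]
    ylog = (-np.logaddexp(0.0, -y[k_f])) + np.concatenate(
        [np.zeros((1, n_paths)),
         np.cumsum(0.5 * (g[1:] + g[:-1]) * dt, axis=0)])
    np.clip(ylog, _LOG_FLOOR, 0.0, out=ylog)
    for k in range(k_f, t.size):
        i = keep_set.get(k)
        if i is not None:
            out[i] = np.exp(ylog[k - k_f])


def stopping_times(ens: Ensemble, n_e: float) -> FirstPassage:
    """First recorded time t > 0 with n(t) < n_e, per path.

    Crossing detection is at the recorded grid resolution (no bridge
    correction); paths that never cross are censored at the horizon.
    """
    if not n_e < ens.species.eps:
        raise ValueError("extinction threshold n_e must be below the initial "
                         f"abundance eps={ens.species.eps}")
    below = ens.n[1:] < n_e  # exclude t = 0
    crossed = below.any(axis=0)
    first = below.argmax(axis=0) + 1
    times = np.where(crossed, ens.t[np.minimum(first, ens.t.size - 1)],
                     ens.t[-1])
    return FirstPassage(times=times, censored=~crossed, threshold=float(n_e))
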