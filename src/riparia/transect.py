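"""Spatial patterns along the riparian transect.

Moving away from the channel the ground surface rises, so the divergence
``eta'(x) = mu - eta(x)`` declines, while soil and the capillary fringe
damp the water-table fluctuation, so ``sigma(x)`` declines too.  The stock
profiles use a logarithmic divergence gradient

    eta'(x) = eta'(0) + k * ln(1 + x / x0),    k < 0,

with three gradient strengths (slow / moderate / rapid water-table decline
with distance) and a linearly decreasing, floored sigma:

    sigma(x) = max(sigma(0) - s * x, sigma_min).

Because mean abundance and lifespan both peak at eta' = 0 and decrease with
sigma, the three gradients generate the three canonical cross-transect
patterns: monotonically increasing; peaked then flat; peaked then rapidly
declining.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analytic import mean_abundance
from .lifespan import mean_lifespan
from .species import SpeciesParams

__all__ = ["TransectProfile", "make_profiles", "spatial_pattern",
           "classify_pattern", "STOCK_GRADIENTS"]

#: gradient coefficient k (m per log-distance) of the three stock profiles
STOCK_GRADIENTS = {"slow": -0.55, "moderate": -1.1, "rapid": -1.6}


@dataclass(frozen=True)
class TransectProfile:
    """Divergence and deviation profiles along the transect."""

    x: np.ndarray
    eta_prime: np.ndarray
    sigma: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("sigma(x) must be positive everywhere")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "eta_prime",
                           np.asarray(self.eta_prime, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))


def make_profiles(kind: str, x_grid=None, *, eta_prime_0: float = 2.0,
                  k: float | None = None, x0: float = 50.0,
                  sigma_0: float = 0.6, slope: float = 0.001,
                  sigma_min: float = 0.15) -> TransectProfile:
    """Build a transect profile of one of the three stock kinds.

    ``kind`` selects the gradient coefficient from :data:`STOCK_GRADIENTS`
    unless ``k`` overrides it.  Defaults span x in [0, 500] m.
    """
    if sigma_min <= 0:
        raise ValueError("sigma_min must be > 0")
    if k is None:
        try:
            k = STOCK_GRADIENTS[kind]
        except KeyError:
            raise ValueError(f"unknown profile kind {kind!r}; expected one of "
                             f"{sorted(STOCK_GRADIENTS)} or an explicit k")
    x = (np.arange(0.0, 501.0, 10.0) if x_grid is None
         else np.asarray(x_grid, dtype=float))
    eta_prime = eta_prime_0 + k * np.log1p(x / x0)
    sigma = np.maximum(sigma_0 - slope * x, sigma_min)
    return TransectProfile(x=x, eta_prime=eta_prime, sigma=sigma, kind=kind)


def spatial_pattern(profile: TransectProfile, sp: SpeciesParams,
                    tau_h: float = 0.0,
                    t_eval: float | None = None) -> pd.DataFrame:
    """Mean abundance at t_eval (default T_f) and mean lifespan along x."""
    t_eval = sp.T_f if t_eval is None else t_eval
    if t_eval > sp.T_f:
        raise ValueError("the abundance column is evaluated within the "
                         f"formative stage (t_eval <= T_f={sp.T_f})")
    rows = []
    for x, ep, sig in zip(profile.x, profile.eta_prime, profile.sigma):
        rows.append({
            "x": float(x),
            "eta_prime": float(ep),
            "sigma": float(sig),
            "mean_abundance": mean_abundance(t_eval, sp, float(ep),
                                             float(sig), tau_h),
            "lifespan": mean_lifespan(sp, float(ep), float(sig), tau_h),
        })
    return pd.DataFrame(rows)


def classify_pattern(values, rho_tol: float = 0.02,
                     theta: float = 0.3) -> str:
    """Classify a cross-transect curve into one of three patterns.

    ``monotonic_increasing`` if the maximum drawdown never exceeds
    ``rho_tol`` of the curve's range; otherwise the curve is peaked, and the
    post-peak drop relative to the rise splits ``peaked_flat`` (< ``theta``)
    from ``peaked_rapid_decline``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 points to classify a pattern")
    rng = float(v.max() - v.min())
    if rng == 0.0:
        return "monotonic_increasing"
    drawdown = float(np.max(np.maximum.accumulate(v) - v))
    if drawdown <= rho_tol * rng:
        return "monotonic_increasing"
    peak = int(np.argmax(v))
    rise = float(v[peak] - v[0])
    drop = float(v[peak] - v[peak:].min())
    if rise <= 0:  # never rose: treat the full drawdown as the drop
        return "peaked_rapid_decline"
    return "peaked_flat" if drop < theta * rise else "peaked_rapid_decline"
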