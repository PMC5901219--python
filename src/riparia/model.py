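"""Mechanistic model object for a single same-aged cohort.

``CohortModel`` bundles a species, a flow regime and a plot's favorable
level, and exposes the analytic laws, Monte-Carlo simulation and lifespan
calculations through one object, so a typical session reads::

    sp = SpeciesParams.birch()
    m = CohortModel(sp, FlowRegime(mu=82.8, sigma=0.58), eta=83.03)
    m.moments(1.0).mean          # mean of logit n at the stage boundary
    m.mean_lifespan()            # average lifespan <Td> (yr)
    ens = m.simulate(t_max=1.0, n_paths=10_000, seed=1)
"""

from __future__ import annotations

import numpy as np

from . import analytic, lifespan as _lifespan
from .flow import FlowRegime
from .simulate import Ensemble, simulate_cohort, stopping_times
from .species import SpeciesParams

__all__ = ["CohortModel"]


class CohortModel:
    """A same-aged cohort at one plot under one stationary flow regime."""

    def __init__(self, species: SpeciesParams, regime: FlowRegime,
                 eta: float):
        if not isinstance(regime, FlowRegime):
            raise TypeError("CohortModel takes a stationary FlowRegime; use "
                            "simulate_cohort / simulate_community directly "
                            "for segmented regimes")
        self.species = species
        self.regime = regime
        self.eta = float(eta)

    @property
    def eta_prime(self) -> float:
        """Divergence mu - eta of the mean water level (m)."""
        return self.regime.mu - self.eta

    @property
    def M(self) -> float:
        return self.eta_prime ** 2 + self.regime.sigma ** 2

    @property
    def Sigma(self) -> float:
        return self.eta_prime * self.regime.sigma

    def moments(self, t: float) -> analytic.StageMoments:
        return analytic.stage_moments(t, self.species, self.eta_prime,
                                      self.regime.sigma, self.regime.tau_h)

    def continuity_constant(self) -> float:
        return analytic.continuity_constant(self.species, self.eta_prime,
                                            self.regime.sigma,
                                            self.regime.tau_h)

    def pdf(self, n, t: float):
        return analytic.abundance_pdf(n, self.moments(t))

    def mean_abundance(self, t: float) -> float:
        return analytic.mean_abundance(t, self.species, self.eta_prime,
                                       self.regime.sigma, self.regime.tau_h)

    def mean_lifespan(self, n_e: float | None = None) -> float:
        return _lifespan.mean_lifespan(self.species, self.eta_prime,
                                       self.regime.sigma, self.regime.tau_h,
                                       n_e=n_e)

    def simulate(self, t_max: float, n_paths: int, seed,
                 dt: float = 0.01, mode: str | None = None,
                 record_stride: int = 1) -> Ensemble:
        if mode is None:
            mode = "wgn_exact" if self.regime.tau_h == 0 else "ou_pathwise"
        tgrid = np.arange(0.0, t_max + dt / 2, dt)
        return simulate_cohort(self.species, self.regime, self.eta, tgrid,
                               n_paths, seed, mode=mode,
                               record_stride=record_stride)

    def lifespan_mc(self, n_paths: int = 1000, seed=0,
                    horizon: float = 300.0,
                    n_e: float | None = None) -> _lifespan.LifespanMC:
        return _lifespan.lifespan_mc(self.species, self.eta_prime,
                                     self.regime.sigma, self.regime.tau_h,
                                     n_paths=n_paths, seed=seed,
                                     horizon=horizon, n_e=n_e)

    def first_passage(self, ens: Ensemble, n_e: float | None = None):
        n_e = self.species.n_e if n_e is None else n_e
        return stopping_times(ens, n_e)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"CohortModel(eta={self.eta}, eta_prime={self.eta_prime:.3g},"
                f" mu={self.regime.mu}, sigma={self.regime.sigma},"
                f" tau_h={self.regime.tau_h})")
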