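import numpy as np
import pytest

from riparia import FlowRegime, PlotSite, SpeciesParams
from riparia.model import CohortModel

#: favorable levels of the three calibrated birch plots (m)
BIRCH_ETAS = (83.03, 83.97, 84.67)


@pytest.fixture(scope="session")
def birch() -> SpeciesParams:
    """Calibrated white-birch parameter set (lam=3.24, a_f=0.49, ...)."""
    return SpeciesParams.birch()


@pytest.fixture(scope="session")
def regime() -> FlowRegime:
    """Stationary white-noise flow regime of the birch transect."""
    return FlowRegime(mu=82.8, sigma=0.58, tau_h=0.0)


@pytest.fixture(scope="session")
def plot1(birch, regime) -> CohortModel:
    """Cohort model at the lowest plot (eta=83.03, eta'=-0.23)."""
    return CohortModel(birch, regime, eta=BIRCH_ETAS[0])


@pytest.fixture(scope="session")
def birch_plots(regime):
    return [PlotSite(f"plot{i + 1}", x=10.0 * (i + 1), altitude=e, eta=e)
            for i, e in enumerate(BIRCH_ETAS)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
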