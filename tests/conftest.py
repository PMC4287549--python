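import numpy as np
import pytest

from bymst.inference import MCMCSettings, fit, sample_posterior
from bymst.model import ModelSpec
from bymst.synthetic_data import recovery_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """30 tracts x 5 years Poisson panel with recorded truth."""
    return recovery_scenario(seed=42, n_tracts=30, n_years=5, pob_mean=1500.0)


@pytest.fixture(scope="session")
def small_fit(small_scenario):
    geometry, panel, _ = small_scenario
    spec = ModelSpec(family="poisson", seed=42)
    settings = MCMCSettings(n_iter=1500, n_burnin=600, thin=1, n_chains=1)
    return fit(panel, geometry, spec, settings), panel, geometry, spec


@pytest.fixture(scope="session")
def small_chains(small_scenario):
    geometry, panel, _ = small_scenario
    spec = ModelSpec(family="poisson", seed=7)
    settings = MCMCSettings(n_iter=3000, n_burnin=1200, thin=1, n_chains=2)
    return sample_posterior(panel, geometry, spec, settings)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
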