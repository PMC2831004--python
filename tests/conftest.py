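import numpy as np
import pytest

from p2net.model import Hyperparameters
from p2net.network_io import Network, network_from_edges
from p2net.sampler import SamplerConfig, run_chains
from p2net.simulate_gof import generate_synthetic_study


@pytest.fixture
def triangle() -> Network:
    return network_from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star5() -> Network:
    return network_from_edges([("H", f"L{i}") for i in range(1, 5)])


@pytest.fixture(scope="session")
def study_nocov():
    """Covariate-free synthetic study with real node heterogeneity."""
    return generate_synthetic_study(n=50, theta=-3.0, gamma=0.0, sigma_a=1.2,
                                    prevalence=0.0, seed=20)


@pytest.fixture(scope="session")
def fit_nocov(study_nocov):
    """A converged 2-chain fit of the covariate-free study, shared across tests."""
    from p2net.network_io import empty_covariates

    cfg = SamplerConfig(burn_in=1000, draws=4000, thin=5, chains=2, seed=21)
    return run_chains(study_nocov.network, empty_covariates(study_nocov.network),
                      Hyperparameters(), cfg)


@pytest.fixture(scope="session")
def study_cov():
    """Synthetic study with a binary covariate of moderate effect."""
    return generate_synthetic_study(n=60, theta=-2.5, gamma=0.7, sigma_a=0.8,
                                    prevalence=0.3, seed=22)


@pytest.fixture(scope="session")
def fit_cov(study_cov):
    cfg = SamplerConfig(burn_in=1000, draws=4000, thin=5, chains=2, seed=23)
    return run_chains(study_cov.network, study_cov.covariates, Hyperparameters(), cfg)
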