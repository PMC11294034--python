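import warnings

import pytest

from goshawkipm import simulate_dataset
from goshawkipm.inference import FitConfig, fit_ipm
from goshawkipm.population_model import DemographicRatesYear

warnings.filterwarnings("ignore", message=".*R-hat above.*")


def random_rates(rng, omega=None):
    """A random valid rate set (kept away from the boundaries)."""
    return DemographicRatesYear(
        s=rng.uniform(0.2, 0.9, (3, 2)),
        eta=rng.uniform(0.3, 0.9, 3),
        rho=rng.uniform(0.8, 3.0, 3),
        xi=rng.uniform(0.3, 0.7, 3),
        alpha=rng.uniform(0.1, 0.9, (2, 2)),
        omega=rng.uniform(0.5, 3.0) if omega is None else omega,
    )


@pytest.fixture(scope="session")
def desk_data():
    """A 15-year goshawk-like data set with its ground truth."""
    return simulate_dataset(seed=7, years=15)


@pytest.fixture(scope="session")
def desk_posterior(desk_data):
    """A short two-chain fit of the desk data, shared across tests."""
    data, _ = desk_data
    cfg = FitConfig.desk(n_chains=2, n_iter=700, n_burnin=250, thin=2, seed=1)
    return fit_ipm(data, cfg)
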