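import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from atherotrend import PriorSpec, sample_posterior
from atherotrend.cohort import CohortConfig, simulate_cohort

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_cohort():
    """One study-shaped synthetic cohort (4 diets, 6/6/6/3 mice, weeks 0-10)."""
    config = CohortConfig(seed=5)
    truth, table = simulate_cohort(config)
    return config, truth, table


@pytest.fixture(scope="session")
def fitted_study(study_cohort):
    """A converged fit of the study cohort, shared across tests."""
    _, truth, table = study_cohort
    draws = sample_posterior(
        table, prior=PriorSpec(data_rescale=100.0),
        n_chains=4, n_draws=3000, n_warmup=1000, seed=11)
    return truth, table, draws


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
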