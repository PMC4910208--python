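import pytest

from linkcohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def clean_sim():
    """A moderately sized clean population with enough prisoners to exercise
    exposure classification (prevalence raised above the default for test
    power; study-condition defaults are exercised in the acceptance tests)."""
    cfg = SimulationConfig(n_women=4000, seed=11, prisoner_prevalence=0.03)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_bundle(clean_sim):
    return clean_sim[0]


@pytest.fixture(scope="session")
def clean_truth(clean_sim):
    return clean_sim[1]
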