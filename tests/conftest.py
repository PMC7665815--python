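import pytest

from lirads_dta import (
    SimulationParams,
    build_reference_cohort,
    categorize_cohort,
    evaluate_cohort,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def cohort():
    return build_reference_cohort()


@pytest.fixture(scope="session")
def baseline(cohort):
    return categorize_cohort(cohort)


@pytest.fixture(scope="session")
def evaluation(cohort):
    return evaluate_cohort(cohort)


@pytest.fixture(scope="session")
def sim_cohort():
    """A moderate simulated cohort with a fixed seed for property tests."""
    return simulate_cohort(SimulationParams(n_observations=2000, seed=20260930))


@pytest.fixture(scope="session")
def sim_baseline(sim_cohort):
    return categorize_cohort(sim_cohort)
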