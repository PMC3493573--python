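import numpy as np
import pytest

from lboost import AnnealSchedule, EpistasisScenario, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20121108)


@pytest.fixture(scope="session")
def fast_schedule():
    """Short cooling schedule for small fitting problems in unit tests."""
    return AnnealSchedule(n_iter=1500)


@pytest.fixture(scope="session")
def small_dd_data():
    """A small single-DD-interaction dataset (MAF 0.3, n = 300)."""
    scenario = EpistasisScenario.one_dd(0.3)
    data, truth = simulate_dataset(scenario, 300, np.random.default_rng(7))
    return data, truth
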