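import numpy as np
import pytest

from mciprog import ProgressionModel, SimulationParams, simulate_baseline, simulate_cohort


@pytest.fixture(scope="session")
def small_params():
    """Small imbalanced cohort keeping the 290/120-style class ratio."""
    return SimulationParams(n_stable=70, n_progressive=30, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    cohort, _ = simulate_baseline(small_params)
    return cohort


@pytest.fixture(scope="session")
def small_cohort_longitudinal(small_params):
    cohort, truth = simulate_cohort(small_params)
    return cohort, truth


@pytest.fixture(scope="session")
def small_model(small_cohort):
    """A modest trained ensemble shared by read-only tests."""
    return ProgressionModel(n_resamples=12, epochs=150, random_state=7).fit(small_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
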