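import numpy as np
import pytest

from hemexpand.datagen import CohortSpec, simulate_cohort, split_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient cohort with events, shared across preprocessing tests."""
    spec = CohortSpec(n_patients=60, duration=48.0, horizon=24.0, seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    return split_cohort(small_cohort, seed=7)
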