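import numpy as np
import pytest

import canaldyn as cd


@pytest.fixture(scope="session")
def protocol():
    """The standard 12-direction, 3-trial, 735 s protocol at 1 Hz."""
    return cd.default_protocol()


@pytest.fixture(scope="session")
def small_spec():
    """A small canalized cohort spec used across unit tests."""
    return cd.CohortSpec(n_fish=4, n_neurons=60, trial_noise_sd=0.1, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return cd.simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def noiseless_spec():
    return cd.CohortSpec(n_fish=3, n_neurons=40, trial_noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_spec):
    return cd.simulate_cohort(noiseless_spec)
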