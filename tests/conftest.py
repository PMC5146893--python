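import numpy as np
import pytest

from dtctrace import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic patient at default study conditions."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
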