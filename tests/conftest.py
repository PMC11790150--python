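import numpy as np
import pytest

from strawsim import default_config, run_cohort

#: canonical seed for the shared default cohort used across the suite
SEED = 42


@pytest.fixture(scope="session")
def default_cohort():
    """One default 10,000-flower cohort, shared read-only across tests."""
    return run_cohort(default_config(seed=SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
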