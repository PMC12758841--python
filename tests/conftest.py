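import numpy as np
import pytest

from campnet.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300-record default-condition cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n_records=300, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
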