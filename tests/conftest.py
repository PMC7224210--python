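import numpy as np
import pytest

from nodulecaps.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but full-featured cohort shared by read-only tests."""
    return generate_cohort(SyntheticConfig(n_patients=6, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
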