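import numpy as np
import pytest

from psa5ts.cohort import default_config, generate


@pytest.fixture(scope="session")
def small_cohort():
    """One default synthetic cohort at the study size."""
    return generate(default_config(n=155, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20230718)
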