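import numpy as np
import pytest
from hypothesis import settings

import hostpar as hp

settings.register_profile("det", derandomize=True, max_examples=100,
                          deadline=None)
settings.load_profile("det")


@pytest.fixture
def constants():
    return hp.DesignConstants()


@pytest.fixture
def truth():
    return hp.default_truth()


@pytest.fixture(scope="session")
def additive_dataset():
    """One seeded realization of the full additive factorial design."""
    return hp.generate(hp.scenario_preset("additive_null", seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
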