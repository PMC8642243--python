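import numpy as np
import pytest

import cytoref as cr


@pytest.fixture(scope="session")
def config():
    return cr.default_config()


@pytest.fixture(scope="session")
def atlas_and_truth(config):
    return cr.generate_reference(config, seed=11)


@pytest.fixture(scope="session")
def atlas(atlas_and_truth):
    return atlas_and_truth[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
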