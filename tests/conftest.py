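import numpy as np
import pytest

from dbsnet.params import default_params, merge_params

SMALL_NET = {
    "network": {"n_cortical": 6, "n_interneuron": 6, "n_stn": 12,
                "n_gpe": 12},
}


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def small_params():
    """Reduced populations for engine-level unit tests."""
    return merge_params(default_params(), SMALL_NET)


@pytest.fixture(scope="session")
def small_model(small_params):
    from dbsnet.engine import NetworkModel
    return NetworkModel(small_params, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
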