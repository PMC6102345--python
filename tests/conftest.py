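import numpy as np
import pytest

from salnet import (CNNConfig, activation_timeseries, build_network, gen_scene,
                    random_scene_config)


@pytest.fixture(scope="session")
def network():
    """Seeded random-weight network shared across tests (weights are fixed)."""
    return build_network(CNNConfig(seed=0))


@pytest.fixture(scope="session")
def short_scene():
    """A 10 s sparse synthetic scene with ground-truth annotations."""
    return gen_scene(random_scene_config("sparse", duration_s=10.0, seed=1))


@pytest.fixture(scope="session")
def short_acts(network, short_scene):
    """Per-layer activation series of the 10 s scene at the 0.1 s hop."""
    return activation_timeseries(network, short_scene, hop_s=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
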