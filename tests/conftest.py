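import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from plasticlearn import (
    ControllerParams,
    LoadParams,
    PlasticityParams,
    PlasticNetwork,
    RewireParams,
)


@pytest.fixture
def plasticity_params():
    return PlasticityParams()


@pytest.fixture
def load_params():
    return LoadParams()


@pytest.fixture
def rewire_params():
    return RewireParams()


@pytest.fixture
def controller_params():
    return ControllerParams()


def make_network(weights, positions=None, biases=None, activations=None):
    """Small hand-built network from a dense weight matrix (0 = no synapse)."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    mask = w != 0
    np.fill_diagonal(mask, False)
    if positions is None:
        rng = np.random.default_rng(0)
        positions = rng.uniform(size=(n, 2))
    if biases is None:
        biases = np.zeros(n)
    return PlasticNetwork(positions, biases, w, mask, activations=activations)


@pytest.fixture
def two_neuron_chain():
    """Neuron 0 -> neuron 1 with weight 1."""
    w = np.zeros((2, 2))
    w[0, 1] = 1.0
    return make_network(w)
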