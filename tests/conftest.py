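import numpy as np
import pytest

from measim import NeuronParams, SynapseParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def neuron():
    return NeuronParams()


@pytest.fixture
def synapse():
    return SynapseParams()
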