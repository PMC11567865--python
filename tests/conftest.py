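import numpy as np
import pytest

from peptinet.core import NodeMeta, SignedNetwork, MultilayerNetwork


def make_net(W, layers=None, n_samples=100):
    """SignedNetwork from a weight matrix with simple node ids n0, n1, ..."""
    W = np.asarray(W, dtype=float)
    p = W.shape[0]
    layers = layers or ["synaptic_peptide"] * p
    nodes = [NodeMeta(f"n{i}", f"n{i}", layers[i]) for i in range(p)]
    return SignedNetwork(nodes=nodes, W=W, n_samples=n_samples)


def make_multilayer(W, layers, n_samples=100):
    return MultilayerNetwork(network=make_net(W, layers, n_samples))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle_net():
    W = np.array([[0, 0.2, 0.2], [0.2, 0, 0.2], [0.2, 0.2, 0]])
    return make_net(W)


@pytest.fixture
def path3_net():
    # A - B - C with |w| = 0.5 each
    W = np.array([[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]])
    return make_net(W)
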