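import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def two_hubs():
    """Two-hub common-neighbor example: A-B share C,D,E; F,G,H are
    A-only neighbors; I,J,K,L are B-only neighbors."""
    from ganet import fixture
    return fixture("two_hubs")


@pytest.fixture(scope="session")
def random_graphs():
    """Small random graphs at three densities (shared census test bed)."""
    out = []
    for i, p in enumerate((0.2, 0.5, 0.8)):
        for s in range(16):
            out.append(nx.gnp_random_graph(10, p, seed=1000 * i + s))
    return out


@pytest.fixture(scope="session")
def random_digraphs():
    out = []
    for i, p in enumerate((0.1, 0.3, 0.6)):
        for s in range(16):
            out.append(nx.gnp_random_graph(10, p, seed=2000 * i + s,
                                           directed=True))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
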