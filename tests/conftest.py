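import itertools

import networkx as nx
import numpy as np
import pytest

from modrefine.core import Network, Partition


@pytest.fixture
def two_triangles():
    """Two triangles joined by one bridge edge; L = 7."""
    net = Network([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
    part = Partition.from_modules([{0, 1, 2}, {3, 4, 5}])
    return net, part


@pytest.fixture
def two_k4_bridge():
    """Two K4 cliques joined by one bridge edge; L = 13."""
    edges = list(itertools.combinations(range(4), 2))
    edges += [(u + 4, v + 4) for u, v in itertools.combinations(range(4), 2)]
    edges.append((3, 4))
    net = Network(edges)
    part = Partition.from_modules([{0, 1, 2, 3}, {4, 5, 6, 7}])
    return net, part


@pytest.fixture
def k5_in_40_edge_network():
    """K5 with a single external edge, embedded in a 40-edge network."""
    edges = list(itertools.combinations(range(5), 2))  # 10 clique edges
    edges.append((4, 5))                               # the one external edge
    # a 29-edge circulant among nodes 5..33, untouched by the clique
    outside = list(range(5, 34))
    for i in range(29):
        edges.append((outside[i], outside[(i + 1) % 29]))
    net = Network(edges)
    assert net.L == 40
    return net


def random_network(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    return Network.from_graph(g)


def random_partition(network, n_modules, seed):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_modules, size=len(network))
    return Partition({v: int(labels[i])
                      for i, v in enumerate(network.nodes)})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
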