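import numpy as np
import pytest

from gsnet import Network, build_matrices, largest_connected_component, map_geneset


def random_graph(n: int, p: float, seed: int) -> Network:
    """Erdős–Rényi-style random simple graph with zero-padded node names."""
    rng = np.random.default_rng(seed)
    draws = rng.random((n, n))
    adj = np.triu(draws < p, k=1)
    adj = (adj | adj.T).astype(np.uint8)
    width = len(str(n - 1))
    return Network.from_adjacency([f"g{i:0{width}d}" for i in range(n)], adj)


def random_connected_graph(n: int, p: float, seed: int) -> Network:
    """LCC of a random graph (non-trivial for the p used in tests)."""
    net = largest_connected_component(random_graph(n, p, seed))
    assert net.n_nodes >= 3
    return net


@pytest.fixture
def k2_net() -> Network:
    """Single edge a–b: the smallest graph with a closed-form heat matrix."""
    return Network.from_edges([("a", "b")])


@pytest.fixture
def path_net() -> Network:
    """Path a–b–c–d."""
    return Network.from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def triangle_net() -> Network:
    return Network.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star_net() -> Network:
    """Star: center c with 4 leaves."""
    return Network.from_edges([("c", l) for l in "lmno"])


@pytest.fixture
def path_matrices(path_net):
    return build_matrices(path_net)


def geneset(net: Network, genes, name="S"):
    return map_geneset(genes, net, name)
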