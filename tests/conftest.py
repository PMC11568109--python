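import itertools

import networkx as nx
import pytest

from gracoal.network import Network


@pytest.fixture
def triangle() -> Network:
    return Network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def k4() -> Network:
    nodes = "abcd"
    return Network([(u, v) for u, v in itertools.combinations(nodes, 2)])


@pytest.fixture
def paw() -> Network:
    """Triangle a, b, c plus pendant d attached to a."""
    return Network([("a", "b"), ("b", "c"), ("a", "c"), ("a", "d")])


@pytest.fixture
def path3() -> Network:
    return Network([("a", "b"), ("b", "c")])


def random_er_network(n: int, p: float, seed: int) -> Network:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return Network.from_integer_edges(sorted(g.edges()), n)
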