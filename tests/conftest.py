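import networkx as nx
import numpy as np
import pytest

from sourceloc import Network


def random_connected_network(rng: np.random.Generator, n_max: int = 12) -> Network:
    """A small random connected simple graph (test helper, not a fixture file)."""
    n = int(rng.integers(3, n_max + 1))
    p = min(1.0, 2.5 / n + 0.15)
    for _ in range(200):
        g = nx.gnp_random_graph(n, p, seed=rng)
        if nx.is_connected(g):
            return Network.from_networkx(g)
    raise AssertionError("could not draw a connected test graph")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path3():
    return Network([("a", "b"), ("b", "c")])
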