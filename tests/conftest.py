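import random

import networkx as nx
import pytest


def _named(g: nx.Graph) -> nx.Graph:
    return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})


@pytest.fixture
def star9() -> nx.Graph:
    """Star with 9 leaves; center N00. Degrees: 9 and 1x9; center betweenness 36."""
    return _named(nx.star_graph(9))


@pytest.fixture
def path3() -> nx.Graph:
    """Path A-B-C."""
    g = nx.path_graph(3)
    return nx.relabel_nodes(g, {0: "A", 1: "B", 2: "C"})


@pytest.fixture
def cycle5() -> nx.Graph:
    return _named(nx.cycle_graph(5))


def random_graph(seed: int, n_min: int = 4, n_max: int = 12) -> nx.Graph:
    """Seeded Erdos-Renyi graph with symbol-style node names."""
    rng = random.Random(seed)
    n = rng.randint(n_min, n_max)
    g = nx.gnp_random_graph(n, rng.uniform(0.15, 0.75), seed=rng.randint(0, 2**31 - 1))
    return _named(g)
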