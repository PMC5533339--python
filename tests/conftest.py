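import networkx as nx
import pytest

from cotb.graph_io import ComplexCatalog, LocalizationTable, OrthologyTable


@pytest.fixture
def triangle() -> nx.Graph:
    return nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star4() -> nx.Graph:
    """Star K1,4: hub H with leaves L1..L4."""
    return nx.Graph([("H", f"L{i}") for i in range(1, 5)])


@pytest.fixture
def path5() -> nx.Graph:
    return nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


@pytest.fixture
def empty_annotations():
    return (
        ComplexCatalog([]),
        OrthologyTable(),
        LocalizationTable(),
    )


def random_connected_graph(rng, max_nodes: int = 8) -> nx.Graph:
    """A random connected simple graph with 2..max_nodes nodes."""
    while True:
        n = int(rng.integers(2, max_nodes + 1))
        p = float(rng.uniform(0.25, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
        if g.number_of_edges() > 0 and nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
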