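import networkx as nx
import pytest

from drugspn import weighting


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g


@pytest.fixture
def path3():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


@pytest.fixture
def star5():
    """K_{1,4}: center X with leaves L1..L4."""
    g = nx.Graph()
    g.add_edges_from([("X", f"L{i}") for i in range(1, 5)])
    return g


@pytest.fixture
def toy_dag():
    """Five-term BP tree: root; A, B children of root; A1 child of A (is_a)."""
    parents = {
        "root": set(),
        "A": {("root", "is_a")},
        "B": {("root", "is_a")},
        "A1": {("A", "is_a")},
        "C": {("root", "part_of")},
    }
    domain = {t: "BP" for t in parents}
    return weighting.OntologyDAG(parents, domain)
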