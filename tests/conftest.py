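import networkx as nx
import pytest

from stressweave import synthetic


@pytest.fixture(scope="session")
def planted_dataset():
    """Default planted-structure dataset (4 clusters x 30 genes, seed 7)."""
    return synthetic.generate_all(synthetic.SyntheticSpec(seed=7))


@pytest.fixture
def two_triangles():
    g = nx.Graph()
    g.add_edges_from(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
    )
    return g


@pytest.fixture
def two_cliques():
    """Two disjoint K5 cliques on nodes 0-4 and 5-9, unit weights."""
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
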