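import networkx as nx
import pytest

from mocplex.ontology import AnnotationTable, OntologyDAG


@pytest.fixture
def k4():
    return nx.complete_graph(["a", "b", "c", "d"])


@pytest.fixture
def path4():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "D")])
    return g


@pytest.fixture
def star4():
    """4-node star: center c with leaves l1, l2, l3."""
    g = nx.Graph()
    g.add_edges_from([("c", "l1"), ("c", "l2"), ("c", "l3")])
    return g


@pytest.fixture
def triangle_pendant():
    """Triangle a-b-c plus pendant vertex d attached to a."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"), ("a", "d")])
    return g


@pytest.fixture
def chain_dag():
    """Single-chain ontology: leaf -> mid -> root, all BP."""
    return OntologyDAG(
        parents={"root": frozenset(), "mid": frozenset({"root"}), "leaf": frozenset({"mid"})},
        aspect={"root": "BP", "mid": "BP", "leaf": "BP"},
    )


@pytest.fixture
def chain_annotations():
    """10 proteins: p1..p5 on mid (so p(mid)=0.5), p6 on leaf, rest on root."""
    ann = {f"p{i}": {"mid"} for i in range(1, 6)}
    ann["p6"] = {"leaf"}
    for i in range(7, 11):
        ann[f"p{i}"] = {"root"}
    return AnnotationTable({k: frozenset(v) for k, v in ann.items()})
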