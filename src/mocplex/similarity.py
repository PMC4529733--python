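"""Relevance GO semantic similarity and the edge-weighted similarity network.

Protein functional similarity is measured with Schlicker's Relevance measure:
for two terms t1, t2 with information content IC(t) = -ln p(t) (annotation
frequency with descendant propagation, Resnik-style),

    sim_Rel(t1, t2) = max over common ancestors a of
                      [2 IC(a) / (IC(t1) + IC(t2))] * [1 - p(a)],

i.e. Lin's ratio damped by (1 - p) so that similarity through near-root
(uninformative) ancestors vanishes.  Protein-level similarity is the
arithmetic mean over all GO-term cross pairs of the two proteins within one
aspect.  Assigning these values to every PPI edge yields the similarity
network whose edge weights drive the GO objective of the complex search.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import networkx as nx

from .ontology import AnnotationTable, OntologyDAG

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityNetwork",
    "information_content",
    "relevance_similarity",
    "protein_similarity",
    "build_similarity_network",
    "load_similarity_weights",
    "write_similarity_weights",
]


class SimilarityNetwork:
    """A PPI network edge set with one semantic-similarity weight per edge.

    Wraps an undirected graph whose every edge carries a ``weight`` attribute
    in [0, 1].  Lookup for non-edges returns 0.
    """

    def __init__(self, graph: nx.Graph):
        for u, v, w in graph.edges(data="weight"):
            if w is None:
                raise ValueError(f"edge ({u}, {v}) has no weight")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"edge ({u}, {v}) weight {w} outside [0, 1]")
        self.graph = graph

    @classmethod
    def from_weights(cls, net: nx.Graph, weights: Mapping[tuple[str, str], float] | float) -> "SimilarityNetwork":
        """Build from a base network and an edge -> weight map (or a constant)."""
        graph = nx.Graph()
        graph.add_nodes_from(net.nodes)
        const = weights if isinstance(weights, (int, float)) else None
        for u, v in net.edges():
            if const is not None:
                w = float(const)
            else:
                w = weights.get((u, v), weights.get((v, u)))  # type: ignore[union-attr]
                if w is None:
                    raise ValueError(f"no weight for edge ({u}, {v})")
            graph.add_edge(u, v, weight=float(w))
        return cls(graph)

    def weight(self, u: str, v: str) -> float:
        data = self.graph.get_edge_data(u, v)
        return 0.0 if data is None else data["weight"]

    def induced_edge_weights(self, nodes: Iterable[str]) -> list[float]:
        nodes = set(nodes)
        adj = self.graph.adj
        out = []
        for u in nodes:
            if u not in adj:
                continue
            for v, data in adj[u].items():
                if v in nodes and u < v:
                    out.append(data["weight"])
        return out


def information_content(dag: OntologyDAG, ann: AnnotationTable) -> dict[str, tuple[float, float]]:
    """Annotation probability and information content per term.

    p(t) is the fraction of annotated proteins annotated to t or any of its
    descendants; IC(t) = -ln p(t) (natural log — the Relevance measure only
    uses IC in ratios, so the base is immaterial).  Terms with p = 0 are
    excluded.
    """
    corpus = ann.corpus_size
    if corpus < 1:
        raise ValueError("annotation corpus is empty")
    ann.validate_against(dag)
    direct: dict[str, set[str]] = {t: set() for t in dag.terms}
    for protein, terms in ann.annotations.items():
        for t in terms:
            direct[t].add(protein)
    # accumulate protein sets children-first (reverse topological order)
    covered: dict[str, set[str]] = {}
    for term in reversed(dag._topo_order):
        acc = set(direct[term])
        for child in dag.children(term):
            acc |= covered[child]
        covered[term] = acc
    out: dict[str, tuple[float, float]] = {}
    for term, proteins in covered.items():
        if proteins:
            p = len(proteins) / corpus
            out[term] = (p, -math.log(p))
    return out


def relevance_similarity(
    t1: str,
    t2: str,
    ic: Mapping[str, tuple[float, float]],
    dag: OntologyDAG,
) -> float:
    """Schlicker Relevance similarity between two terms of the same aspect."""
    if dag.aspect[t1] != dag.aspect[t2]:
        raise ValueError(
            f"terms {t1!r} ({dag.aspect[t1]}) and {t2!r} ({dag.aspect[t2]}) "
            "are from different aspects"
        )
    if t1 not in ic or t2 not in ic:
        raise KeyError("both terms must be present in the IC map")
    ic1, ic2 = ic[t1][1], ic[t2][1]
    denom = ic1 + ic2
    if denom == 0.0:
        return 0.0
    best = 0.0
    for a in dag.ancestors(t1) & dag.ancestors(t2):
        entry = ic.get(a)
        if entry is None:
            continue
        p_a, ic_a = entry
        score = (2.0 * ic_a / denom) * (1.0 - p_a)
        if score > best:
            best = score
    return best


def protein_similarity(
    p1: str,
    p2: str,
    ann: AnnotationTable,
    ic: Mapping[str, tuple[float, float]],
    dag: OntologyDAG,
    aspect: str = "BP",
    _term_cache: dict | None = None,
) -> float:
    """All-cross-pairs mean of Relevance term similarities within one aspect.

    Proteins with no usable annotation in the aspect score 0, so GO-silent
    edges neither help nor hurt the GO objective.
    """
    terms1 = [t for t in ann.terms_of(p1) if dag.aspect.get(t) == aspect and t in ic]
    terms2 = [t for t in ann.terms_of(p2) if dag.aspect.get(t) == aspect and t in ic]
    if not terms1 or not terms2:
        return 0.0
    total = 0.0
    for t1 in terms1:
        for t2 in terms2:
            if _term_cache is None:
                total += relevance_similarity(t1, t2, ic, dag)
            else:
                key = (t1, t2) if t1 <= t2 else (t2, t1)
                cached = _term_cache.get(key)
                if cached is None:
                    cached = relevance_similarity(t1, t2, ic, dag)
                    _term_cache[key] = cached
                total += cached
    return total / (len(terms1) * len(terms2))


def build_similarity_network(
    net: nx.Graph,
    ann: AnnotationTable,
    ic: Mapping[str, tuple[float, float]],
    dag: OntologyDAG,
    aspect: str = "BP",
) -> SimilarityNetwork:
    """Weight every edge of ``net`` with the protein-pair Relevance similarity."""
    graph = nx.Graph()
    graph.add_nodes_from(net.nodes)
    term_cache: dict = {}
    for u, v in net.edges():
        w = protein_similarity(u, v, ann, ic, dag, aspect=aspect, _term_cache=term_cache)
        graph.add_edge(u, v, weight=w)
    return SimilarityNetwork(graph)


def load_similarity_weights(path, net: nx.Graph) -> SimilarityNetwork:
    """Read a precomputed 3-column ``u v w`` weight file over ``net``'s edges.

    Network edges missing from the file get weight 0 (logged); weight lines
    for non-edges are ignored (logged); weights outside [0, 1] are an error.
    """
    graph = nx.Graph()
    graph.add_nodes_from(net.nodes)
    ignored = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            u, v, w_str = fields[0], fields[1], fields[2]
            w = float(w_str)
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{path}: line {lineno}: weight {w} outside [0, 1]")
            if not net.has_edge(u, v):
                ignored += 1
                continue
            graph.add_edge(u, v, weight=w)
    missing = 0
    for u, v in net.edges():
        if not graph.has_edge(u, v):
            graph.add_edge(u, v, weight=0.0)
            missing += 1
    if ignored:
        logger.warning("load_similarity_weights(%s): ignored %d non-edge weight lines", path, ignored)
    if missing:
        logger.info("load_similarity_weights(%s): %d network edges defaulted to weight 0", path, missing)
    return SimilarityNetwork(graph)


def write_similarity_weights(simnet: SimilarityNetwork, path) -> None:
    with open(path, "w") as handle:
        for u, v in sorted(tuple(sorted(e)) for e in simnet.graph.edges()):
            handle.write(f"{u}\t{v}\t{simnet.weight(u, v):.6f}\n")
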