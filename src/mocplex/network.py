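"""PPI network data model, edge-list / complex-catalog I/O and whole-network statistics.

Protein-protein interaction (PPI) networks are modelled as simple undirected
:class:`networkx.Graph` objects whose nodes are opaque protein identifier
strings.  Self-loops and duplicate pairs are dropped at load time because all
downstream statistics (density, degree, contribution) assume a simple graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ComplexCatalog",
    "NetworkSummary",
    "load_edge_list",
    "write_edge_list",
    "load_complex_catalog",
    "write_complex_catalog",
    "network_summary",
    "subgraph_density",
    "closeness_centrality",
]


@dataclass
class ComplexCatalog:
    """An ordered collection of named protein sets (predicted or reference complexes)."""

    complexes: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.complexes]
        if len(set(names)) != len(names):
            raise ValueError("complex names must be unique")
        for name, members in self.complexes:
            if not members:
                raise ValueError(f"complex {name!r} has no members")
        self.complexes = [(n, frozenset(m)) for n, m in self.complexes]

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.complexes]

    @property
    def member_sets(self) -> list[frozenset[str]]:
        return [members for _, members in self.complexes]

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[str]], prefix: str = "complex") -> "ComplexCatalog":
        return cls([(f"{prefix}_{i + 1}", frozenset(s)) for i, s in enumerate(sets)])


@dataclass(frozen=True)
class NetworkSummary:
    """Whole-network topological statistics (one row per network)."""

    protein_count: int
    interaction_count: int
    avg_degree: float
    max_degree: int
    density: float
    clustering_coefficient: float
    connected_components: int
    diameter: int
    avg_neighbors: float

    FIELDS = (
        "protein_count",
        "interaction_count",
        "avg_degree",
        "max_degree",
        "density",
        "clustering_coefficient",
        "connected_components",
        "diameter",
        "avg_neighbors",
    )

    def as_row(self) -> list:
        return [getattr(self, f) for f in self.FIELDS]


def load_edge_list(
    path,
    columns: Sequence[int] = (0, 1),
    comment: str = "#",
    sep: str | None = None,
) -> nx.Graph:
    """Read a tab/whitespace-delimited edge list into a simple undirected graph.

    Parameters
    ----------
    path : str or path-like
        Text file with one interaction per line.
    columns : pair of int
        0-based indices of the two identifier columns (HPRD exports vary).
    comment : str
        Lines starting with this prefix are skipped.
    sep : str or None
        Field separator; ``None`` splits on any whitespace (tabs included).

    Self-loops and duplicate pairs are silently dropped; drop counts are logged
    so preprocessing discrepancies in published degree statistics can be traced.
    """
    c1, c2 = columns
    need = max(c1, c2) + 1
    graph = nx.Graph()
    self_loops = duplicates = 0
    n_lines = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or (comment and line.startswith(comment)):
                continue
            fields = line.split(sep)
            if len(fields) < need:
                raise ValueError(
                    f"{path}: malformed line {lineno}: expected at least "
                    f"{need} columns, got {len(fields)}"
                )
            n_lines += 1
            u, v = fields[c1], fields[c2]
            if u == v:
                self_loops += 1
                graph.add_node(u)
                continue
            if graph.has_edge(u, v):
                duplicates += 1
                continue
            graph.add_edge(u, v)
    if n_lines == 0:
        raise ValueError(f"{path}: empty edge list")
    if self_loops or duplicates:
        logger.info(
            "load_edge_list(%s): dropped %d self-loops and %d duplicate pairs",
            path,
            self_loops,
            duplicates,
        )
    return graph


def write_edge_list(net: nx.Graph, path) -> None:
    """Write one interaction per line, tab-separated, in sorted order."""
    with open(path, "w") as handle:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            handle.write(f"{u}\t{v}\n")


def load_complex_catalog(path, named: bool = True) -> ComplexCatalog:
    """Read a flat one-complex-per-line catalog (PCDq-style export).

    With ``named=True`` the first tab-separated field is the complex name and
    the rest are members; with ``named=False`` every field is a member and
    complexes are auto-named ``complex_1``, ``complex_2``, ... by line order.
    """
    complexes: list[tuple[str, frozenset[str]]] = []
    seen: set[str] = set()
    with open(path) as handle:
        index = 0
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f for f in line.split("\t") if f]
            index += 1
            if named:
                name, members = fields[0], fields[1:]
            else:
                name, members = f"complex_{index}", fields
            if name in seen:
                raise ValueError(f"{path}: duplicate complex name {name!r} on line {lineno}")
            if not members:
                raise ValueError(f"{path}: complex {name!r} on line {lineno} has no members")
            seen.add(name)
            complexes.append((name, frozenset(members)))
    return ComplexCatalog(complexes)


def write_complex_catalog(catalog: ComplexCatalog, path) -> None:
    with open(path, "w") as handle:
        for name, members in catalog:
            handle.write("\t".join([name, *sorted(members)]) + "\n")


def network_summary(net: nx.Graph) -> NetworkSummary:
    """Compute the nine standard summary statistics of a PPI network.

    The clustering coefficient is the unweighted mean of per-node local
    coefficients (nodes of degree < 2 contribute 0) and the diameter is taken
    on the largest connected component, the usual conventions for a single
    network-level number.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    n = net.number_of_nodes()
    m = net.number_of_edges()
    degrees = [d for _, d in net.degree()]
    components = list(nx.connected_components(net))
    largest = max(components, key=len)
    diameter = nx.diameter(net.subgraph(largest)) if len(largest) > 1 else 0
    clustering = sum(nx.clustering(net).values()) / n
    avg_degree = 2.0 * m / n
    return NetworkSummary(
        protein_count=n,
        interaction_count=m,
        avg_degree=avg_degree,
        max_degree=max(degrees),
        density=(2.0 * m / (n * (n - 1))) if n > 1 else 0.0,
        clustering_coefficient=clustering,
        connected_components=len(components),
        diameter=diameter,
        avg_neighbors=avg_degree,
    )


def subgraph_density(net: nx.Graph, nodes: Iterable[str]) -> float:
    """Density of the subgraph induced by ``nodes``: |E(C)| / (|C| choose 2)."""
    nodes = set(nodes)
    if len(nodes) < 2:
        raise ValueError("subgraph density requires at least 2 nodes")
    missing = nodes - set(net.nodes)
    if missing:
        raise ValueError(f"nodes not in network: {sorted(missing)[:5]}")
    edges = 0
    for u in nodes:
        edges += sum(1 for v in net.adj[u] if v in nodes)
    edges //= 2
    possible = len(nodes) * (len(nodes) - 1) // 2
    return edges / possible


def closeness_centrality(net: nx.Graph) -> dict[str, float]:
    """Reachable-only closeness centrality: CC(v) = |R(v)| / sum of distances.

    ``R(v)`` is the set of nodes reachable from ``v`` (excluding ``v``); with a
    disconnected network this is the component-local reciprocal mean distance.
    Isolated nodes get 0.
    """
    # networkx with wf_improved=False computes exactly |R(v)| / sum d(v, u).
    return nx.closeness_centrality(net, wf_improved=False)
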