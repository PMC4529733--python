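"""Association of predicted complexes with genetic disorders and disease classes.

Follows the standard diseasome organisation: every genetic disorder is
caused by a set of genes and belongs to exactly one of 22 primary disease
classes (named after the physiological system affected).  A disorder is
associated with a predicted complex when *all* of its genes belong to that
complex — the all-genes membership rule — and the associations are summarised
as two bipartite networks (complex-disorder and complex-class) plus per-class
PPI density / semantic-similarity metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable

import networkx as nx

from .network import ComplexCatalog, subgraph_density
from .similarity import SimilarityNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DISEASE_CLASSES",
    "DisorderCatalog",
    "BipartiteAssociation",
    "ClassNetworkMetrics",
    "load_disorder_catalog",
    "write_disorder_catalog",
    "associated_disorders",
    "complex_class_network",
    "complex_disorder_network",
    "project_disorders_to_classes",
    "class_network_metrics",
]

# the 22 primary disease classes of the diseasome classification
# (named after the physiological system affected by the disorder)
DISEASE_CLASSES = (
    "Bone",
    "Cancer",
    "Cardiovascular",
    "Connective_tissue",
    "Dermatological",
    "Developmental",
    "Ear_nose_throat",
    "Endocrine",
    "Gastrointestinal",
    "Hematological",
    "Immunological",
    "Metabolic",
    "Muscular",
    "Neurological",
    "Nutritional",
    "Ophthalmological",
    "Psychiatric",
    "Renal",
    "Respiratory",
    "Skeletal",
    "Unclassified",
    "Multiple",
)


@dataclass
class DisorderCatalog:
    """Gene -> disorder -> disease-class records with derived lookup maps."""

    records: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        self.disorder_genes: dict[str, frozenset[str]] = {}
        self.disorder_class: dict[str, str] = {}
        genes: dict[str, set[str]] = {}
        for gene, disorder, cls in self.records:
            genes.setdefault(disorder, set()).add(gene)
            if disorder in self.disorder_class and self.disorder_class[disorder] != cls:
                raise ValueError(
                    f"disorder {disorder!r} assigned to both "
                    f"{self.disorder_class[disorder]!r} and {cls!r}"
                )
            self.disorder_class[disorder] = cls
        for disorder, gs in genes.items():
            if not gs:
                raise ValueError(f"disorder {disorder!r} has no genes")
            self.disorder_genes[disorder] = frozenset(gs)
        self.class_disorders: dict[str, frozenset[str]] = {}
        self.class_genes: dict[str, frozenset[str]] = {}
        for disorder, cls in self.disorder_class.items():
            self.class_disorders.setdefault(cls, frozenset())
        by_class_d: dict[str, set[str]] = {}
        by_class_g: dict[str, set[str]] = {}
        for disorder, cls in self.disorder_class.items():
            by_class_d.setdefault(cls, set()).add(disorder)
            by_class_g.setdefault(cls, set()).update(self.disorder_genes[disorder])
        self.class_disorders = {c: frozenset(d) for c, d in by_class_d.items()}
        self.class_genes = {c: frozenset(g) for c, g in by_class_g.items()}

    @property
    def disorders(self) -> set[str]:
        return set(self.disorder_genes)

    @property
    def classes(self) -> set[str]:
        return set(self.class_disorders)


@dataclass
class BipartiteAssociation:
    """Weighted bipartite complex-disorder or complex-class associations."""

    left: list[str]
    right: list[str]
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    right_attrs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        left, right = set(self.left), set(self.right)
        for (l, r), w in self.edges.items():
            if l not in left or r not in right:
                raise ValueError(f"edge ({l}, {r}) crosses outside the partitions")
            if not (isinstance(w, int) and w > 0):
                raise ValueError(f"edge ({l}, {r}) weight {w} is not a positive integer")

    @property
    def total_weight(self) -> int:
        return sum(self.edges.values())

    def to_tables(self) -> tuple[list[tuple], list[tuple]]:
        """GraphML-style (node table, edge table) rows for external visualisation."""
        nodes = [(n, "complex", "") for n in self.left]
        nodes += [(n, "partner", self.right_attrs.get(n, "")) for n in self.right]
        edges = [(l, r, w) for (l, r), w in sorted(self.edges.items())]
        return nodes, edges


@dataclass(frozen=True)
class ClassNetworkMetrics:
    """Per-class PPI subnetwork statistics (diseasome-style class gene sets)."""

    gene_count: int
    interaction_count: int
    density: float
    mean_similarity: float


def load_disorder_catalog(path) -> DisorderCatalog:
    """Read a 3-column ``gene TAB disorder TAB class`` table."""
    records = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            records.append((fields[0], fields[1], fields[2]))
    return DisorderCatalog(records)


def write_disorder_catalog(catalog: DisorderCatalog, path) -> None:
    with open(path, "w") as handle:
        for gene, disorder, cls in sorted(catalog.records):
            handle.write(f"{gene}\t{disorder}\t{cls}\n")


def associated_disorders(
    complex_members: Iterable[str],
    catalog: DisorderCatalog,
    network: nx.Graph | None = None,
) -> set[str]:
    """Disorders whose full gene set is contained in the complex.

    When ``network`` is given, disorders with no genes at all in the analysis
    network are excluded from consideration (logged).
    """
    members = set(complex_members)
    nodes = set(network.nodes) if network is not None else None
    out = set()
    dropped = 0
    for disorder, genes in catalog.disorder_genes.items():
        if nodes is not None and not (genes & nodes):
            dropped += 1
            continue
        if genes <= members:
            out.add(disorder)
    if dropped:
        logger.debug("associated_disorders: %d disorders have no gene in the network", dropped)
    return out


def complex_disorder_network(
    complexes: ComplexCatalog,
    catalog: DisorderCatalog,
    network: nx.Graph | None = None,
) -> BipartiteAssociation:
    """Unweighted complex-disorder bipartite network (disorders tagged by class)."""
    edges: dict[tuple[str, str], int] = {}
    for name, members in complexes:
        for disorder in associated_disorders(members, catalog, network):
            edges[(name, disorder)] = 1
    return BipartiteAssociation(
        left=list(complexes.names),
        right=sorted(catalog.disorders),
        edges=edges,
        right_attrs=dict(catalog.disorder_class),
    )


def complex_class_network(
    complexes: ComplexCatalog,
    catalog: DisorderCatalog,
    network: nx.Graph | None = None,
) -> BipartiteAssociation:
    """Complex-class bipartite network, edge weight = associated disorder count."""
    edges: dict[tuple[str, str], int] = {}
    for name, members in complexes:
        counts: dict[str, int] = {}
        for disorder in associated_disorders(members, catalog, network):
            cls = catalog.disorder_class[disorder]
            counts[cls] = counts.get(cls, 0) + 1
        for cls, w in counts.items():
            edges[(name, cls)] = w
    return BipartiteAssociation(
        left=list(complexes.names),
        right=sorted(catalog.classes),
        edges=edges,
    )


def project_disorders_to_classes(
    bip: BipartiteAssociation,
    catalog: DisorderCatalog,
) -> BipartiteAssociation:
    """Collapse a complex-disorder network by disease class (consistency identity)."""
    edges: dict[tuple[str, str], int] = {}
    for (name, disorder), w in bip.edges.items():
        cls = catalog.disorder_class[disorder]
        edges[(name, cls)] = edges.get((name, cls), 0) + w
    return BipartiteAssociation(
        left=list(bip.left),
        right=sorted(catalog.classes),
        edges=edges,
    )


def class_network_metrics(
    catalog: DisorderCatalog,
    net: nx.Graph,
    similarity: SimilarityNetwork | Callable[[str, str], float] | None = None,
) -> dict[str, ClassNetworkMetrics]:
    """Per-class induced PPI subnetwork size, density and mean pairwise similarity.

    The similarity column averages over *all* unordered gene pairs of the class
    (pairs with no similarity defined contribute 0); classes with fewer than
    two genes in the network get all-zero metrics (logged).
    """
    if isinstance(similarity, SimilarityNetwork):
        sim_fn = similarity.weight
    elif callable(similarity):
        sim_fn = similarity
    else:
        sim_fn = lambda u, v: 0.0  # noqa: E731
    out: dict[str, ClassNetworkMetrics] = {}
    for cls in sorted(catalog.classes):
        genes = sorted(catalog.class_genes[cls] & set(net.nodes))
        if len(genes) < 2:
            logger.info("class_network_metrics: class %s has <2 genes in network", cls)
            out[cls] = ClassNetworkMetrics(len(genes), 0, 0.0, 0.0)
            continue
        interactions = net.subgraph(genes).number_of_edges()
        density = subgraph_density(net, genes)
        total = 0.0
        pairs = 0
        for i, u in enumerate(genes):
            for v in genes[i + 1:]:
                total += sim_fn(u, v)
                pairs += 1
        out[cls] = ClassNetworkMetrics(len(genes), interactions, density, total / pairs)
    return out
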