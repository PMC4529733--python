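"""Seeded synthetic fixtures with the statistical structure the method assumes.

The generators emulate the input ecology of a human PPI complex-detection
study: dense, functionally coherent planted complexes inside a sparse
background graph (planted-partition model), semantic-similarity edge weights
that are high inside complexes and low elsewhere, a toy GO hierarchy in which
same-complex proteins share a deep term, and a diseasome-style disorder
catalog over the 22 primary disease classes.  Everything is a pure function
of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import truncnorm

from .disease import DISEASE_CLASSES, DisorderCatalog
from .network import ComplexCatalog
from .ontology import AnnotationTable, OntologyDAG
from .similarity import SimilarityNetwork

__all__ = [
    "SyntheticSpec",
    "generate_planted_network",
    "generate_toy_ontology",
    "generate_disorder_catalog",
    "generate_study",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-complex benchmark.

    Defaults are the package's reference study conditions: 8 node-disjoint
    planted complexes of 6-12 proteins with within-complex edge probability
    0.9 against a 100-node background wired at 0.02, and semantic-similarity
    weights drawn around 0.9 inside complexes and 0.1 elsewhere (truncated
    normal, sd 0.05).
    """

    n_complexes: int = 8
    size_range: tuple[int, int] = (6, 12)
    p_in: float = 0.9
    p_out: float = 0.02
    n_background: int = 100
    w_in: float = 0.9
    w_out: float = 0.1
    w_sd: float = 0.05
    ontology_depth: int = 4
    branching: int = 3
    n_disorders_per_class: int = 2
    disorder_size_range: tuple[int, int] = (2, 4)
    n_decoys: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        for w in (self.w_in, self.w_out):
            if not 0.0 <= w <= 1.0:
                raise ValueError("weight means must be in [0, 1]")
        if self.size_range[0] < 2:
            raise ValueError("planted complexes need at least 2 nodes")


def _truncated_weights(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0:
        return np.full(size, mean)
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_planted_network(
    spec: SyntheticSpec,
    seed: int | None = None,
) -> tuple[nx.Graph, SimilarityNetwork, ComplexCatalog]:
    """Planted-partition PPI graph, its similarity network, and the truth catalog."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lo, hi = spec.size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_complexes)]
    complexes: list[frozenset[str]] = []
    nodes: list[str] = []
    complex_of: dict[str, int] = {}
    counter = 0
    for ci, size in enumerate(sizes):
        members = []
        for _ in range(size):
            counter += 1
            name = f"P{counter:04d}"
            members.append(name)
            complex_of[name] = ci
        complexes.append(frozenset(members))
        nodes.extend(members)
    for _ in range(spec.n_background):
        counter += 1
        nodes.append(f"B{counter:04d}")

    net = nx.Graph()
    net.add_nodes_from(nodes)
    within_pairs: list[tuple[str, str]] = []
    background_pairs: list[tuple[str, str]] = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            same = (
                u in complex_of
                and v in complex_of
                and complex_of[u] == complex_of[v]
            )
            (within_pairs if same else background_pairs).append((u, v))
    draw_in = rng.random(len(within_pairs)) < spec.p_in
    draw_out = rng.random(len(background_pairs)) < spec.p_out
    edges_in = [p for p, keep in zip(within_pairs, draw_in) if keep]
    edges_out = [p for p, keep in zip(background_pairs, draw_out) if keep]
    net.add_edges_from(edges_in)
    net.add_edges_from(edges_out)

    sim_graph = nx.Graph()
    sim_graph.add_nodes_from(nodes)
    w_in = _truncated_weights(spec.w_in, spec.w_sd, len(edges_in), rng)
    w_out = _truncated_weights(spec.w_out, spec.w_sd, len(edges_out), rng)
    for (u, v), w in zip(edges_in, w_in):
        sim_graph.add_edge(u, v, weight=float(w))
    for (u, v), w in zip(edges_out, w_out):
        sim_graph.add_edge(u, v, weight=float(w))

    truth = ComplexCatalog.from_sets(complexes, prefix="planted")
    return net, SimilarityNetwork(sim_graph), truth


def generate_toy_ontology(
    spec: SyntheticSpec,
    truth: ComplexCatalog,
    background: list[str] | None = None,
    seed: int | None = None,
) -> tuple[OntologyDAG, AnnotationTable]:
    """Tree-shaped BP ontology with one deep term per planted complex.

    Proteins of the same complex share a deep (informative) term so their
    pairwise Relevance similarity is high; background proteins are annotated
    to shallow, near-root terms with low information content.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    parents: dict[str, frozenset[str]] = {"T_root": frozenset()}
    aspect: dict[str, str] = {"T_root": "BP"}
    levels: list[list[str]] = [["T_root"]]
    for depth in range(1, spec.ontology_depth + 1):
        level = []
        for parent in levels[depth - 1]:
            for b in range(spec.branching):
                term = f"{parent}.{b}"
                parents[term] = frozenset({parent})
                aspect[term] = "BP"
                level.append(term)
        levels.append(level)
    dag = OntologyDAG(parents, aspect)

    leaves = levels[-1]
    if len(leaves) < len(truth):
        raise ValueError("ontology too small for the number of planted complexes")
    stride = max(1, len(leaves) // max(1, len(truth)))
    annotations: dict[str, set[str]] = {}
    for ci, (_, members) in enumerate(truth):
        leaf = leaves[(ci * stride) % len(leaves)]
        for protein in sorted(members):
            annotations.setdefault(protein, set()).add(leaf)
    shallow = levels[1]
    for i, protein in enumerate(sorted(background or [])):
        annotations.setdefault(protein, set()).add(shallow[int(rng.integers(len(shallow)))])
    return dag, AnnotationTable({p: frozenset(t) for p, t in annotations.items()})


def generate_disorder_catalog(
    spec: SyntheticSpec,
    truth: ComplexCatalog,
    seed: int | None = None,
) -> DisorderCatalog:
    """Diseasome-style catalog: in-complex disorders plus cross-complex decoys.

    Real disorders are small gene subsets of a single planted complex (so the
    all-genes association rule fires); decoys span two complexes (so it does
    not).  Disorders are assigned round-robin over the 22 primary classes.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    member_sets = truth.member_sets
    records: list[tuple[str, str, str]] = []
    lo, hi = spec.disorder_size_range
    idx = 0
    for cls in DISEASE_CLASSES:
        for k in range(spec.n_disorders_per_class):
            source = member_sets[int(rng.integers(len(member_sets)))]
            size = min(int(rng.integers(lo, hi + 1)), len(source))
            genes = sorted(source)
            pick = rng.choice(len(genes), size=size, replace=False)
            idx += 1
            disorder = f"disorder_{idx:03d}"
            for i in np.atleast_1d(pick):
                records.append((genes[i], disorder, cls))
    for k in range(spec.n_decoys):
        ci, cj = rng.choice(len(member_sets), size=2, replace=False)
        g1 = sorted(member_sets[ci])
        g2 = sorted(member_sets[cj])
        idx += 1
        disorder = f"decoy_{idx:03d}"
        cls = DISEASE_CLASSES[k % len(DISEASE_CLASSES)]
        records.append((g1[int(rng.integers(len(g1)))], disorder, cls))
        records.append((g2[int(rng.integers(len(g2)))], disorder, cls))
    return DisorderCatalog(records)


def generate_study(spec: SyntheticSpec, seed: int | None = None):
    """All four fixture objects from one spec and one seed.

    Sub-generators get independent child seeds spawned from the master seed,
    so each component is individually reproducible.
    """
    master = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    s_net, s_ont, s_dis = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    net, simnet, truth = generate_planted_network(spec, seed=s_net)
    background = [n for n in net.nodes if n.startswith("B")]
    dag, ann = generate_toy_ontology(spec, truth, background, seed=s_ont)
    disorders = generate_disorder_catalog(spec, truth, seed=s_dis)
    return net, simnet, truth, dag, ann, disorders
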