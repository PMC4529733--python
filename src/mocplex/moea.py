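"""NSGA-II search for protein complexes in a PPI network.

A candidate complex is encoded directly as a connected node subset of the PPI
graph (a "chromosome").  Three objectives, all maximized, score a candidate C:

* contribution — sum over members of (in-cluster neighbors / network degree);
  a normalized internal-degree ratio that rewards compact, separated modules,
* closeness   — sum of whole-network closeness centralities of the members,
* similarity  — sum of semantic-similarity edge weights inside C divided by
  |C| (formula-literal default) or by the induced edge count (mean weight).

Raw subgraph density is available as an optional fourth objective.  There is
no crossover (it overwhelmingly produces disconnected subgraphs); variation is
an insertion/deletion mutation followed by a connectivity repair.  Selection
is the standard NSGA-II machinery: fast non-dominated sorting, crowding
distance, crowded binary tournaments, and elitist environmental selection on
the union of parents and offspring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .network import ComplexCatalog, closeness_centrality, subgraph_density
from .similarity import SimilarityNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "AlgorithmConfig",
    "Chromosome",
    "ObjectiveVector",
    "Population",
    "contribution_objective",
    "closeness_objective",
    "similarity_objective",
    "evaluate",
    "initialize_population",
    "mutate",
    "fast_nondominated_sort",
    "crowding_distance",
    "run",
    "extract_complexes",
]


@dataclass(frozen=True)
class ObjectiveVector:
    """The maximized objective values of one candidate complex."""

    contribution: float
    closeness: float
    similarity: float
    density: float | None = None

    def as_tuple(self) -> tuple[float, ...]:
        if self.density is None:
            return (self.contribution, self.closeness, self.similarity)
        return (self.contribution, self.closeness, self.similarity, self.density)


@dataclass(frozen=True)
class Chromosome:
    """A candidate complex: a node subset with its cached objective vector."""

    members: frozenset[str]
    objectives: ObjectiveVector | None = None

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Population:
    individuals: list[Chromosome]
    generation: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class AlgorithmConfig:
    """Tunable parameters of the complex search.

    ``mutation_probability`` follows the published setting (0.9); the
    remaining values are package defaults, configurable everywhere.
    """

    population_size: int = 100
    generations: int = 200
    mutation_probability: float = 0.9
    mutate_fraction: float = 0.2
    min_size: int = 3
    max_size: int = 300
    seed: int = 0
    use_density_objective: bool = False
    similarity_denominator: str = "nodes"
    merge_jaccard: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.mutation_probability <= 1.0:
            raise ValueError("mutation_probability must be in (0, 1]")
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.similarity_denominator not in ("nodes", "edges"):
            raise ValueError("similarity_denominator must be 'nodes' or 'edges'")
        if not 0.0 < self.mutate_fraction <= 1.0:
            raise ValueError("mutate_fraction must be in (0, 1]")
        if self.min_size < 2 or self.max_size < self.min_size:
            raise ValueError("need 2 <= min_size <= max_size")
        if not 0.0 < self.merge_jaccard <= 1.0:
            raise ValueError("merge_jaccard must be in (0, 1]")


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def contribution_objective(net: nx.Graph, members: Iterable[str]) -> float:
    """Sum over members of (in-cluster neighbor count / whole-network degree)."""
    members = set(members)
    total = 0.0
    for n in members:
        degree = net.degree(n)
        if degree == 0:
            logger.debug("contribution: node %s has network degree 0, contributes 0", n)
            continue
        inside = sum(1 for v in net.adj[n] if v in members)
        total += inside / degree
    return total


def closeness_objective(cc: Mapping[str, float], members: Iterable[str]) -> float:
    """Sum of precomputed whole-network closeness centralities over the cluster."""
    return sum(cc[n] for n in members)


def similarity_objective(
    simnet: SimilarityNetwork,
    members: Iterable[str],
    denominator: str = "nodes",
) -> float:
    """Summed semantic-similarity weight of induced edges, averaged.

    ``denominator="nodes"`` divides by the cluster size (the literal formula);
    ``denominator="edges"`` divides by the induced edge count (mean weight).
    A cluster inducing no edge scores 0.
    """
    members = set(members)
    weights = simnet.induced_edge_weights(members)
    if not weights:
        logger.debug("similarity: cluster of %d nodes induces no edge", len(members))
        return 0.0
    if denominator == "nodes":
        return sum(weights) / len(members)
    if denominator == "edges":
        return sum(weights) / len(weights)
    raise ValueError("denominator must be 'nodes' or 'edges'")


def evaluate(
    chrom: Chromosome,
    net: nx.Graph,
    cc: Mapping[str, float],
    simnet: SimilarityNetwork,
    cfg: AlgorithmConfig,
) -> Chromosome:
    """Return the chromosome with all configured objectives computed and cached."""
    if chrom.objectives is not None:
        return chrom
    density = None
    if cfg.use_density_objective:
        density = subgraph_density(net, chrom.members) if len(chrom.members) >= 2 else 0.0
    vec = ObjectiveVector(
        contribution=contribution_objective(net, chrom.members),
        closeness=closeness_objective(cc, chrom.members),
        similarity=similarity_objective(simnet, chrom.members, cfg.similarity_denominator),
        density=density,
    )
    return replace(chrom, objectives=vec)


# ---------------------------------------------------------------------------
# initialization: all-1s substructures of the adjacency matrix
# ---------------------------------------------------------------------------

def _grow_all_ones(net: nx.Graph, seed_edge: tuple[str, str], rng: np.random.Generator, max_size: int) -> frozenset[str]:
    """Randomized greedy expansion of an all-1s adjacency submatrix.

    With the diagonal treated as 1, a symmetric all-1s submatrix over node set
    S is exactly a clique on S; starting from a random edge, candidates are
    added in random order while S stays a clique (capped at ``max_size``).
    """
    members = set(seed_edge)
    adj = net.adj
    candidates = set(adj[seed_edge[0]]) & set(adj[seed_edge[1]]) - members
    while candidates and len(members) < max_size:
        order = sorted(candidates)
        x = order[rng.integers(len(order))]
        members.add(x)
        candidates = (candidates & set(adj[x])) - {x}
    return frozenset(members)


def initialize_population(
    net: nx.Graph,
    simnet: SimilarityNetwork,
    cfg: AlgorithmConfig,
    rng: np.random.Generator,
) -> Population:
    """Seed the population with dense substructures mined from the adjacency matrix.

    Each chromosome is the union of rows and columns of a randomly grown
    all-1s submatrix (a randomized maximal clique around a random edge).  If
    the bounded retry budget cannot produce ``population_size`` distinct
    member sets, the remainder is filled with random edges as 2-node
    chromosomes (logged).
    """
    edges = sorted(tuple(sorted(e)) for e in net.edges())
    if not edges:
        raise ValueError("network has no edges")
    seen: set[frozenset[str]] = set()
    individuals: list[Chromosome] = []
    attempts = 0
    max_attempts = 20 * cfg.population_size
    while len(individuals) < cfg.population_size and attempts < max_attempts:
        attempts += 1
        e = edges[rng.integers(len(edges))]
        members = _grow_all_ones(net, e, rng, cfg.max_size)
        if members in seen:
            continue
        seen.add(members)
        individuals.append(Chromosome(members))
    n_fill = cfg.population_size - len(individuals)
    if n_fill:
        logger.info("initialize_population: filling %d slots with random 2-node chromosomes", n_fill)
        for _ in range(n_fill):
            e = edges[rng.integers(len(edges))]
            individuals.append(Chromosome(frozenset(e)))
    return Population(individuals, generation=0, seed=cfg.seed)


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

def _largest_component(net: nx.Graph, members: set[str]) -> frozenset[str]:
    """Largest connected component of the induced subgraph (deterministic ties)."""
    components = list(nx.connected_components(net.subgraph(members)))
    if not components:
        return frozenset()
    best = max(components, key=lambda c: (len(c), tuple(sorted(c))))
    return frozenset(best)


def mutate(
    chrom: Chromosome,
    net: nx.Graph,
    cfg: AlgorithmConfig,
    rng: np.random.Generator,
) -> Chromosome:
    """Insertion/deletion mutation with connectivity repair.

    With probability ``mutation_probability``: select ceil(mutate_fraction * n)
    member nodes uniformly, then with equal probability either insert all of
    their direct network neighbors or delete the selected nodes.  The result is
    repaired to the largest connected component; if the repaired set violates
    the size bounds the input chromosome is returned unchanged.
    """
    if rng.random() >= cfg.mutation_probability:
        return chrom
    members = sorted(chrom.members)
    k = math.ceil(cfg.mutate_fraction * len(members))
    idx = rng.choice(len(members), size=k, replace=False)
    selected = {members[i] for i in np.atleast_1d(idx)}
    if rng.random() < 0.5:  # insertion
        new = set(chrom.members)
        for n in selected:
            new |= set(net.adj[n])
    else:  # deletion
        new = set(chrom.members) - selected
    if not new:
        return chrom
    repaired = _largest_component(net, new)
    if len(repaired) < max(2, cfg.min_size) or len(repaired) > cfg.max_size:
        # allow shrunken seeds to persist below min_size only if unchanged
        return chrom
    return Chromosome(repaired)


# ---------------------------------------------------------------------------
# NSGA-II machinery
# ---------------------------------------------------------------------------

def _dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Maximization dominance: a >= b everywhere and a > b somewhere."""
    ge = all(x >= y for x, y in zip(a, b))
    return ge and any(x > y for x, y in zip(a, b))


def fast_nondominated_sort(vectors: Sequence[Sequence[float]]) -> list[list[int]]:
    """Deb's fast non-dominated sort (maximization); returns index fronts."""
    n = len(vectors)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    domination_count = [0] * n
    fronts: list[list[int]] = [[]]
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(vectors[i], vectors[j]):
                dominated_by[i].append(j)
                domination_count[j] += 1
            elif _dominates(vectors[j], vectors[i]):
                dominated_by[j].append(i)
                domination_count[i] += 1
    for i in range(n):
        if domination_count[i] == 0:
            fronts[0].append(i)
    k = 0
    while fronts[k]:
        nxt: list[int] = []
        for i in fronts[k]:
            for j in dominated_by[i]:
                domination_count[j] -= 1
                if domination_count[j] == 0:
                    nxt.append(j)
        k += 1
        fronts.append(sorted(nxt))
    fronts.pop()
    return fronts


def crowding_distance(front: Sequence[Sequence[float]]) -> list[float]:
    """NSGA-II crowding distance within one front.

    Per objective, boundary points get infinity and interior points get the
    normalized gap between their neighbors; zero-range objectives contribute 0.
    Ties are broken by index order (stable sort), so duplicated vectors get
    finite, deterministic distances.
    """
    n = len(front)
    if n == 0:
        return []
    if n <= 2:
        return [math.inf] * n
    m = len(front[0])
    dist = [0.0] * n
    for obj in range(m):
        order = sorted(range(n), key=lambda i: (front[i][obj], i))
        lo, hi = front[order[0]][obj], front[order[-1]][obj]
        rng_ = hi - lo
        dist[order[0]] = math.inf
        dist[order[-1]] = math.inf
        if rng_ == 0.0:
            continue
        for pos in range(1, n - 1):
            i = order[pos]
            if dist[i] != math.inf:
                gap = front[order[pos + 1]][obj] - front[order[pos - 1]][obj]
                dist[i] += gap / rng_
    return dist


def _rank_and_crowd(vectors: Sequence[Sequence[float]]) -> tuple[list[int], list[float]]:
    fronts = fast_nondominated_sort(vectors)
    rank = [0] * len(vectors)
    crowd = [0.0] * len(vectors)
    for r, front in enumerate(fronts):
        dists = crowding_distance([vectors[i] for i in front])
        for i, d in zip(front, dists):
            rank[i] = r
            crowd[i] = d
    return rank, crowd


def _tournament(rng: np.random.Generator, rank: Sequence[int], crowd: Sequence[float]) -> int:
    i = int(rng.integers(len(rank)))
    j = int(rng.integers(len(rank)))
    if rank[i] != rank[j]:
        return i if rank[i] < rank[j] else j
    if crowd[i] != crowd[j]:
        return i if crowd[i] > crowd[j] else j
    return i if rng.random() < 0.5 else j


def run(
    net: nx.Graph,
    simnet: SimilarityNetwork,
    cfg: AlgorithmConfig,
    history: list[tuple[float, ...]] | None = None,
) -> Population:
    """Full generational NSGA-II loop; fully reproducible from ``cfg.seed``.

    Parents breed ``population_size`` offspring by crowded binary tournament
    plus mutation (no crossover); environmental selection keeps the best
    ``population_size`` of parents plus offspring by front rank, then crowding.
    If ``history`` is given, the per-generation maximum of each objective is
    appended to it.
    """
    rng = np.random.default_rng(cfg.seed)
    cc = closeness_centrality(net)
    cache: dict[frozenset[str], ObjectiveVector] = {}

    def _eval(ch: Chromosome) -> Chromosome:
        if ch.objectives is not None:
            return ch
        vec = cache.get(ch.members)
        if vec is None:
            vec = evaluate(ch, net, cc, simnet, cfg).objectives
            cache[ch.members] = vec
        return replace(ch, objectives=vec)

    pop = initialize_population(net, simnet, cfg, rng)
    pop.individuals = [_eval(ch) for ch in pop.individuals]
    if history is not None:
        vs = [ch.objectives.as_tuple() for ch in pop.individuals]
        history.append(tuple(max(v[k] for v in vs) for k in range(len(vs[0]))))
    for gen in range(cfg.generations):
        vectors = [ch.objectives.as_tuple() for ch in pop.individuals]
        rank, crowd = _rank_and_crowd(vectors)
        offspring = []
        for _ in range(cfg.population_size):
            parent = pop.individuals[_tournament(rng, rank, crowd)]
            offspring.append(_eval(mutate(parent, net, cfg, rng)))
        combined = pop.individuals + offspring
        comb_vectors = [ch.objectives.as_tuple() for ch in combined]
        fronts = fast_nondominated_sort(comb_vectors)
        survivors: list[int] = []
        for front in fronts:
            if len(survivors) + len(front) <= cfg.population_size:
                survivors.extend(front)
            else:
                dists = crowding_distance([comb_vectors[i] for i in front])
                order = sorted(range(len(front)), key=lambda k: (-dists[k], k))
                need = cfg.population_size - len(survivors)
                survivors.extend(front[k] for k in order[:need])
                break
        pop = Population([combined[i] for i in survivors], generation=gen + 1, seed=cfg.seed)
        if history is not None:
            vs = [ch.objectives.as_tuple() for ch in pop.individuals]
            history.append(tuple(max(v[k] for v in vs) for k in range(len(vs[0]))))
    return pop


# ---------------------------------------------------------------------------
# reading complexes off the final population
# ---------------------------------------------------------------------------

def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def extract_complexes(
    pop: Population,
    cfg: AlgorithmConfig,
    source: str = "front",
) -> ComplexCatalog:
    """Turn the final population into a predicted-complex catalog.

    ``source="front"`` (default) reads off the rank-1 Pareto front;
    ``source="population"`` reads off every distinct chromosome of the final
    population (useful because all objectives grow with cluster size, so the
    front concentrates on the largest modules while lower ranks may retain
    smaller locally optimal ones — see the methods note).

    Member sets below ``min_size`` are discarded, duplicates collapsed, and
    pairs with Jaccard >= ``merge_jaccard`` greedily merged to a fixpoint in a
    deterministic order (descending size, then lexicographic).
    """
    if source == "front":
        vectors = [ch.objectives.as_tuple() for ch in pop.individuals]
        keep_idx = fast_nondominated_sort(vectors)[0] if vectors else []
        pool = [pop.individuals[i] for i in keep_idx]
    elif source == "population":
        pool = list(pop.individuals)
    else:
        raise ValueError("source must be 'population' or 'front'")
    sets = {ch.members for ch in pool if len(ch.members) >= cfg.min_size}
    if not sets:
        logger.warning("extract_complexes: empty %s, returning empty catalog", source)
        return ComplexCatalog([])
    items = sorted(sets, key=lambda s: (-len(s), tuple(sorted(s))))
    merged = True
    while merged:
        merged = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if _jaccard(items[i], items[j]) >= cfg.merge_jaccard:
                    union = items[i] | items[j]
                    items = [s for k, s in enumerate(items) if k not in (i, j)]
                    items.append(union)
                    items = sorted(set(items), key=lambda s: (-len(s), tuple(sorted(s))))
                    merged = True
                    break
            if merged:
                break
    return ComplexCatalog.from_sets(items)
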