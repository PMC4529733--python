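"""scikit-learn style estimator wrapping the multiobjective complex search."""

from __future__ import annotations

import numbers

import networkx as nx
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .moea import AlgorithmConfig, extract_complexes, fast_nondominated_sort, run
from .network import ComplexCatalog
from .similarity import SimilarityNetwork

__all__ = ["ComplexDetector", "detect_complexes"]


def _as_graph(X) -> nx.Graph:
    if isinstance(X, nx.Graph):
        return X
    if sp.issparse(X) or isinstance(X, np.ndarray):
        graph = nx.from_scipy_sparse_array(sp.csr_matrix(X)) if sp.issparse(X) else nx.from_numpy_array(np.asarray(X))
        return nx.relabel_nodes(graph, {i: str(i) for i in graph.nodes})
    raise TypeError("X must be a networkx Graph or a (sparse) adjacency matrix")


class ComplexDetector(BaseEstimator):
    """Detect protein complexes in a PPI network by NSGA-II multiobjective search.

    Candidate complexes (connected subgraphs) evolve under maximization of a
    topological contribution score, summed whole-network closeness centrality,
    and averaged Gene-Ontology semantic-similarity edge weight; the final
    population is read off as the predicted complex catalog.

    Parameters
    ----------
    population_size : int, default=100
        Number of chromosomes kept after environmental selection.
    generations : int, default=200
        Generational loop length.
    mutation_probability : float, default=0.9
        Per-offspring probability of applying the insertion/deletion mutation.
    mutate_fraction : float, default=0.2
        Fraction of a chromosome's nodes selected per mutation.
    min_size, max_size : int, defaults 3 and 300
        Complex size bounds enforced by repair and extraction.
    use_density_objective : bool, default=False
        Add raw subgraph density as a fourth objective.
    similarity_denominator : {"nodes", "edges"}, default="nodes"
        Denominator of the similarity objective (cluster size, or induced
        edge count for a plain mean edge weight).
    merge_jaccard : float, default=0.8
        Near-duplicate complexes with Jaccard >= this are merged at extraction.
    extract_from : {"front", "population"}, default="front"
        Read predictions off the rank-1 Pareto front only, or off the whole
        final population.
    random_state : int or None, default=None
        Seed for the single RNG driving the whole run.

    Attributes
    ----------
    complexes_ : ComplexCatalog
        Predicted complexes (deduplicated, merged).
    population_ : Population
        Final evolved population with cached objective vectors.
    pareto_front_ : list of Chromosome
        Rank-1 subset of the final population.
    labels_ : dict
        Node -> predicted complex index (first containing complex, -1 if none).

    Examples
    --------
    >>> from mocplex.synth import SyntheticSpec, generate_planted_network
    >>> net, simnet, truth = generate_planted_network(SyntheticSpec(seed=0))
    >>> det = ComplexDetector(population_size=20, generations=10, random_state=0)
    >>> catalog = det.fit(net, similarity=simnet).complexes_
    """

    def __init__(
        self,
        population_size: int = 100,
        generations: int = 200,
        mutation_probability: float = 0.9,
        mutate_fraction: float = 0.2,
        min_size: int = 3,
        max_size: int = 300,
        use_density_objective: bool = False,
        similarity_denominator: str = "nodes",
        merge_jaccard: float = 0.8,
        extract_from: str = "front",
        random_state: int | None = None,
    ):
        self.population_size = population_size
        self.generations = generations
        self.mutation_probability = mutation_probability
        self.mutate_fraction = mutate_fraction
        self.min_size = min_size
        self.max_size = max_size
        self.use_density_objective = use_density_objective
        self.similarity_denominator = similarity_denominator
        self.merge_jaccard = merge_jaccard
        self.extract_from = extract_from
        self.random_state = random_state

    def _config(self) -> AlgorithmConfig:
        if self.random_state is None:
            seed = int(np.random.SeedSequence().entropy % (2**31))
        elif isinstance(self.random_state, numbers.Integral):
            seed = int(self.random_state)
        else:
            raise TypeError("random_state must be an int or None")
        return AlgorithmConfig(
            population_size=self.population_size,
            generations=self.generations,
            mutation_probability=self.mutation_probability,
            mutate_fraction=self.mutate_fraction,
            min_size=self.min_size,
            max_size=self.max_size,
            seed=seed,
            use_density_objective=self.use_density_objective,
            similarity_denominator=self.similarity_denominator,
            merge_jaccard=self.merge_jaccard,
        )

    def fit(self, X, y=None, similarity: SimilarityNetwork | None = None):
        """Run the evolutionary search on network ``X``.

        ``X`` is a :class:`networkx.Graph` or an adjacency matrix; ``similarity``
        is the edge-weighted semantic-similarity network (all weights default
        to 0 when omitted, silencing the GO objective).
        """
        net = _as_graph(X)
        if net.number_of_edges() == 0:
            raise ValueError("network has no edges")
        if similarity is None:
            similarity = SimilarityNetwork.from_weights(net, 0.0)
        cfg = self._config()
        self.history_: list[tuple[float, ...]] = []
        self.population_ = run(net, similarity, cfg, history=self.history_)
        vectors = [ch.objectives.as_tuple() for ch in self.population_.individuals]
        front_idx = fast_nondominated_sort(vectors)[0]
        self.pareto_front_ = [self.population_.individuals[i] for i in front_idx]
        self.complexes_ = extract_complexes(self.population_, cfg, source=self.extract_from)
        self.labels_ = {}
        for node in net.nodes:
            self.labels_[node] = -1
            for idx, (_, members) in enumerate(self.complexes_):
                if node in members:
                    self.labels_[node] = idx
                    break
        self.n_complexes_ = len(self.complexes_)
        return self

    def fit_predict(self, X, y=None, similarity: SimilarityNetwork | None = None):
        """Fit and return per-node complex labels (sorted node order; -1 = none)."""
        self.fit(X, y=y, similarity=similarity)
        return np.array([self.labels_[n] for n in sorted(self.labels_)])


def detect_complexes(net, similarity=None, **params) -> ComplexCatalog:
    """Functional one-shot wrapper around :class:`ComplexDetector`."""
    return ComplexDetector(**params).fit(net, similarity=similarity).complexes_
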