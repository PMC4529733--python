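import itertools
import math
import random

import networkx as nx
import numpy as np
import pytest

from mocplex.detect import ComplexDetector, detect_complexes
from mocplex.moea import (
    AlgorithmConfig,
    Chromosome,
    ObjectiveVector,
    closeness_objective,
    contribution_objective,
    crowding_distance,
    evaluate,
    extract_complexes,
    fast_nondominated_sort,
    initialize_population,
    mutate,
    run,
    similarity_objective,
    Population,
)
from mocplex.network import closeness_centrality
from mocplex.similarity import SimilarityNetwork


def _bruteforce_fronts(vectors):
    """O(n^2) front assignment by repeated removal of non-dominated points."""
    def dominates(a, b):
        return all(x >= y for x, y in zip(a, b)) and any(x > y for x, y in zip(a, b))

    remaining = list(range(len(vectors)))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(dominates(vectors[j], vectors[i]) for j in remaining if j != i)
        ]
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


@pytest.fixture
def triangle_with_externals():
    """Triangle a-b-c where each member has exactly one extra external neighbor."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"), ("a", "x"), ("b", "y"), ("c", "z")])
    return g


class TestObjectives:
    def test_contribution_isolated_triangle(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert contribution_objective(g, {"a", "b", "c"}) == 3.0

    def test_contribution_triangle_with_external_neighbors(self, triangle_with_externals):
        assert contribution_objective(triangle_with_externals, {"a", "b", "c"}) == pytest.approx(2.0)

    def test_contribution_isolated_edge(self):
        g = nx.Graph([("a", "b")])
        assert contribution_objective(g, {"a", "b"}) == 2.0

    def test_contribution_degree_zero_node_contributes_zero(self):
        g = nx.Graph([("a", "b")])
        g.add_node("iso")
        assert contribution_objective(g, {"a", "b", "iso"}) == 2.0

    def test_closeness_sum_star(self, star4):
        cc = closeness_centrality(star4)
        assert closeness_objective(cc, {"c", "l1"}) == pytest.approx(1.6)

    def test_closeness_sum_k4(self, k4):
        cc = closeness_centrality(k4)
        assert closeness_objective(cc, set(k4.nodes)) == pytest.approx(4.0)

    def test_closeness_missing_node_is_error(self, k4):
        with pytest.raises(KeyError):
            closeness_objective(closeness_centrality(k4), {"nope"})

    def test_similarity_triangle_node_denominator(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        simnet = SimilarityNetwork.from_weights(
            g, {("a", "b"): 0.9, ("b", "c"): 0.6, ("a", "c"): 0.3}
        )
        assert similarity_objective(simnet, {"a", "b", "c"}, "nodes") == pytest.approx(0.6)
        assert similarity_objective(simnet, {"a", "b", "c"}, "edges") == pytest.approx(0.6)

    def test_similarity_single_edge_exposes_denominator_choice(self):
        g = nx.Graph([("a", "b")])
        simnet = SimilarityNetwork.from_weights(g, {("a", "b"): 0.8})
        assert similarity_objective(simnet, {"a", "b"}, "nodes") == pytest.approx(0.4)
        assert similarity_objective(simnet, {"a", "b"}, "edges") == pytest.approx(0.8)

    def test_similarity_no_induced_edges_is_zero(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        simnet = SimilarityNetwork.from_weights(g, 0.5)
        assert similarity_objective(simnet, {"a", "c"}, "nodes") == 0.0

    def test_evaluate_composes_and_caches(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        simnet = SimilarityNetwork.from_weights(g, 1.0)
        cfg = AlgorithmConfig(population_size=4, generations=1)
        cc = closeness_centrality(g)
        ch = evaluate(Chromosome(frozenset("abc")), g, cc, simnet, cfg)
        assert ch.objectives.contribution == 3.0
        assert ch.objectives.similarity == pytest.approx(1.0)
        assert ch.objectives.closeness == pytest.approx(closeness_objective(cc, set("abc")))
        again = evaluate(ch, g, cc, simnet, cfg)
        assert again.objectives == ch.objectives


class TestNondominatedSort:
    def test_worked_example(self):
        fronts = fast_nondominated_sort([(2, 2), (1, 1), (0, 3)])
        assert fronts == [[0, 2], [1]]

    def test_identical_points_single_front(self):
        assert fast_nondominated_sort([(1, 1)] * 5) == [[0, 1, 2, 3, 4]]

    def test_matches_bruteforce_oracle(self):
        rng = random.Random(5)
        for _ in range(40):
            n = rng.randint(1, 50)
            m = rng.randint(2, 4)
            vectors = [tuple(rng.randint(0, 5) for _ in range(m)) for _ in range(n)]
            assert fast_nondominated_sort(vectors) == _bruteforce_fronts(vectors)


class TestCrowdingDistance:
    def test_two_point_front_both_infinite(self):
        assert crowding_distance([(1, 2), (3, 4)]) == [math.inf, math.inf]

    def test_equally_spaced_interior_point(self):
        d = crowding_distance([(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)])
        assert d[0] == math.inf and d[2] == math.inf
        assert d[1] == pytest.approx(2.0)  # 1.0 per objective after normalization

    def test_duplicates_get_finite_deterministic_distances(self):
        d = crowding_distance([(1.0, 1.0)] * 4)
        assert d[0] == math.inf and d[3] == math.inf  # boundary by index order
        assert d[1] == 0.0 and d[2] == 0.0


class TestInitialization:
    def _cfg(self, **kw):
        defaults = dict(population_size=10, generations=1, seed=0)
        defaults.update(kw)
        return AlgorithmConfig(**defaults)

    def test_k4_expansion_reaches_full_clique(self, k4):
        simnet = SimilarityNetwork.from_weights(k4, 0.5)
        rng = np.random.default_rng(0)
        pop = initialize_population(k4, simnet, self._cfg(), rng)
        assert frozenset(k4.nodes) in {ch.members for ch in pop.individuals}

    def test_pendant_breaks_expansion(self, triangle_pendant):
        simnet = SimilarityNetwork.from_weights(triangle_pendant, 0.5)
        rng = np.random.default_rng(1)
        pop = initialize_population(triangle_pendant, simnet, self._cfg(), rng)
        sets = {ch.members for ch in pop.individuals}
        # the only all-1s substructures are the triangle and single edges
        assert sets <= {
            frozenset("abc"), frozenset("ab"), frozenset("bc"), frozenset("ac"),
            frozenset("ad"),
        }
        assert frozenset("abc") in sets

    def test_seeded_initialization_is_reproducible(self, k4):
        simnet = SimilarityNetwork.from_weights(k4, 0.5)
        pops = [
            initialize_population(k4, simnet, self._cfg(), np.random.default_rng(7))
            for _ in range(2)
        ]
        assert [c.members for c in pops[0].individuals] == [c.members for c in pops[1].individuals]


class TestMutation:
    def _cfg(self, **kw):
        defaults = dict(population_size=4, generations=1, mutation_probability=1.0, seed=0)
        defaults.update(kw)
        return AlgorithmConfig(**defaults)

    def test_insertion_adds_neighbors_of_selected(self):
        g = nx.Graph([("1", "2"), ("2", "3"), ("2", "4")])
        cfg = self._cfg(mutate_fraction=1.0, min_size=2)
        # force insertion by retrying until one happens (seeded, deterministic)
        rng = np.random.default_rng(3)
        results = {mutate(Chromosome(frozenset({"1", "2"})), g, cfg, rng).members for _ in range(20)}
        assert frozenset({"1", "2", "3", "4"}) in results

    def test_deletion_that_disconnects_reverts(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        cfg = self._cfg(min_size=3, mutate_fraction=0.3)
        chrom = Chromosome(frozenset("abc"))
        rng = np.random.default_rng(0)
        for _ in range(30):
            out = mutate(chrom, g, cfg, rng)
            # any deletion disconnects or shrinks below min size, so output is
            # either the input or an insertion-grown superset (none exists here)
            assert out.members == chrom.members

    def test_zero_probability_is_identity(self, k4):
        cfg = AlgorithmConfig(population_size=4, generations=1, mutation_probability=1e-12)
        chrom = Chromosome(frozenset(k4.nodes))
        rng = np.random.default_rng(0)
        assert mutate(chrom, k4, cfg, rng).members == chrom.members

    def test_chromosomes_stay_connected_and_bounded(self):
        g = nx.gnp_random_graph(30, 0.15, seed=2)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        simnet = SimilarityNetwork.from_weights(g, 0.5)
        cfg = AlgorithmConfig(population_size=12, generations=8, min_size=3, max_size=12, seed=5)
        pop = run(g, simnet, cfg)
        for ch in pop.individuals:
            assert len(ch.members) <= cfg.max_size
            if len(ch.members) >= 2:
                assert nx.is_connected(g.subgraph(ch.members))


class TestRun:
    def test_zero_generations_returns_initial_population(self, k4):
        simnet = SimilarityNetwork.from_weights(k4, 0.5)
        cfg = AlgorithmConfig(population_size=6, generations=0, seed=1)
        pop = run(k4, simnet, cfg)
        assert pop.generation == 0 and len(pop.individuals) == 6

    def test_equal_seeds_give_identical_populations(self):
        g = nx.gnp_random_graph(25, 0.2, seed=3)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        simnet = SimilarityNetwork.from_weights(g, 0.7)
        cfg = AlgorithmConfig(population_size=10, generations=10, seed=9)
        p1 = run(g, simnet, cfg)
        p2 = run(g, simnet, cfg)
        assert [c.members for c in p1.individuals] == [c.members for c in p2.individuals]

    def test_elitism_best_objective_never_decreases(self):
        g = nx.gnp_random_graph(30, 0.15, seed=8)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        simnet = SimilarityNetwork.from_weights(g, 0.6)
        history: list = []
        cfg = AlgorithmConfig(population_size=16, generations=20, seed=2)
        run(g, simnet, cfg, history=history)
        arr = np.array(history)
        assert np.all(np.diff(arr, axis=0) >= -1e-12)

    def test_recovers_single_planted_clique(self):
        # one dense planted module inside background noise: the front must
        # contain a chromosome matching it exactly
        rng = random.Random(0)
        g = nx.Graph()
        clique = [f"c{i}" for i in range(5)]
        g.add_edges_from(itertools.combinations(clique, 2))
        noise = [f"b{i}" for i in range(15)]
        for u, v in itertools.combinations(noise, 2):
            if rng.random() < 0.08:
                g.add_edge(u, v)
        g.add_edge(clique[0], noise[0])  # connect module to background
        weights = {
            tuple(sorted(e)): (0.9 if e[0][0] == "c" and e[1][0] == "c" else 0.1)
            for e in g.edges()
        }
        simnet = SimilarityNetwork.from_weights(g, weights)
        cfg = AlgorithmConfig(population_size=20, generations=50, seed=1, max_size=10)
        pop = run(g, simnet, cfg)
        vectors = [ch.objectives.as_tuple() for ch in pop.individuals]
        front = {pop.individuals[i].members for i in fast_nondominated_sort(vectors)[0]}
        assert frozenset(clique) in front


class TestExtractComplexes:
    def _pop(self, sets):
        vec = ObjectiveVector(1.0, 1.0, 1.0)
        return Population([Chromosome(frozenset(s), vec) for s in sets])

    def test_duplicates_collapse(self):
        cfg = AlgorithmConfig(population_size=4, generations=1)
        cat = extract_complexes(self._pop(["ABC", "ABC"]), cfg)
        assert cat.member_sets == [frozenset("ABC")]

    def test_below_merge_threshold_kept_separate(self):
        cfg = AlgorithmConfig(population_size=4, generations=1, merge_jaccard=0.8)
        cat = extract_complexes(self._pop(["ABCD", "ABCE"]), cfg)
        assert set(cat.member_sets) == {frozenset("ABCD"), frozenset("ABCE")}

    def test_above_merge_threshold_merged_to_union(self):
        cfg = AlgorithmConfig(population_size=4, generations=1, merge_jaccard=0.5)
        cat = extract_complexes(self._pop(["ABCD", "ABCE"]), cfg)
        assert cat.member_sets == [frozenset("ABCDE")]

    def test_small_sets_filtered(self):
        cfg = AlgorithmConfig(population_size=4, generations=1, min_size=3)
        cat = extract_complexes(self._pop(["AB", "XYZ"]), cfg)
        assert cat.member_sets == [frozenset("XYZ")]


class TestComplexDetectorEstimator:
    def test_sklearn_param_interface(self):
        det = ComplexDetector(population_size=8, generations=2)
        params = det.get_params()
        assert params["population_size"] == 8
        det.set_params(generations=3)
        assert det.generations == 3

    def test_fit_sets_attributes_and_is_reproducible(self, k4):
        det = ComplexDetector(population_size=8, generations=3, random_state=0)
        det.fit(k4)
        assert hasattr(det, "complexes_") and hasattr(det, "pareto_front_")
        labels = det.fit_predict(k4)
        assert len(labels) == 4
        det2 = ComplexDetector(population_size=8, generations=3, random_state=0).fit(k4)
        assert det.complexes_.member_sets == det2.complexes_.member_sets

    def test_accepts_adjacency_matrix(self):
        adj = nx.to_numpy_array(nx.complete_graph(5))
        det = ComplexDetector(population_size=8, generations=2, random_state=1)
        det.fit(adj)
        assert det.n_complexes_ >= 1

    def test_functional_wrapper(self, k4):
        cat = detect_complexes(k4, population_size=8, generations=2, random_state=0)
        assert frozenset(k4.nodes) in set(cat.member_sets)
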