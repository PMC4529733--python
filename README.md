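# mocplex

Multiobjective evolutionary detection of protein complexes in
protein–protein interaction (PPI) networks, with Gene-Ontology–aware
objectives, standard complex-matching evaluation metrics, and
disease/disorder association analysis.

## The problem

Protein complexes — groups of proteins that physically associate to carry out
a cellular function — appear in a PPI network as dense, functionally coherent
subgraphs. `mocplex` casts their detection as a multiobjective optimization
problem and solves it with NSGA-II: a candidate complex is encoded directly
as a connected node subset *C* of the PPI graph (a chromosome), and three
objectives are maximized simultaneously:

- **contribution** (topological):
  `sum_{n in C} |N_C(n)| / deg(n)`, where `N_C(n)` are the neighbors of `n`
  inside `C` and `deg(n)` its whole-network degree — rewards modules whose
  members keep most of their interactions internal;
- **closeness** (topological):
  `sum_{n in C} CC(n)`, where `CC(n)` is whole-network closeness centrality
  (reachable-count over summed BFS distances) — rewards central modules;
- **semantic coherence** (biological):
  `sim(C) = sum_{(u,v) in E(C)} w(u,v) / |C|`, where `w(u,v) in [0,1]` is the
  Relevance GO semantic similarity between the interacting proteins
  (`sum / |E(C)|`, i.e. the mean edge weight, is available via
  `similarity_denominator="edges"`).

Relevance similarity between two GO terms is Lin's information-content ratio
damped by the annotation probability of the best common ancestor *a*:
`sim_Rel(t1,t2) = max_a [2 IC(a) / (IC(t1)+IC(t2))] * [1 - p(a)]`, with
`IC(t) = -ln p(t)` from annotation frequencies propagated over the GO DAG;
protein-level similarity is the mean over all GO-term cross pairs.

The evolutionary loop is conventional NSGA-II — fast non-dominated sorting,
crowding distance, crowded binary tournaments, elitist selection on parents
plus offspring — except that there is **no crossover** (it mostly produces
disconnected subgraphs). Variation is an insertion/deletion mutation (with
probability 0.9, a random subset of member nodes is picked; insertion adds
all their direct neighbors, deletion removes them, each with probability
0.5), followed by repair to the largest connected component. The population
is seeded with all-1s substructures of the adjacency matrix (randomized
maximal cliques grown around random edges).

Predictions are compared against a reference catalog with the standard
contingency-table statistics — Sensitivity (size-weighted best coverage of
real complexes), Positive Predictive Value (column-weighted best purity of
predicted complexes) and their geometric mean Accuracy — and with
Jaccard-threshold precision–recall curves (`J(B_i, C_j) > t` counts as
covered) and their AUC. Predicted complexes are associated with genetic
disorders by the all-genes rule (a disorder maps to a complex iff *all* its
genes are members) and summarised over the 22 primary diseasome disease
classes as bipartite networks and per-class subnetwork metrics.

A seeded synthetic-data module generates planted-partition benchmarks
(dense planted complexes in a sparse background, similarity weights high
inside / low outside, a toy GO hierarchy, and a diseasome-style disorder
catalog) so that the whole stack is testable without any download.

## Worked example

```python
from mocplex import (
    ComplexDetector, SyntheticSpec, generate_study,
    contingency, sensitivity, ppv, accuracy,
    precision_recall_curve, mean_best_match_jaccard, complex_class_network,
)

spec = SyntheticSpec(n_complexes=4, size_range=(5, 8), n_background=30)
net, simnet, truth, dag, ann, disorders = generate_study(spec, seed=42)
print(f"network: {net.number_of_nodes()} proteins, {net.number_of_edges()} interactions")

det = ComplexDetector(population_size=30, generations=40, max_size=15, random_state=42)
det.fit(net, similarity=simnet)
print(f"predicted complexes: {det.n_complexes_} "
      f"(sizes {sorted(len(s) for s in det.complexes_.member_sets)})")

ct = contingency(truth, det.complexes_)
sn, pv = sensitivity(ct), ppv(ct)
curve = precision_recall_curve(truth, det.complexes_)
print(f"Sn = {sn:.4f}  PPV = {pv:.4f}  Acc = {accuracy(sn, pv):.4f}  AUC = {curve.auc:.4f}")
print(f"mean best-match Jaccard vs planted truth: "
      f"{mean_best_match_jaccard(truth, det.complexes_):.4f}")

classes = complex_class_network(det.complexes_, disorders, net)
print(f"complex-class associations: {len(classes.edges)} edges, "
      f"total weight {classes.total_weight}")
```

prints

```
network: 58 proteins, 117 interactions
predicted complexes: 8 (sizes [10, 10, 10, 13, 15, 15, 17, 17])
Sn = 0.7857  PPV = 0.7273  Acc = 0.7559  AUC = 0.7559
mean best-match Jaccard vs planted truth: 0.5118
complex-class associations: 82 edges, total weight 108
```

Sensitivity 0.79 says the predicted catalog covers most members of each
planted complex; PPV 0.73 says predicted complexes are mostly made of
proteins from a single planted complex; Accuracy is their geometric mean, and
the AUC summarizes the Jaccard precision–recall curve swept over coverage
thresholds 0.00–1.00. The mean best-match Jaccard of 0.51 reflects the
method's known bias toward merged, oversized modules (see
`docs/methods.md`). The class network links each predicted complex to the
disease classes whose disorders satisfy the all-genes rule, weighted by
disorder count.

`ComplexDetector` is a scikit-learn style estimator (`get_params` /
`set_params` / `fit` / `fit_predict`); the same functionality is available
functionally (`mocplex.moea.run`, `mocplex.detect_complexes`) and from the
command line:

```bash
mocplex synth --outdir data --seed 1
mocplex detect --network data/network.tsv --weights data/weights.tsv \
        --seed 1 --out predicted.tsv
mocplex evaluate --benchmark data/truth.tsv --predicted predicted.tsv \
        --out metrics.tsv --curve curve.tsv
mocplex associate --predicted predicted.tsv --disorders data/disorders.tsv \
        --network data/network.tsv --out-prefix assoc
mocplex summary --network data/network.tsv
```

All inputs and outputs are plain tab-separated text (HPRD-style edge lists,
PCDq-style one-complex-per-line catalogs, 3-column similarity weight files,
OBO or child–parent ontology tables, GAF-like annotations, 3-column
gene/disorder/class tables).

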