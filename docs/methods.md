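# Methods

## Model and search procedure

`mocplex` treats protein-complex detection as multiobjective subgraph
optimization over a simple undirected PPI graph. A candidate complex is a
connected node subset ("chromosome"); no binary masks or crossover are used,
because recombining two connected subgraphs almost always yields a
disconnected one. Three objectives are maximized jointly under NSGA-II:

1. **Contribution** `sum_{n in C} |N_C(n)| / deg(n)` — each member contributes
   the fraction of its whole-network interactions that stay inside the
   cluster. A node with network degree 0 contributes 0 rather than raising a
   division error.
2. **Closeness** `sum_{n in C} CC(n)` — closeness centrality is precomputed
   once on the whole network, not on the candidate subgraph. Because real PPI
   networks are disconnected (hundreds of components), we use the
   reachable-only form `CC(v) = |R(v)| / sum_{u in R(v)} d(v,u)` (component-
   local reciprocal mean distance); isolated nodes get 0. This is defined
   everywhere and deterministic.
3. **Semantic coherence** `sim(C) = sum of induced edge weights / |C|`.
   Dividing by the node count is the formula-literal reading; dividing by the
   induced edge count (a plain mean edge weight) is the "averaging the edge
   weights" reading. Both are implemented (`similarity_denominator`, default
   `"nodes"`); they coincide whenever `|E(C)| = |C|` (e.g. a triangle) and
   differ elsewhere, so the choice is explicit and logged.

Raw subgraph density `|E(C)| / (|C| choose 2)` is available as an optional
fourth objective (`use_density_objective`, default off): the contribution sum
already acts as the normalized internal-density objective, and with three
objectives fronts stay better populated.

### Semantic similarity

Term-level similarity is Schlicker's Relevance measure,
`max_a [2 IC(a)/(IC(t1)+IC(t2))] * [1 - p(a)]` over common ancestors *a*
(each term is its own ancestor), with `p(t)` the fraction of annotated
proteins annotated to *t* or any descendant and `IC = -ln p`. Natural log is
used; since IC only enters as a ratio and `(1 - p)` is log-free, the
similarity itself is base-invariant. Protein similarity is the arithmetic
mean over all GO-term cross pairs within a single aspect (not best-match
averaging) — the cross-pair mean is what the edge-weighting step expects.
The default aspect is BP, configurable to CC or MF; whether to mix aspects
is genuinely open, so it is exposed as configuration rather than decided
silently. Unannotated proteins score 0, so GO-silent edges neither help nor
hurt the coherence objective.

### Initialization

The population is seeded with "all-1s substructures" of the adjacency
matrix. With the diagonal treated as 1, a symmetric all-1s submatrix over a
node set is exactly a clique, so seeding draws a random edge and greedily
adds random common neighbors while the set stays a clique (capped at
`max_size`). Asymmetric row/column growth was considered and rejected: it
also admits star-shaped submatrices (rows {a} x columns {b, d}), which are
poor seeds for density-driven search. If the bounded retry budget (20x the
population size) cannot produce enough distinct sets, remaining slots are
filled with random edges as 2-node chromosomes and the shortfall is logged.

### Variation and repair

With probability `mutation_probability` (0.9, the published setting),
`ceil(mutate_fraction * |C|)` member nodes are selected uniformly; with equal
probability either all their direct network neighbors are inserted or the
selected nodes are deleted. The result is repaired to the largest connected
component of the induced subgraph (ties broken deterministically by size then
lexicographic order); if the repaired set violates the size bounds
`[min_size, max_size]` the input chromosome is returned unchanged. The repair
rule is the counterpart of rejecting crossover: the chromosome invariant is
connectivity.

### Selection

Standard NSGA-II: fast non-dominated sorting under maximization dominance,
crowding distance with infinite distance at per-objective boundaries (ties
broken by index order, so duplicated vectors get finite deterministic
distances; zero-range objectives contribute 0), crowded binary tournament
(rank, then crowding, then a seeded coin flip), and elitist environmental
selection on parents plus offspring. Elitism implies the per-generation best
of each objective never decreases, which is property-tested.

### Reading off complexes

`extract_complexes` takes the rank-1 front of the final population
(`source="front"`, default; `source="population"` uses every individual),
drops member sets below `min_size`, deduplicates, and greedily merges pairs
with Jaccard ≥ `merge_jaccard` (default 0.8) to a fixpoint in a deterministic
order (descending size, then lexicographic member order). The merge threshold
controls how aggressively near-duplicate front members collapse.

## Evaluation metrics

Sensitivity `sum_i N_i max_j T_ij/N_i / sum_i N_i`, PPV
`sum_j T_.j max_i T_ij/T_.j / sum_j T_.j` and Accuracy `sqrt(Sn * PPV)` are
computed from the protein-overlap contingency table; empty columns contribute
0 to both PPV sums so all metrics are total functions. Note that the PPV
identity "predicted == reference implies PPV = 1" holds only for references
whose complexes are mutually disjoint: the column-sum denominator counts
every overlap, so a self-overlapping catalog scores below 1 against itself.
This is a property of the measure, not of the implementation.

The precision–recall curve sweeps a Jaccard threshold `t` over
0.00, 0.05, …, 1.00; a benchmark (predicted) complex counts as covered at `t`
when its best Jaccard against the other catalog **strictly exceeds** `t`.
Recall and precision are covered-complex counts over catalog sizes
(size-weighted variants via `weighted=True`). The AUC is the trapezoid over
the swept (recall, precision) points restricted to recall > 0, with ties in
recall averaged and the lowest-recall precision extended flat to recall 0 —
a perfect prediction scores exactly 1. Proteins present in only one catalog
are kept; the formulas are intersection-based and need no universe
restriction.

## Disorder association

A disorder is associated with a complex iff its full gene set is contained in
the complex (all-genes rule). Disorders with no genes at all in the analysis
network can be excluded from consideration (and are logged); genes assigned
to several classes arrive only via the catalog's own 'Multiple' class — no
reclassification is done. The complex–class network weights each edge by the
number of the class's disorders associated with the complex, so collapsing
the complex–disorder network by class reproduces it exactly (a conservation
identity used as a property test). Per-class metrics (gene count, induced
interaction count, density, mean semantic similarity) average similarity over
*all* unordered gene pairs of the class, not only interacting pairs, since
the similarity column is meant to be contrasted with PPI density as an
independent signal.

## Synthetic benchmark

`SyntheticSpec` defaults define the package's reference study: 8 node-disjoint
planted complexes of 6–12 proteins with within-complex edge probability 0.9,
a 100-node background wired at p_out = 0.02, and truncated-normal similarity
weights (mean 0.9 inside complexes, 0.1 elsewhere, sd 0.05). The 100-node
background is sized so that roughly half of all edges are background noise —
enough to make detection non-trivial while keeping a full search (population
100, 150 generations) around twenty seconds on one CPU; the methods' test and
acceptance runs use these sizes throughout. The toy ontology is a depth-4,
branching-3 BP tree; each planted complex shares one deep (high-IC) term and
background proteins are annotated just below the root, so same-complex pairs
have high Relevance similarity and cross-complex pairs low. Disorders are
small gene subsets of single planted complexes (the all-genes rule fires)
plus decoys spanning two complexes (it cannot), assigned round-robin to the
22 diseasome classes. All generators are pure functions of (spec, seed).

What the generator does *not* emulate: scale-free degree structure, overlap
between true complexes (an option exists but is off by default), annotation
noise or missing annotations, and confidence-scored interactions. Passing
tests on this benchmark therefore demonstrate correctness of the machinery
and recoverability under idealized module structure, not performance on real
interactome data.

## Known limitations

The three objectives are all sums over cluster members or edges, so each is
monotone non-decreasing in cluster size for fixed per-node quality. Two
consequences follow.

First, the method is biased toward large modules: growth that does not dilute
semantic coherence is always non-dominated, so the Pareto front is a sweep
from coherent cores to large unions (on real interactome data this shows up
as predicted complexes spanning tens to hundreds of proteins).

Second, on a homogeneous planted benchmark — where every planted complex has
the same edge-weight and centrality texture and differs only in size — the
objective vectors of the planted complexes are totally ordered by size:
every smaller complex is strictly dominated by every larger disjoint one, at
every generation. NSGA-II selection therefore culls all but the largest
complex's neighborhood, and *no* read-off of the run (rank-1 front, whole
final population, or an archive across generations) retains the smaller
planted modules. Empirically, the reference benchmark yields mean best-match
Jaccard around 0.3 (the largest complexes recovered exactly, the rest matched
only by unions containing them), and the idealized regime p_in = 1,
p_out = 0 collapses to the single largest planted clique. A single planted
module, by contrast, is recovered exactly (property-tested). Recovering many
same-texture modules simultaneously would require objectives normalized per
node (means rather than sums), niching, or per-seed restarts — all outside
the method as defined.

Numerical conventions: degenerate inputs never raise during search
(degree-0 nodes and edge-less clusters contribute 0 and are logged); all
RNG flows from one integer seed through `numpy.random.Generator`, node
ordering is always sorted before sampling, and byte-identical outputs for
identical seeds are property-tested end to end.
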