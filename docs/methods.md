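# Methods

This note documents the models, algorithmic choices, defaults and known
limitations of `commexplain`, in the spirit of a statistical software
methods appendix. Everything quantitative stated here is computed by the
test suite or `scripts/acceptance.py`; nothing is asserted that the code
does not measure.

## Problem and pipeline

Stochastic community-finding algorithms produce different partitions on
different seeded runs. The pipeline explains two aspects of that
behaviour on a given graph:

1. **Node level** — why is a node consistently assigned (easy to
   cluster) or oscillating between communities (hard)?
2. **Pair level** — why do two nodes usually share, or not share, a
   community?

Both are cast as binary classification problems whose labels come from
the algorithm's own behaviour over `R` runs, and whose inputs are
interpretable graph metrics. Feature rankings by permutation importance,
aggregated over many graphs and compared nonparametrically, are the
explanation.

## Graph generation

Experiment graphs come from the LFR benchmark as implemented in
networkx (`LFR_benchmark_graph`), with defaults matching the study
setting this package reproduces: `n = 1000`, degree exponent
`tau1 = 3`, community-size exponent `tau2 = 2`, average degree 20,
maximum degree 50, mixing parameter `mu ∈ {0.2, 0.3, 0.4}`. Self-loops
are removed; generation retries with derived seeds until the graph is
connected (the shortest-path features require it), capped at 100
attempts.

Two properties of this generator matter for interpretation and are
deliberately left as-is rather than corrected, because the study data
came from the same implementation:

* the realized degrees overshoot the nominal parameters (mean degree
  ≈ 25 rather than 20; a handful of nodes exceed the max-degree cap by
  up to ~15%);
* the realized mixing is roughly 1.7× the nominal `mu` (at `mu = 0.2`
  about 34% of edges are inter-community, not 20%), because the
  generator overlays more between-community edges than the nominal
  fraction. The planted labels remain correct (Louvain recovers them
  with NMI ≈ 0.98 at `mu = 0.2`), and mixing is strictly monotone in
  `mu`, which is what the experiments rely on.

A planted-partition (stochastic block model) generator and a
two-cliques-plus-bridge barbell fixture provide fast, hand-checkable
graphs for testing; they are first-class generators with the same
simplicity/connectivity guarantees, not production defaults.

## Community-finding algorithms

Three algorithms are wrapped behind one seeded interface
(`run_once` / `run_ensemble`); ensemble run `r` uses seed
`base_seed + r`, making every ensemble reproducible end to end.

* **Louvain** — igraph's C multilevel modularity optimization,
  resolution 1.0; the final (coarsest) hierarchy level is the partition.
* **Infomap** — igraph's two-level map-equation optimization with one
  optimization trial per run (igraph's default best-of-10 would make
  runs artificially stable; one trial per run matches "run the
  algorithm R times").
* **LPA** — networkx's asynchronous label propagation: uniform-random
  node order, uniform tie-breaking among majority labels, stopping when
  every node holds a majority label of its neighbours. igraph's label
  propagation variant uses a different stopping rule and produces
  measurably different entropy profiles; the networkx implementation
  follows the original algorithm exactly and is used instead.

Partitions are dense integer label arrays; labels are run-local, and all
downstream consumers are invariant to bijective relabelling (tested).

A run is **degenerate** when its largest community exceeds half the
nodes; a graph is degenerate when more than half its runs are, and a
grid cell is excluded when more than half its graphs are. These 50%
thresholds operationalize "clustered a majority of nodes into one large
community"; label propagation at `mu = 0.4` trips them reliably.

## Coassociation, entropy, labels

`C_ij` is the fraction of runs in which `i` and `j` share a community
(symmetric, unit diagonal, entries are counts over `R`). Node entropy is
the row mean of `p_ij = −C_ij log₂ C_ij` over all `j` including the
diagonal (which contributes 0); it is a mean of per-pair entropy terms,
not a distribution entropy, and is bounded by `log₂(e)/e ≈ 0.531`.

Easy/hard labels come from **exact** 1-D 2-means: the optimal
2-clustering of scalars is a threshold split of the sorted values, so
all `N−1` splits between distinct values are scanned and the
within-cluster sum of squares minimized. This removes k-means
initialization sensitivity entirely; the seed parameter is accepted only
for API symmetry. All entropies identical is a degenerate labeling and
raises (except in summary tables, where a uniformly-zero-entropy graph
is reported as having no hard nodes).

Strategic undersampling keeps every hard node and the
`ceil(n_hard / 0.75)` lowest-entropy easy nodes (ties broken by node
id), so the hard:easy ratio never exceeds 0.75; if easy nodes are
scarcer than that, all are kept. Pair labels use `C_ij ≥ 0.5` for "same
community" (the boundary case is deliberately "same"); balanced training
sets draw `min(n_per_class, smaller class size)` pairs uniformly without
replacement from each class.

## Features

Fourteen node features and five pair features. Community-independent
features (degree, average shortest path, clustering coefficient,
betweenness, eigenvector centrality, closeness) are computed once per
graph with exact algorithms (igraph's C routines; eigenvector centrality
as the principal eigenpair from a Lanczos solve with a deterministic
start vector, unit Euclidean norm, nonnegative orientation — the
residual `‖Ax − λx‖ ≤ 1e−8` is asserted in tests). Betweenness (node and
edge) is the unnormalized Brandes sum over unordered pairs with
endpoints excluded.

Community-dependent features are evaluated against every run's partition
and averaged with equal weight per run. Per run, with `w` the number of
*other* nodes in `i`'s community and `N = |V|`: `E_in`/`E_out` (internal
and external edge counts, with `E_in + E_out = deg(i)` asserted),
`E_in/E_out` with the denominator floored at 1 so the ratio stays finite
and monotone when no edge leaves, out-degree fraction `E_out/deg(i)`,
expansion `E_out/w`, cut ratio `E_out/(N−w)`, conductance
`E_out/(deg(i)+E_in)`, and triangle participation `c_i/w`, where `c_i`
counts community-mates of `i` sharing a common neighbour that itself
lies inside the community (the edge `(i, j)` is not required). The
alternative reading — common neighbour anywhere in the graph — is
available behind `require_internal_neighbour=False`. Degenerate
denominators (singleton community, `w = 0`) are floored at 1; the
numerators are 0 there as well.

Pair features: shortest path length, common neighbour count `n_ij`,
cosine similarity `n_ij/√(deg i · deg j)`, Jaccard
`|Γ(i)∩Γ(j)|/|Γ(i)∪Γ(j)|`, and max edge centrality — the maximum edge
betweenness over the edges of shortest paths between the pair. With
multiple geodesics this is ambiguous; the default takes the union of
edges on *all* shortest paths (deterministic and path-choice-free,
computed from the distance identity `d(i,u) + 1 + d(v,j) = d(i,j)`),
with a single canonical path available via `geodesic_edges="single"`.
Both orderings were measured; the importance rankings below are robust
to the choice. Edge betweenness is computed once per graph and reused
for all pairs; pair features are computed only for the undersampled
training pairs.

## Classifier and importance

A 100-tree random forest (scikit-learn defaults otherwise: unlimited
depth, √p features per split) under stratified 5-fold cross-validation
reshuffled over 10 repeats. After each of the 50 evaluations, the
permutation importance of every feature is the held-out accuracy drop
averaged over 5 independent column shuffles; the graph's final score per
feature is the mean of its 50 evaluation scores, and negative scores are
reported as computed. The shuffle-predict loop stacks all shuffled
copies into a single prediction call per evaluation; a unit test checks
it against scikit-learn's `permutation_importance` reference. The
scoring metric (accuracy) and the 5-shuffle count are configurable; 5 is
small because 50 evaluations are averaged anyway.

## Statistics

* **Power analysis**: smallest `n` for a two-sided paired t-test at
  Cohen's `d`, solved on the noncentral t distribution (statsmodels).
  The paired family is the right one because feature comparisons are
  paired by graph; the default spec (d = 0.3, α = 0.05, power = 0.9)
  yields 119 graphs.
* **Normality**: Shapiro–Wilk per feature, with constant samples
  flagged degenerate and reported not-normal.
* **Comparisons**: two-sided Wilcoxon signed-rank on the per-graph
  paired differences of every unordered feature pair, Pratt handling of
  zero differences, continuity correction; all-zero differences get
  p = 1 by convention. Bonferroni–Holm step-down over the full family
  of pairs within one experiment cell, flags at adjusted p < 0.05, with
  the direction recorded as the feature with the larger mean difference.
* **NMI**: scikit-learn's normalized mutual information with
  arithmetic-mean normalization (the standard choice in the
  community-detection literature; `min`/`max`/`geometric` switchable),
  cross-checked against igraph in tests.
* **Summary tables**: per algorithm and mixing level — community counts
  per run; NMI over uniformly sampled (with replacement) cross-algorithm
  partition pairs; hard-node proportions.

## Problem sizes

The published study used 120 graphs per mixing level and R = 1000 runs
per graph. The test suite and acceptance script rerun the pipeline at
10–20 graphs per cell and R = 15–100 (R = 100 wherever a quantity
depends on the coassociation matrix's resolution), sizes chosen so the
per-graph statistics are stable while a full rerun stays within tens of
minutes on one CPU. Tolerances for comparisons against the published
values are ±2 standard errors at the reduced graph counts, using the
published standard deviations.

## What reproduces and what does not

With the implementations above, this pipeline reproduces: the
power-analysis count (119) exactly; Infomap's community counts at
`mu = 0.2` (40.6 vs 40.65) and the cross-algorithm NMI values
(Infomap–Louvain 0.972 vs 0.977 ± 0.01; Louvain–LPA 0.935 vs
0.922 ± 0.02); Infomap's hard-node proportion at `mu = 0.4`; the
label-propagation degeneracy at `mu = 0.4`; and, exactly, the headline
node-feature result — clustering coefficient, triangle participation,
eigenvector centrality and expansion are the four dominant node
features.

Three quantities deviate systematically, and are reported rather than
tuned away:

* **Louvain community counts at `mu = 0.4`** come out ≈ 23.2 vs the
  published 24.20 ± 0.8. igraph's multilevel and networkx's Louvain
  agree with each other here; the study used a third Louvain
  implementation whose local-move order evidently differs slightly.
* **LPA hard-node proportion at `mu = 0.2`** comes out ≈ 0.3–0.4 vs the
  published 0.242 ± 0.05, with very large per-graph spread (0.02–0.55;
  the published std 0.117 shows the same spread). Both available LPA
  implementations sit above the published mean.
* **Pair-feature ranking**: max edge centrality ranks *first* at every
  mixing level and algorithm tested, with cosine and Jaccard clearly
  second and third and the remaining pair features at zero — whereas
  the study reports Jaccard and cosine on top with max edge centrality
  growing in importance with mixing (already important for Louvain at
  `mu = 0.2`). Given that this generator realizes ~1.7× the nominal
  mixing, the observed ordering is the study's own trend evaluated at a
  higher effective mixing; the qualitative conclusion — neighbourhood
  overlap plus bridge-edge centrality carry the signal, distance and
  raw common-neighbour counts do not — is unchanged.

## Limitations

* Synthetic LFR graphs only; nothing here validates the feature
  rankings on real networks.
* Partitioning algorithms only — no overlapping or hierarchical
  community structures.
* Permutation importance splits credit between strongly correlated
  features (cosine and Jaccard being the obvious pair); rankings should
  be read jointly with the correlation structure.
* The importance estimator is an internal interface; Shapley-style
  estimators could be swapped in but are not provided.
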