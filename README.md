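# commexplain

Post-hoc explanation of stochastic community-finding algorithms with
interpretable graph features.

Community detection algorithms — Louvain, Infomap, label propagation —
are stochastic: run them twice on the same network and some nodes land in
different communities. Practitioners (e.g. social-network analysts
planning public-health interventions) have no way to see *why* a given
node oscillates or why two nodes end up together. `commexplain`
implements a model-agnostic pipeline that answers those questions in the
vocabulary such users already speak: standard social-network-analysis
metrics, ranked by how much predictive power they carry.

## The method

For a graph `G = (V, E)` and an algorithm, run the algorithm `R` times
and build the **coassociation matrix**

    C_ij = r_ij / R

where `r_ij` counts the runs in which nodes *i* and *j* share a
community. Each node's **entropy**

    E_i = (1/N) Σ_j p_ij,   p_ij = −C_ij log₂ C_ij  (0 if C_ij ≤ 0)

measures how much it flips between communities. Exact one-dimensional
2-means clustering of the entropies yields binary **easy / hard to
cluster** labels; pairs are labelled **same / different community** by
`C_ij ≥ ½`. After class balancing (all hard nodes plus the
lowest-entropy easy nodes at a 3:4 ratio; 1000 random pairs per class),
a random forest (100 trees, 5-fold cross-validation × 10 repeats) is
trained on 14 node features (degree, E_in, E_out, E_in/E_out, out-degree
fraction, expansion, cut ratio, conductance, average shortest path,
triangle participation, clustering coefficient, betweenness, eigenvector
and closeness centrality) or 5 pair features (shortest path length,
common neighbours, max edge centrality along geodesics, cosine
similarity, Jaccard). Each feature's **permutation importance** — the
held-out accuracy drop when its column is shuffled — is averaged over
the 50 evaluations; per-graph means over many LFR benchmark graphs are
then compared with paired Wilcoxon signed-rank tests under
Bonferroni–Holm correction, with the number of graphs fixed in advance
by a power analysis (d = 0.3, α = 0.05, power = 0.9 → 119 graphs).

## Worked example

```python
from commexplain import (LFRConfig, generate_lfr, run_ensemble,
                         ClassifierConfig, node_experiment)

graph, _ = generate_lfr(LFRConfig(mu=0.4, seed=11))
ensemble = run_ensemble(graph, "louvain", R=100, base_seed=2)
result = node_experiment(graph, ensemble, ClassifierConfig(seed=0))
print(result.mean_importance.sort_values(ascending=False).head(3))
```

prints (held-out accuracy 0.949 on this graph):

```
clustering_coefficient    0.0800
expansion                 0.0735
triangle_participation    0.0394
```

meaning that shuffling the clustering-coefficient column costs the
forest eight points of held-out accuracy: nodes in triangle-rich
community cores are reliably easy to cluster, nodes with many edges
leaving a small community are the ones that oscillate. Averaged over ~20
graphs the stable top four node features are clustering coefficient,
triangle participation, eigenvector centrality and expansion.

The `examples/` directory has one short script per capability
(generation, labeling, node/pair experiments, statistics, the grid); the
`commexplain` CLI exposes the same stages as verbs
(`generate`, `ensemble`, `explain-nodes`, `explain-pairs`, `stats`,
`grid --preset desk`).

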