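"""Which features predict that two nodes share a community?

Pair experiment: every node pair is labelled same/different community by
majority over 100 runs, 1000 pairs per class are sampled, and five pair
features (shortest path length, common neighbours, max edge centrality
along geodesics, cosine similarity, Jaccard) are ranked by permutation
importance.
"""

from commexplain import ClassifierConfig, LFRConfig, generate_lfr, pair_experiment, run_ensemble

graph, _ = generate_lfr(LFRConfig(mu=0.3, seed=13))
ensemble = run_ensemble(graph, "louvain", R=100, base_seed=4)
result = pair_experiment(
    graph, ensemble, ClassifierConfig(seed=0), n_per_class=1000, graph_id="demo"
)

print(f"held-out accuracy: {result.accuracy.mean():.3f}")
print("mean permutation importance:")
print(result.mean_importance.sort_values(ascending=False).round(4).to_string())
print(
    "\nNeighbourhood overlap (cosine/Jaccard) and the centrality of the "
    "most bridge-like edge between the pair carry the signal; raw "
    "distance and common-neighbour counts add little once those are known."
)
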