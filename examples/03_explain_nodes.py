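"""Which interpretable features predict that a node is hard to cluster?

Full node experiment on one graph: ensemble -> entropy labels ->
14 features -> random forest (100 trees, 5-fold x 10 repeats) ->
mean permutation importance per feature. A large value means shuffling
that feature costs the classifier real held-out accuracy.
"""

from commexplain import ClassifierConfig, LFRConfig, generate_lfr, node_experiment, run_ensemble

graph, _ = generate_lfr(LFRConfig(mu=0.4, seed=11))
ensemble = run_ensemble(graph, "louvain", R=100, base_seed=2)
result = node_experiment(graph, ensemble, ClassifierConfig(seed=0), graph_id="demo")

print(f"held-out accuracy: {result.accuracy.mean():.3f}")
print("mean permutation importance (top 6):")
print(result.mean_importance.sort_values(ascending=False).head(6).round(4).to_string())
print(
    "\nNodes embedded in triangle-rich community cores (high clustering "
    "coefficient / triangle participation) are easy to place; nodes with "
    "many outgoing edges relative to their community size (high "
    "expansion) are not. Single-graph rankings are noisy — averaged over "
    "~20 graphs the stable top four are clustering coefficient, triangle "
    "participation, eigenvector centrality and expansion."
)
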