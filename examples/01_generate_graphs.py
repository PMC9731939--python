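"""Generate an LFR benchmark graph and inspect its planted communities.

The LFR model produces graphs with power-law degrees and community sizes;
the mixing parameter mu sets how many of each node's edges leave its
planted community (higher mu = harder to detect).
"""

import numpy as np

from commexplain import LFRConfig, generate_lfr

config = LFRConfig(n=1000, tau1=3, tau2=2, mu=0.2, avg_degree=20, max_degree=50, seed=1)
graph, truth = generate_lfr(config)

sizes = np.bincount(list(truth.values()))
degrees = np.array([d for _, d in graph.degree()])
print(f"nodes: {graph.number_of_nodes()}, edges: {graph.number_of_edges()}")
print(f"planted communities: {len(sizes)} (sizes {sizes.min()}..{sizes.max()})")
print(f"degrees: mean {degrees.mean():.1f}, max {degrees.max()}")

# How mixed is the graph really? Fraction of each node's edges that stay
# inside its planted community (the generator realizes somewhat more
# inter-community edges than the nominal 1 - mu).
intra = np.mean(
    [
        np.mean([truth[u] == truth[v] for u in graph.neighbors(v)])
        for v in graph.nodes()
    ]
)
print(f"mean intra-community edge fraction: {intra:.3f} (nominal 1-mu = 0.8)")
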