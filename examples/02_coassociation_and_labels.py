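"""Run an algorithm many times and label nodes easy/hard to cluster.

100 seeded Louvain runs on one LFR graph give a coassociation matrix
(C[i, j] = fraction of runs where i and j share a community). Each node's
entropy summarizes how much it flips between communities; 2-means on the
entropies splits the easy and hard classes, and strategic undersampling
keeps all hard nodes plus the easiest easy nodes at a 0.75 hard:easy
ratio.
"""

import numpy as np

from commexplain import (
    LFRConfig,
    build_coassociation,
    generate_lfr,
    label_easy_hard,
    node_entropy,
    run_ensemble,
    strategic_undersample,
)

graph, _ = generate_lfr(LFRConfig(mu=0.3, seed=7))
ensemble = run_ensemble(graph, "louvain", R=100, base_seed=0)
print(f"communities per run: mean {ensemble.community_counts().mean():.1f}")

C = build_coassociation(ensemble)
entropies = node_entropy(C)
print(f"entropy: min {entropies.min():.4f}, max {entropies.max():.4f}")

labels = label_easy_hard(entropies)
print(
    f"hard-to-cluster nodes: {labels.hard.sum()} of {len(entropies)} "
    f"({labels.hard.mean():.1%}); entropy threshold {labels.threshold:.4f}"
)

training = strategic_undersample(labels, entropies)
kept_easy = len(training.selected) - labels.hard.sum()
print(
    f"training set after strategic undersampling: {labels.hard.sum()} hard "
    f"+ {kept_easy} easy (ratio {labels.hard.sum() / kept_easy:.3f})"
)
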