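"""Coassociation matrices, node entropies, and classification labelings.

From R runs of a stochastic algorithm on one graph we build the
coassociation matrix ``C``, where ``C[i, j]`` is the fraction of runs in
which nodes ``i`` and ``j`` share a community. Two binary labelings derive
from it:

* **easy / hard to cluster** (node level): each node's entropy
  ``E_i = (sum_j p_ij) / N`` with ``p_ij = -C_ij log2(C_ij)`` (0 when
  ``C_ij <= 0``) measures how much the node flips between communities
  across runs; exact one-dimensional 2-means clustering of the entropies
  splits nodes into a low-entropy "easy" and a high-entropy "hard" class.
* **same / different community** (pair level): pair ``(i, j)`` is "same"
  when ``C_ij >= 0.5`` (ties at exactly 0.5 are deliberately labelled
  "same"), otherwise "different".

Both labelings come with undersampling schemes producing balanced-enough
training sets: *strategic* undersampling keeps all hard nodes plus the
lowest-entropy easy nodes until hard = 75% of easy; pair undersampling
draws the same number of pairs uniformly at random from each class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detectors import RunEnsemble

__all__ = [
    "CoassociationMatrix",
    "build_coassociation",
    "node_entropy",
    "NodeClassLabels",
    "label_easy_hard",
    "strategic_undersample",
    "PairClassLabels",
    "label_pairs",
    "undersample_pairs",
    "DegenerateLabelingError",
    "MAX_ENTROPY",
]

#: Upper bound on any node entropy: max of -C log2 C over C in (0, 1].
MAX_ENTROPY = math.log2(math.e) / math.e


class DegenerateLabelingError(ValueError):
    """Raised when a labeling cannot produce two usable classes."""


@dataclass
class CoassociationMatrix:
    """Symmetric ``(n, n)`` matrix of co-membership frequencies over R runs."""

    values: np.ndarray
    R: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("coassociation matrix must be square")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def build_coassociation(ensemble: RunEnsemble) -> CoassociationMatrix:
    """``C[i, j]`` = fraction of runs in which i and j share a community."""
    n = ensemble.n_nodes
    counts = np.zeros((n, n), dtype=np.uint32)
    for row in ensemble.partitions:
        counts += row[:, None] == row[None, :]
    return CoassociationMatrix(values=counts / ensemble.R, R=ensemble.R)


def node_entropy(C: CoassociationMatrix) -> np.ndarray:
    """Per-node mean of the pairwise entropy terms ``-C_ij log2 C_ij``.

    The diagonal contributes 0 (``C_ii = 1``) but is included in the mean's
    denominator ``N``, matching the definition exactly. Values lie in
    ``[0, MAX_ENTROPY]``.
    """
    V = C.values
    safe = np.where(V > 0, V, 1.0)
    P = np.where(V > 0, -safe * np.log2(safe), 0.0)
    return P.mean(axis=1)


@dataclass
class NodeClassLabels:
    """Easy/hard labels plus the selected training subset of nodes."""

    hard: np.ndarray  # bool, shape (n,); True = hard to cluster
    selected: np.ndarray  # int node indices forming the training subset
    threshold: float  # entropy boundary between the two k-means clusters

    @property
    def easy_nodes(self) -> np.ndarray:
        return np.flatnonzero(~self.hard)

    @property
    def hard_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.hard)


def _best_threshold_split(values: np.ndarray) -> int:
    """Index t minimizing within-cluster sum of squares over sorted values.

    Exact 1-D 2-means: the optimal 2-clustering of scalars is a threshold
    split of the sorted sequence, so scanning all N-1 splits (restricted
    to boundaries between distinct values) is exact and removes any
    initialization sensitivity.
    """
    v = np.sort(values)
    n = len(v)
    csum = np.cumsum(v)
    csq = np.cumsum(v * v)
    t = np.arange(1, n)  # left cluster = v[:t], right = v[t:]
    left_ss = csq[t - 1] - csum[t - 1] ** 2 / t
    rsum = csum[-1] - csum[t - 1]
    rsq = csq[-1] - csq[t - 1]
    right_ss = rsq - rsum**2 / (n - t)
    wcss = left_ss + right_ss
    valid = v[t] > v[t - 1]
    if not valid.any():
        raise DegenerateLabelingError(
            "all entropy values identical; no easy/hard split exists"
        )
    wcss[~valid] = np.inf
    return int(t[np.argmin(wcss)])


def label_easy_hard(entropies: np.ndarray, seed: int = 0) -> NodeClassLabels:
    """Split nodes into easy/hard by exact 1-D 2-means on their entropies.

    The cluster with the lower centroid is "easy", the higher "hard". The
    seed is accepted for API symmetry only: the threshold scan is exact,
    so the result is deterministic regardless.
    """
    entropies = np.asarray(entropies, dtype=np.float64)
    if entropies.ndim != 1 or len(entropies) < 2:
        raise ValueError("need a 1-D array of >= 2 entropies")
    t = _best_threshold_split(entropies)
    v = np.sort(entropies)
    threshold = (v[t - 1] + v[t]) / 2
    hard = entropies > threshold
    if not hard.any() or hard.all():
        raise DegenerateLabelingError("2-means produced an empty class")
    return NodeClassLabels(
        hard=hard, selected=np.arange(len(entropies)), threshold=threshold
    )


def strategic_undersample(
    labels: NodeClassLabels, entropies: np.ndarray
) -> NodeClassLabels:
    """Keep all hard nodes and the lowest-entropy easy nodes.

    Easy nodes are retained in increasing entropy order (ties broken by
    node identifier) until hard = 75% of easy, i.e. ``ceil(n_hard / 0.75)``
    easy nodes; if fewer easy nodes exist, all are kept. Using the
    *easiest* easy nodes rather than a random sample separates the classes
    far from the arbitrary 2-means cut-off.
    """
    entropies = np.asarray(entropies, dtype=np.float64)
    hard_nodes = labels.hard_nodes
    easy_nodes = labels.easy_nodes
    if len(hard_nodes) == 0 or len(easy_nodes) == 0:
        raise DegenerateLabelingError("both classes must be nonempty")
    n_keep = math.ceil(len(hard_nodes) / 0.75)
    order = easy_nodes[np.argsort(entropies[easy_nodes], kind="stable")]
    kept_easy = order[:n_keep] if n_keep < len(easy_nodes) else easy_nodes
    selected = np.sort(np.concatenate([hard_nodes, kept_easy]))
    return NodeClassLabels(
        hard=labels.hard, selected=selected, threshold=labels.threshold
    )


@dataclass
class PairClassLabels:
    """Same/different labels over all unordered pairs, plus training subset.

    ``pairs_i``/``pairs_j`` enumerate the strict upper triangle (i < j);
    ``same[k]`` labels pair k; ``selected`` indexes into the pair arrays.
    """

    pairs_i: np.ndarray
    pairs_j: np.ndarray
    same: np.ndarray
    selected: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def selected_pairs(self) -> np.ndarray:
        """(k, 2) array of the selected node pairs."""
        return np.column_stack(
            [self.pairs_i[self.selected], self.pairs_j[self.selected]]
        )


def label_pairs(C: CoassociationMatrix) -> PairClassLabels:
    """Label every unordered pair: same community iff ``C_ij >= 0.5``."""
    i, j = np.triu_indices(C.n_nodes, k=1)
    same = C.values[i, j] >= 0.5
    return PairClassLabels(
        pairs_i=i, pairs_j=j, same=same, selected=np.arange(len(i))
    )


def undersample_pairs(
    labels: PairClassLabels, n_per_class: int, seed: int
) -> PairClassLabels:
    """Uniform random balanced subsample of the two pair classes.

    Draws ``min(n_per_class, smaller class size)`` pairs without
    replacement from *each* class, keeping the training set balanced even
    when one class is scarce.
    """
    same_idx = np.flatnonzero(labels.same)
    diff_idx = np.flatnonzero(~labels.same)
    if len(same_idx) == 0 or len(diff_idx) == 0:
        raise DegenerateLabelingError("a pair class is empty")
    n_eff = min(n_per_class, len(same_idx), len(diff_idx))
    rng = np.random.default_rng(seed)
    chosen = np.concatenate(
        [
            rng.choice(same_idx, size=n_eff, replace=False),
            rng.choice(diff_idx, size=n_eff, replace=False),
        ]
    )
    return PairClassLabels(
        pairs_i=labels.pairs_i,
        pairs_j=labels.pairs_j,
        same=labels.same,
        selected=np.sort(chosen),
    )
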