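"""Stochastic community-finding algorithms and run ensembles.

Three partitioning algorithms are supported, each stochastic across seeds
and deterministic for a fixed seed:

``louvain``
    Multilevel modularity optimization (Blondel et al.), resolution 1.0;
    the final (coarsest) level of the hierarchy is the partition.
``infomap``
    Two-level map-equation optimization (Rosvall & Bergstrom), one
    optimization trial per run.
``lpa``
    Asynchronous label propagation (Raghavan et al.): random node order
    each sweep, uniform tie-breaking among majority labels, stopping when
    every node holds a label shared by a majority of its neighbours.

python-igraph's C implementations back Louvain and Infomap; label
propagation uses networkx's asynchronous implementation, which follows
the original update rule exactly. Partitions are returned as dense
integer label arrays indexed by node ``0..n-1``. Labels
are run-local and carry no meaning across runs — every downstream consumer
is invariant to bijective relabelling.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np

__all__ = [
    "ALGORITHMS",
    "run_once",
    "run_ensemble",
    "degenerate_fraction",
    "RunEnsemble",
    "to_igraph",
]

ALGORITHMS = ("infomap", "louvain", "lpa")


def to_igraph(G: nx.Graph) -> ig.Graph:
    """Convert a contiguous-integer-labelled networkx graph to igraph."""
    n = G.number_of_nodes()
    if set(G.nodes()) != set(range(n)):
        raise ValueError("graph nodes must be contiguous integers 0..n-1")
    return ig.Graph(n=n, edges=list(G.edges()))


def _run_lpa(G: nx.Graph, seed: int) -> np.ndarray:
    labels = np.empty(G.number_of_nodes(), dtype=np.int64)
    for c, members in enumerate(nx.community.asyn_lpa_communities(G, seed=seed)):
        for v in members:
            labels[v] = c
    return labels


def _run_igraph(g: ig.Graph, algorithm: str, seed: int) -> np.ndarray:
    ig.set_random_number_generator(random.Random(int(seed)))
    if algorithm == "louvain":
        clustering = g.community_multilevel()
    elif algorithm == "infomap":
        clustering = g.community_infomap(trials=1)
    else:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}"
        )
    return np.asarray(clustering.membership, dtype=np.int64)


def run_once(graph: nx.Graph, algorithm: str, seed: int) -> np.ndarray:
    """One seeded run of a community-finding algorithm.

    Returns the partition as an integer label array of length ``n``;
    ``labels[v]`` is the (run-local) community of node ``v``.
    """
    if algorithm == "lpa":
        return _run_lpa(graph, int(seed))
    return _run_igraph(to_igraph(graph), algorithm, seed)


@dataclass
class RunEnsemble:
    """R seeded partitions of one graph by one algorithm.

    ``partitions`` has shape ``(R, n)``; row ``r`` is the label array of
    run ``r`` (seed ``base_seed + r``).
    """

    graph: nx.Graph
    algorithm: str
    partitions: np.ndarray
    base_seed: int
    n_nodes: int = field(init=False)

    def __post_init__(self) -> None:
        self.partitions = np.asarray(self.partitions, dtype=np.int64)
        if self.partitions.ndim != 2:
            raise ValueError("partitions must be a (R, n) array")
        self.n_nodes = self.partitions.shape[1]
        if self.n_nodes != self.graph.number_of_nodes():
            raise ValueError("partition width does not match the graph")

    @property
    def R(self) -> int:
        return self.partitions.shape[0]

    def community_counts(self) -> np.ndarray:
        """Number of communities in each run."""
        return np.array(
            [len(np.unique(row)) for row in self.partitions], dtype=np.int64
        )


def run_ensemble(
    graph: nx.Graph, algorithm: str, R: int, base_seed: int
) -> RunEnsemble:
    """Run ``algorithm`` R times with seeds ``base_seed + 0..R-1``."""
    if R < 1:
        raise ValueError("R must be >= 1")
    g = None if algorithm == "lpa" else to_igraph(graph)
    parts = np.empty((R, graph.number_of_nodes()), dtype=np.int64)
    for r in range(R):
        seed = (base_seed + r) % (2**31)
        if algorithm == "lpa":
            parts[r] = _run_lpa(graph, seed)
        else:
            parts[r] = _run_igraph(g, algorithm, seed)
    return RunEnsemble(
        graph=graph, algorithm=algorithm, partitions=parts, base_seed=base_seed
    )


def degenerate_fraction(ensemble: RunEnsemble) -> float:
    """Fraction of runs whose largest community holds > 50% of the nodes.

    A run placing a majority of nodes in one community indicates the
    algorithm failed to resolve community structure (label propagation
    does this at high mixing); grid orchestration uses this to exclude
    whole experiment cells.
    """
    n = ensemble.n_nodes
    degenerate = 0
    for row in ensemble.partitions:
        if np.bincount(row).max() > n / 2:
            degenerate += 1
    return degenerate / ensemble.R
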