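"""Synthetic benchmark graphs for community-finding experiments.

The main generator is the LFR benchmark (Lancichinetti-Fortunato-Radicchi),
which produces graphs with power-law degree and community-size distributions
and a mixing parameter ``mu`` giving the expected fraction of each node's
edges that leave its planted community. A planted-partition (stochastic
block model) generator and a barbell fixture are provided as fast,
hand-checkable stand-ins for unit testing.

All generators return a pair ``(graph, ground_truth)`` where ``graph`` is an
undirected, simple, connected :class:`networkx.Graph` with node identifiers
``0..n-1`` and ``ground_truth`` maps each node to its planted community
label. Ground truth is diagnostic only: the explanation pipeline never
consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = [
    "LFRConfig",
    "generate_lfr",
    "generate_planted_partition",
    "fixture_barbell",
]

_MAX_ATTEMPTS = 100


@dataclass(frozen=True)
class LFRConfig:
    """Hyperparameters of the LFR benchmark generator.

    Parameters
    ----------
    n : int
        Number of nodes.
    tau1 : float
        Power-law exponent of the degree distribution (> 1).
    tau2 : float
        Power-law exponent of the community-size distribution (> 1).
    mu : float
        Mixing parameter in (0, 1): the expected fraction of a node's
        edges that attach outside its planted community.
    avg_degree : float
        Target mean degree.
    max_degree : int
        Degree cap.
    seed : int
        RNG seed; identical config + seed yields an identical graph.
    """

    n: int = 1000
    tau1: float = 3.0
    tau2: float = 2.0
    mu: float = 0.2
    avg_degree: float = 20.0
    max_degree: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mu < 1:
            raise ValueError(f"mu must be in (0, 1), got {self.mu}")
        if self.tau1 <= 1 or self.tau2 <= 1:
            raise ValueError("power-law exponents tau1, tau2 must exceed 1")
        if not 1 <= self.avg_degree <= self.max_degree < self.n:
            raise ValueError(
                "need 1 <= avg_degree <= max_degree < n, got "
                f"avg={self.avg_degree}, max={self.max_degree}, n={self.n}"
            )


class GenerationError(RuntimeError):
    """Raised when a generator cannot produce a valid graph."""


def _canonicalize(G: nx.Graph) -> nx.Graph:
    """Relabel nodes to contiguous integers 0..n-1 in sorted order."""
    mapping = {v: i for i, v in enumerate(sorted(G.nodes()))}
    return nx.relabel_nodes(G, mapping, copy=True)


def generate_lfr(config: LFRConfig) -> tuple[nx.Graph, dict[int, int]]:
    """Generate a connected LFR benchmark graph with planted communities.

    Retries with seeds derived from ``config.seed`` until the generator
    succeeds and the result is connected, up to an internal attempt cap.

    Returns
    -------
    (graph, ground_truth)
        ``graph`` is simple, undirected, connected, with nodes ``0..n-1``;
        ``ground_truth[v]`` is the planted community index of node ``v``.

    Raises
    ------
    GenerationError
        If no valid connected graph is produced within the attempt cap
        (infeasible parameter combination).
    """
    last_err: Exception | None = None
    for attempt in range(_MAX_ATTEMPTS):
        seed = (config.seed + 1_000_003 * attempt) % (2**31)
        try:
            G = nx.LFR_benchmark_graph(
                config.n,
                config.tau1,
                config.tau2,
                config.mu,
                average_degree=config.avg_degree,
                max_degree=config.max_degree,
                seed=seed,
            )
        except (nx.ExceededMaxIterations, nx.NetworkXError) as err:
            last_err = err
            continue
        G.remove_edges_from(nx.selfloop_edges(G))
        if not nx.is_connected(G):
            continue
        communities = {frozenset(G.nodes[v]["community"]) for v in G}
        label_of = {}
        for idx, comm in enumerate(sorted(communities, key=min)):
            for v in comm:
                label_of[v] = idx
        H = nx.Graph()
        H.add_nodes_from(range(G.number_of_nodes()))
        H.add_edges_from(G.edges())
        return H, label_of
    raise GenerationError(
        f"LFR generation failed after {_MAX_ATTEMPTS} attempts "
        f"(last error: {last_err}); parameters may be infeasible"
    )


def generate_planted_partition(
    k: int, size: int, p_in: float, p_out: float, seed: int
) -> tuple[nx.Graph, dict[int, int]]:
    """Planted-partition (SBM) graph with ``k`` blocks of ``size`` nodes.

    A fast, desk-scale stand-in for the LFR benchmark: within-block edges
    appear with probability ``p_in``, between-block edges with ``p_out``.
    Regenerates with derived seeds until connected.
    """
    if k < 2 or size < 2:
        raise ValueError("need k >= 2 blocks of size >= 2")
    if not 0 <= p_out < p_in <= 1:
        raise ValueError(
            f"need 0 <= p_out < p_in <= 1 for assortative structure, "
            f"got p_in={p_in}, p_out={p_out}"
        )
    for attempt in range(_MAX_ATTEMPTS):
        s = (seed + 1_000_003 * attempt) % (2**31)
        G = nx.planted_partition_graph(k, size, p_in, p_out, seed=s)
        G = nx.Graph(G)  # drop block metadata wrapper attributes
        if nx.is_connected(G):
            truth = {v: v // size for v in G.nodes()}
            return _canonicalize(G), truth
    raise GenerationError(
        f"planted partition (k={k}, size={size}, p_in={p_in}, p_out={p_out}) "
        f"not connected after {_MAX_ATTEMPTS} attempts"
    )


def fixture_barbell(clique_size: int = 5) -> tuple[nx.Graph, dict[int, int]]:
    """Two cliques of ``clique_size`` nodes joined by a single bridge edge.

    Nodes ``0..clique_size-1`` form the first clique, the rest the second;
    the bridge joins portal nodes ``0`` and ``clique_size``. Exactly one
    edge crosses the ground-truth cut, which makes every feature value
    computable by hand.
    """
    if clique_size < 3:
        raise ValueError("clique_size must be >= 3")
    c = clique_size
    G = nx.Graph()
    G.add_nodes_from(range(2 * c))
    for block in (range(c), range(c, 2 * c)):
        block = list(block)
        G.add_edges_from(
            (block[i], block[j]) for i in range(c) for j in range(i + 1, c)
        )
    G.add_edge(0, c)
    truth = {v: v // c for v in G.nodes()}
    return G, truth
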