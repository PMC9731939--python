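"""Readers and writers for graphs, ground truth, and run ensembles.

Graphs are exchanged as whitespace-delimited edge lists, GML, or GraphML
(via networkx). On read, node identifiers are remapped to contiguous
integers ``0..n-1`` (sorted original order) and the mapping is returned so
results can be reported in the caller's labels. Inputs must be undirected
and simple; directed or multi-edge files are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "read_graph",
    "write_graph",
    "read_ground_truth",
    "write_ground_truth",
    "write_ensemble",
    "read_ensemble",
]

_FORMATS = ("edgelist", "gml", "graphml")


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("gml",):
        return "gml"
    if suffix in ("graphml", "xml"):
        return "graphml"
    return "edgelist"


def read_graph(
    path: str | Path,
    fmt: str | None = None,
    require_connected: bool = True,
) -> tuple[nx.Graph, dict]:
    """Read an undirected simple graph, remapping nodes to ``0..n-1``.

    Parameters
    ----------
    path : path to the graph file.
    fmt : one of ``edgelist``, ``gml``, ``graphml``; inferred from the
        file extension when omitted.
    require_connected : reject disconnected graphs (the experiment
        pipeline needs shortest paths between all node pairs). Pass
        ``False`` for feature-only use on a single component.

    Returns
    -------
    (graph, manifest)
        ``manifest`` maps the new integer identifiers back to the
        original node labels.
    """
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "edgelist":
        raw = nx.read_edgelist(path, create_using=nx.MultiGraph)
    elif fmt == "gml":
        raw = nx.read_gml(path, label="label")
    else:
        raw = nx.read_graphml(path)
    if raw.is_directed():
        raise ValueError(f"{path}: directed graphs are not supported")
    simple = nx.Graph()
    simple.add_nodes_from(raw.nodes())
    for u, v in raw.edges():
        if u == v:
            raise ValueError(f"{path}: self-loop at node {u!r}")
        if simple.has_edge(u, v):
            raise ValueError(f"{path}: duplicate edge ({u!r}, {v!r})")
        simple.add_edge(u, v)
    order = sorted(simple.nodes(), key=str)
    mapping = {v: i for i, v in enumerate(order)}
    G = nx.relabel_nodes(simple, mapping, copy=True)
    if require_connected and not nx.is_connected(G):
        raise ValueError(
            f"{path}: graph is disconnected; pass require_connected=False "
            "for feature-only use"
        )
    manifest = {i: v for v, i in mapping.items()}
    return G, manifest


def write_graph(G: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write a graph as edge list, GML, or GraphML."""
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt == "edgelist":
        nx.write_edgelist(G, path, data=False)
    elif fmt == "gml":
        nx.write_gml(G, path, stringizer=str)
    elif fmt == "graphml":
        nx.write_graphml(G, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def write_ground_truth(truth: dict[int, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(truth.items()), columns=["node", "label"]
    ).to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> dict[int, int]:
    df = pd.read_csv(path)
    return dict(zip(df["node"].astype(int), df["label"].astype(int)))


def write_ensemble(ensemble, directory: str | Path, name: str) -> None:
    """Persist an ensemble as a CSV (rows = nodes, columns = runs) + metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        ensemble.partitions.T,
        columns=[f"run_{r}" for r in range(ensemble.R)],
    )
    df.insert(0, "node", np.arange(ensemble.n_nodes))
    df.to_csv(directory / f"{name}.csv", index=False)
    meta = {
        "algorithm": ensemble.algorithm,
        "R": ensemble.R,
        "base_seed": ensemble.base_seed,
        "n_nodes": ensemble.n_nodes,
        "graph_hash": graph_hash(ensemble.graph),
    }
    (directory / f"{name}.meta.json").write_text(json.dumps(meta, indent=2))


def read_ensemble(directory: str | Path, name: str, graph: nx.Graph):
    """Load an ensemble written by :func:`write_ensemble`."""
    from .detectors import RunEnsemble

    directory = Path(directory)
    meta = json.loads((directory / f"{name}.meta.json").read_text())
    if graph_hash(graph) != meta["graph_hash"]:
        raise ValueError("graph does not match the ensemble's stored hash")
    df = pd.read_csv(directory / f"{name}.csv").set_index("node").sort_index()
    partitions = df.to_numpy(dtype=np.int64).T
    return RunEnsemble(
        graph=graph,
        algorithm=meta["algorithm"],
        partitions=partitions,
        base_seed=meta["base_seed"],
    )


def graph_hash(G: nx.Graph) -> str:
    """Order-independent hash of a graph's edge set (provenance checks)."""
    import hashlib

    edges = sorted(tuple(sorted(e)) for e in G.edges())
    payload = f"{G.number_of_nodes()}|{edges}".encode()
    return hashlib.sha256(payload).hexdigest()[:16]
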