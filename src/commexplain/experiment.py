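"""Experiment-grid orchestration.

An experiment cell is a (mixing parameter, algorithm, feature type)
triple. For each mixing parameter a shared set of LFR graphs is generated
once; every cell then runs its algorithm R times per graph, builds the
coassociation matrix, derives labels, computes features, trains the
random forest, and records per-graph mean permutation importances. Cells
in which the algorithm degenerates (a majority of runs put a majority of
nodes in one community, on a majority of graphs) are excluded rather than
analysed — label propagation does this at high mixing.

All seeds are derived deterministically from the master seed, so a rerun
of the same configuration reproduces every artifact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import pandas as pd

from . import coassoc as ca
from . import features as ft
from .classify import ClassifierConfig, ImportanceResult, collect_distributions, train_and_importances
from .detectors import ALGORITHMS, RunEnsemble, run_ensemble
from .netgen import LFRConfig, generate_lfr
from .stats import StatReport, pairwise_wilcoxon_holm, shapiro_suite, summarize_experiment

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "CellResult",
    "GridResult",
    "run_grid",
    "node_experiment",
    "pair_experiment",
    "DEGENERATE_RUN_THRESHOLD",
    "DEGENERATE_CELL_THRESHOLD",
]

#: a run is degenerate when its largest community exceeds half the nodes;
#: a graph is degenerate when more than this fraction of runs are.
DEGENERATE_RUN_THRESHOLD = 0.5
#: a cell is excluded when more than this fraction of graphs are degenerate.
DEGENERATE_CELL_THRESHOLD = 0.5


@dataclass(frozen=True)
class ExperimentConfig:
    """Full grid configuration; defaults mirror the published study."""

    mus: tuple[float, ...] = (0.2, 0.3, 0.4)
    algorithms: tuple[str, ...] = ALGORITHMS
    feature_types: tuple[str, ...] = ("node", "pair")
    n_graphs: int = 120
    n_runs: int = 1000
    lfr: LFRConfig = LFRConfig()
    classifier: ClassifierConfig = ClassifierConfig()
    n_per_class: int = 1000
    master_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")
        if set(self.feature_types) - {"node", "pair"}:
            raise ValueError("feature_types must be 'node' and/or 'pair'")
        if self.n_graphs < 1 or self.n_runs < 1:
            raise ValueError("n_graphs and n_runs must be >= 1")

    # deterministic seed derivation -------------------------------------
    def graph_seed(self, mu_idx: int, graph_idx: int) -> int:
        return (self.master_seed + 99991 * mu_idx + 101 * graph_idx) % (2**31)

    def ensemble_seed(self, mu_idx: int, alg: str, graph_idx: int) -> int:
        a = ALGORITHMS.index(alg)
        return (
            self.master_seed + 7 + 104729 * mu_idx + 1009 * a + 10007 * graph_idx
        ) % (2**31)

    def analysis_seed(self, mu_idx: int, alg: str, graph_idx: int) -> int:
        return (self.ensemble_seed(mu_idx, alg, graph_idx) + 3) % (2**31)


@dataclass
class CellResult:
    """Outcome of one (mu, algorithm, feature type) cell."""

    mu: float
    algorithm: str
    feature_type: str
    status: str  # "completed" | "excluded-degenerate"
    degenerate_fractions: list[float]
    importances: list[ImportanceResult] = field(default_factory=list)
    distributions: pd.DataFrame | None = None
    shapiro: pd.DataFrame | None = None
    report: StatReport | None = None


@dataclass
class GridResult:
    cells: dict[tuple[float, str, str], CellResult]
    summaries: dict[float, dict[str, pd.DataFrame]]
    config: ExperimentConfig


def node_experiment(
    graph: nx.Graph,
    ensemble: RunEnsemble,
    classifier: ClassifierConfig,
    graph_id: str | None = None,
) -> ImportanceResult:
    """Easy/hard node classification with strategic undersampling."""
    C = ca.build_coassociation(ensemble)
    entropies = ca.node_entropy(C)
    labels = ca.label_easy_hard(entropies, seed=classifier.seed)
    labels = ca.strategic_undersample(labels, entropies)
    table = ft.assemble_feature_table(
        ft.node_feature_table(graph, ensemble), labels
    )
    return train_and_importances(table, classifier, graph_id=graph_id)


def pair_experiment(
    graph: nx.Graph,
    ensemble: RunEnsemble,
    classifier: ClassifierConfig,
    n_per_class: int = 1000,
    graph_id: str | None = None,
) -> ImportanceResult:
    """Same/different pair classification with random balanced undersampling."""
    C = ca.build_coassociation(ensemble)
    labels = ca.label_pairs(C)
    labels = ca.undersample_pairs(labels, n_per_class, seed=classifier.seed)
    feats = ft.pair_features(graph, labels.selected_pairs())
    table = ft.assemble_feature_table(feats, labels)
    return train_and_importances(table, classifier, graph_id=graph_id)


def _generate_graphs(
    config: ExperimentConfig, mu_idx: int, mu: float
) -> list[nx.Graph]:
    graphs = []
    for g_idx in range(config.n_graphs):
        cfg = replace(
            config.lfr, mu=mu, seed=config.graph_seed(mu_idx, g_idx)
        )
        graph, _ = generate_lfr(cfg)
        graphs.append(graph)
        logger.info("generated graph %d/%d at mu=%s", g_idx + 1, config.n_graphs, mu)
    return graphs


def run_grid(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    graphs_by_mu: dict[float, list[nx.Graph]] | None = None,
) -> GridResult:
    """Run the full experiment grid.

    Per mixing parameter, the same graphs are shared by every algorithm
    and feature type (pass ``graphs_by_mu`` to reuse pre-generated
    graphs, e.g. for desk-scale testing). Returns per-cell importance
    results and statistics plus per-mu summary tables; writes JSON/CSV
    artifacts under ``out_dir`` when given.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    cells: dict[tuple[float, str, str], CellResult] = {}
    summaries: dict[float, dict[str, pd.DataFrame]] = {}

    for mu_idx, mu in enumerate(config.mus):
        if graphs_by_mu is not None and mu in graphs_by_mu:
            graphs = graphs_by_mu[mu]
        else:
            graphs = _generate_graphs(config, mu_idx, mu)

        ensembles: dict[str, list[RunEnsemble]] = {}
        degen: dict[str, list[float]] = {}
        from .detectors import degenerate_fraction

        for alg in config.algorithms:
            ensembles[alg] = [
                run_ensemble(
                    g, alg, config.n_runs, config.ensemble_seed(mu_idx, alg, i)
                )
                for i, g in enumerate(graphs)
            ]
            degen[alg] = [degenerate_fraction(e) for e in ensembles[alg]]
            logger.info("mu=%s %s: ensembles done", mu, alg)

        summaries[mu] = summarize_experiment(
            ensembles,
            n_nmi_pairs=min(1000, config.n_runs**2),
            seed=config.master_seed + mu_idx,
        )

        for alg in config.algorithms:
            n_degen = sum(
                f > DEGENERATE_RUN_THRESHOLD for f in degen[alg]
            )
            excluded = n_degen > DEGENERATE_CELL_THRESHOLD * len(graphs)
            for ftype in config.feature_types:
                cell = CellResult(
                    mu=mu,
                    algorithm=alg,
                    feature_type=ftype,
                    status="excluded-degenerate" if excluded else "completed",
                    degenerate_fractions=degen[alg],
                )
                cells[(mu, alg, ftype)] = cell
                if excluded:
                    logger.warning(
                        "cell mu=%s %s %s excluded: %d/%d graphs degenerate",
                        mu, alg, ftype, n_degen, len(graphs),
                    )
                    continue
                for i, (g, e) in enumerate(zip(graphs, ensembles[alg])):
                    cfg = replace(
                        config.classifier,
                        seed=config.analysis_seed(mu_idx, alg, i),
                    )
                    gid = f"mu{mu}-g{i}"
                    if ftype == "node":
                        res = node_experiment(g, e, cfg, graph_id=gid)
                    else:
                        res = pair_experiment(
                            g, e, cfg, config.n_per_class, graph_id=gid
                        )
                    cell.importances.append(res)
                    logger.info(
                        "cell mu=%s %s %s: graph %d/%d analysed",
                        mu, alg, ftype, i + 1, len(graphs),
                    )
                cell.distributions = collect_distributions(cell.importances)
                cell.shapiro = shapiro_suite(cell.distributions)
                if len(cell.distributions) >= 6:
                    cell.report = pairwise_wilcoxon_holm(cell.distributions)
                if out is not None:
                    _persist_cell(out, cell, config)
        if out is not None:
            for name, frame in summaries[mu].items():
                frame.to_csv(out / f"summary_mu{mu}_{name}.csv")
    return GridResult(cells=cells, summaries=summaries, config=config)


def _persist_cell(out: Path, cell: CellResult, config: ExperimentConfig) -> None:
    stem = f"mu{cell.mu}_{cell.algorithm}_{cell.feature_type}"
    payload = {
        "mu": cell.mu,
        "algorithm": cell.algorithm,
        "feature_type": cell.feature_type,
        "status": cell.status,
        "degenerate_fractions": cell.degenerate_fractions,
        "master_seed": config.master_seed,
        "n_runs": config.n_runs,
        "importances": [r.to_dict() for r in cell.importances],
    }
    (out / f"{stem}.json").write_text(json.dumps(payload, indent=2))
    if cell.distributions is not None:
        cell.distributions.to_csv(out / f"{stem}_distributions.csv")
    if cell.report is not None:
        cell.report.table.to_csv(out / f"{stem}_wilcoxon.csv", index=False)
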