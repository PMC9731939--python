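"""Random-forest training and permutation feature importance.

A 100-tree random forest is trained under stratified 5-fold
cross-validation repeated 10 times (50 evaluations). After each
evaluation, the permutation importance of every feature — the drop in
held-out accuracy when that feature's column is shuffled, averaged over a
few independent shuffles — is recorded; the final importance of a feature
on one graph is the mean of its 50 evaluation scores. Negative scores are
kept as computed: the downstream statistics compare whole distributions.

The shuffle-predict loop is vectorized: all shuffled copies of the
held-out fold are stacked into one matrix so each evaluation costs a
single forest prediction. A unit test cross-checks the scores against
scikit-learn's ``permutation_importance``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassifierConfig",
    "ImportanceResult",
    "train_and_importances",
    "collect_distributions",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Forest size, cross-validation scheme and shuffle count."""

    n_trees: int = 100
    n_folds: int = 5
    n_repeats: int = 10
    n_permutations: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.n_folds < 2:
            raise ValueError("need n_trees >= 1 and n_folds >= 2")
        if self.n_repeats < 1 or self.n_permutations < 1:
            raise ValueError("need n_repeats >= 1 and n_permutations >= 1")


@dataclass
class ImportanceResult:
    """Permutation importances of one feature table (one graph).

    ``raw`` holds the full (n_folds * n_repeats, n_features) evaluation
    matrix; ``mean_importance`` its per-feature mean; ``accuracy`` the
    held-out accuracy of each evaluation.
    """

    feature_names: tuple[str, ...]
    raw: np.ndarray
    accuracy: np.ndarray
    config: ClassifierConfig
    graph_id: str | None = None
    mean_importance: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.mean_importance = pd.Series(
            self.raw.mean(axis=0), index=list(self.feature_names)
        )

    def to_dict(self) -> dict:
        return {
            "graph_id": self.graph_id,
            "mean_importance": self.mean_importance.to_dict(),
            "mean_accuracy": float(self.accuracy.mean()),
            "raw": self.raw.tolist(),
            "config": self.config.__dict__,
        }


def _permutation_scores(
    model: RandomForestClassifier,
    X_test: np.ndarray,
    y_test: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Accuracy drop per feature, averaged over shuffles (vectorized)."""
    n, p = X_test.shape
    base = (model.predict(X_test) == y_test).mean()
    stacked = np.tile(X_test, (p * n_permutations, 1)).reshape(
        p, n_permutations, n, p
    )
    for j in range(p):
        for s in range(n_permutations):
            stacked[j, s, :, j] = rng.permutation(X_test[:, j])
    preds = model.predict(stacked.reshape(-1, p)).reshape(p, n_permutations, n)
    acc = (preds == y_test).mean(axis=2).mean(axis=1)
    return base - acc


def train_and_importances(
    table: pd.DataFrame,
    config: ClassifierConfig = ClassifierConfig(),
    graph_id: str | None = None,
) -> ImportanceResult:
    """Repeated cross-validated forest training with permutation importance.

    ``table`` must contain feature columns plus a binary ``label`` column
    with both classes present and at least ``n_folds`` rows per class.
    """
    if "label" not in table.columns:
        raise ValueError("feature table must contain a 'label' column")
    feature_names = tuple(c for c in table.columns if c != "label")
    X = table[list(feature_names)].to_numpy(dtype=np.float64)
    y = table["label"].to_numpy(dtype=np.int64)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("feature table contains a single class")
    if counts.min() < config.n_folds:
        raise ValueError(
            f"need >= {config.n_folds} rows per class, got {counts.min()}"
        )
    n_evals = config.n_folds * config.n_repeats
    raw = np.empty((n_evals, len(feature_names)))
    accuracy = np.empty(n_evals)
    ev = 0
    for rep in range(config.n_repeats):
        rep_seed = (config.seed + 7919 * rep) % (2**31)
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=rep_seed
        )
        for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            fold_seed = (rep_seed + fold) % (2**31)
            model = RandomForestClassifier(
                n_estimators=config.n_trees,
                random_state=fold_seed,
                n_jobs=1,
            ).fit(X[train_idx], y[train_idx])
            accuracy[ev] = model.score(X[test_idx], y[test_idx])
            raw[ev] = _permutation_scores(
                model,
                X[test_idx],
                y[test_idx],
                config.n_permutations,
                np.random.default_rng(fold_seed),
            )
            ev += 1
    return ImportanceResult(
        feature_names=feature_names,
        raw=raw,
        accuracy=accuracy,
        config=config,
        graph_id=graph_id,
    )


def collect_distributions(results: list[ImportanceResult]) -> pd.DataFrame:
    """Stack per-graph mean importances: rows = graphs, columns = features.

    These per-feature columns are the distributions the statistics module
    compares across graphs.
    """
    if not results:
        raise ValueError("no results to collect")
    names = results[0].feature_names
    for r in results[1:]:
        if r.feature_names != names:
            raise ValueError("results have mismatched feature sets")
    return pd.DataFrame(
        [r.mean_importance for r in results],
        index=[r.graph_id for r in results],
    )
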