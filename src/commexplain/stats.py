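"""Statistical methodology: power analysis, normality checks, paired
nonparametric comparisons with family-wise error control, NMI, and
experiment summary tables.

The per-feature importance distributions produced over many graphs are
compared pairwise: a Wilcoxon signed-rank test on the per-graph paired
differences for every unordered feature pair, with Bonferroni-Holm
step-down correction over the whole family. The number of graphs needed
is fixed in advance by a power analysis for a paired t-test (the pilot's
normal assumption) at a chosen Cohen's d, significance level and power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import normalized_mutual_info_score
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestPower

from .coassoc import (
    DegenerateLabelingError,
    build_coassociation,
    label_easy_hard,
    node_entropy,
)
from .detectors import RunEnsemble

__all__ = [
    "PowerSpec",
    "required_sample_size",
    "shapiro_suite",
    "StatReport",
    "pairwise_wilcoxon_holm",
    "nmi",
    "summarize_experiment",
]


@dataclass(frozen=True)
class PowerSpec:
    """Effect size (Cohen's d), significance level, and target power."""

    d: float = 0.3
    alpha: float = 0.05
    power: float = 0.9

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("effect size d must be positive")
        if not 0 < self.alpha < self.power < 1:
            raise ValueError("need 0 < alpha < power < 1")


def required_sample_size(spec: PowerSpec = PowerSpec()) -> int:
    """Smallest n giving the requested power for a two-sided paired t-test.

    Solved on the noncentral t distribution; the default spec
    (d=0.3, alpha=0.05, power=0.9) yields 119.
    """
    n = TTestPower().solve_power(
        effect_size=spec.d,
        alpha=spec.alpha,
        power=spec.power,
        alternative="two-sided",
    )
    return math.ceil(n)


def shapiro_suite(distributions: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk normality test per feature column.

    Returns a frame with columns ``p_value``, ``normal`` (p > 0.05) and
    ``degenerate`` (constant sample, for which the test is undefined and
    the feature is reported as not normal).
    """
    rows = {}
    for name, col in distributions.items():
        x = np.asarray(col, dtype=np.float64)
        if len(x) < 3:
            raise ValueError(f"feature {name!r}: need >= 3 observations")
        if np.ptp(x) == 0:
            rows[name] = {"p_value": 0.0, "normal": False, "degenerate": True}
            continue
        p = sps.shapiro(x).pvalue
        rows[name] = {"p_value": p, "normal": p > 0.05, "degenerate": False}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.attrs["fraction_normal"] = float(out["normal"].mean())
    return out


@dataclass
class StatReport:
    """Pairwise feature comparison results.

    ``table`` has one row per unordered feature pair with the raw and
    Holm-adjusted two-sided Wilcoxon signed-rank p-values, a significance
    flag at adjusted p < 0.05, and the direction (which feature's
    distribution is larger, by mean paired difference).
    """

    table: pd.DataFrame
    alpha: float = 0.05

    def significant_pairs(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def pairwise_wilcoxon_holm(
    distributions: pd.DataFrame, alpha: float = 0.05
) -> StatReport:
    """Wilcoxon signed-rank tests on all feature pairs with Holm correction.

    Rows of ``distributions`` are graphs (paired observations), columns
    are features; at least 6 graphs are required. Zero differences are
    handled by the Pratt method; a pair with all-zero differences gets
    p = 1 by convention and is flagged ``degenerate``.
    """
    if len(distributions) < 6:
        raise ValueError("need >= 6 paired observations (graphs)")
    records = []
    for a, b in combinations(distributions.columns, 2):
        diff = (distributions[a] - distributions[b]).to_numpy(dtype=np.float64)
        degenerate = bool(np.all(diff == 0))
        if degenerate:
            p = 1.0
        else:
            p = sps.wilcoxon(
                diff, zero_method="pratt", correction=True
            ).pvalue
        records.append(
            {
                "feature_a": a,
                "feature_b": b,
                "p_raw": p,
                "larger": a if diff.mean() > 0 else (b if diff.mean() < 0 else "tie"),
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame.from_records(records)
    reject, p_adj, _, _ = multipletests(
        table["p_raw"], alpha=alpha, method="holm"
    )
    table["p_holm"] = p_adj
    table["significant"] = reject
    return StatReport(table=table, alpha=alpha)


def nmi(p: np.ndarray, q: np.ndarray, average_method: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions in [0, 1].

    Invariant to label permutation; 1 iff the partitions agree up to
    relabelling, 0 when either partition is a single community (zero
    marginal entropy) or the labels are independent. Normalization uses
    the arithmetic mean of the marginal entropies by default (``min``,
    ``max`` and ``geometric`` are accepted).
    """
    p = np.asarray(p)
    q = np.asarray(q)
    if p.shape != q.shape:
        raise ValueError("partitions must cover the same node set")
    return float(normalized_mutual_info_score(p, q, average_method=average_method))


def _summary(values) -> dict[str, float]:
    arr = np.asarray(values, dtype=np.float64)
    return {
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "std": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
    }


def summarize_experiment(
    ensembles: dict[str, list[RunEnsemble]],
    n_nmi_pairs: int = 1000,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Summary tables over a cell's graphs: community counts, cross-algorithm
    NMI, and hard-node proportions.

    ``ensembles`` maps algorithm name to one ensemble per graph (all
    algorithms share the same graph list, in the same order). Three frames
    are returned:

    ``communities``
        per algorithm: mean/median/std of the number of communities per
        run, pooled over all runs of all graphs.
    ``nmi``
        per algorithm pair: mean/median/std of NMI over ``n_nmi_pairs``
        uniformly sampled (with replacement) cross-algorithm partition
        pairs per graph.
    ``hard_fraction``
        per algorithm: mean/median/std over graphs of the proportion of
        nodes labelled hard to cluster.
    """
    rng = np.random.default_rng(seed)
    algs = sorted(ensembles)
    n_graphs = {a: len(ensembles[a]) for a in algs}
    if len(set(n_graphs.values())) != 1 or min(n_graphs.values()) == 0:
        raise ValueError("every algorithm needs the same nonempty graph list")

    communities = {
        a: _summary(
            np.concatenate([e.community_counts() for e in ensembles[a]])
        )
        for a in algs
    }

    nmi_rows = {}
    for a, b in combinations(algs, 2):
        vals = []
        for ea, eb in zip(ensembles[a], ensembles[b]):
            ia = rng.integers(0, ea.R, size=n_nmi_pairs)
            ib = rng.integers(0, eb.R, size=n_nmi_pairs)
            vals.extend(
                nmi(ea.partitions[r1], eb.partitions[r2])
                for r1, r2 in zip(ia, ib)
            )
        nmi_rows[f"{a}-{b}"] = _summary(vals)

    hard = {}
    for a in algs:
        fractions = []
        for e in ensembles[a]:
            ent = node_entropy(build_coassociation(e))
            try:
                fractions.append(label_easy_hard(ent).hard.mean())
            except DegenerateLabelingError:
                # uniform entropies: nothing oscillates, no hard class
                fractions.append(0.0)
        hard[a] = _summary(fractions)

    return {
        "communities": pd.DataFrame.from_dict(communities, orient="index"),
        "nmi": pd.DataFrame.from_dict(nmi_rows, orient="index"),
        "hard_fraction": pd.DataFrame.from_dict(hard, orient="index"),
    }
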