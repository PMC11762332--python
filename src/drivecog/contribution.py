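"""Variance-weighted PCA-loading feature contributions.

After per-fold PCA, each retained component i explains a fraction
gamma_i of the training variance and carries unit-norm loadings w_{i,j}
over the original features.  A feature's contribution score is

    score_j = sum_i |w_{i,j}| * gamma_i

— the absolute loadings weighted by how much variance each component
actually explains, so features dominating low-variance components are
not overrated.  Scores are summed element-wise across cross-validation
folds and ranked descending to identify the kinematic features that
drive the learned representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_eval import PcaModel
from .turn_features import FEATURE_NAMES, N_FEATURES

__all__ = [
    "ContributionTable",
    "loading_contribution",
    "aggregate_contributions",
    "write_contributions",
    "plot_contributions",
]


@dataclass
class ContributionTable:
    """Per-feature contribution scores with a deterministic ranking.

    ``table`` columns: ``feature_index`` (1-based, canonical order),
    ``feature_name``, ``score`` (>= 0, unitless), ``rank`` (1 = highest
    score; ties broken by feature index), and ``score_normalized``
    (score / total score — an optional convenience, not part of the
    canonical metric).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table["score"] < 0).any():
            raise ValueError("contribution scores must be >= 0")
        ranks = np.sort(self.table["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(self.table) + 1)):
            raise ValueError("ranks must be a permutation of 1..n")

    def top(self, n: int = 5) -> pd.DataFrame:
        return self.table.nsmallest(n, "rank")


def loading_contribution(pca: PcaModel) -> np.ndarray:
    """Per-feature score vector from one fitted PCA.

    ``score_j = sum_i |w_{i,j}| * gamma_i`` over the retained components.
    For unit-norm loading rows each score is bounded by ``sum_i gamma_i``.
    """
    W = np.asarray(pca.loadings, float)
    gamma = np.asarray(pca.explained_variance_ratio, float)
    if W.shape[0] != gamma.shape[0]:
        raise ValueError(
            f"loadings have {W.shape[0]} components but gamma has "
            f"{gamma.shape[0]}"
        )
    return np.abs(W).T @ gamma


def aggregate_contributions(
    per_fold_scores: list[np.ndarray],
    feature_names: list[str] | None = None,
) -> ContributionTable:
    """Sum per-fold score vectors and rank features descending.

    All folds must agree on length.  Ties in score break toward the
    lower (earlier) feature index, keeping the ranking deterministic.
    """
    if not per_fold_scores:
        raise ValueError("at least one fold score vector is required")
    lengths = {len(np.atleast_1d(s)) for s in per_fold_scores}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent score-vector lengths: {sorted(lengths)}")
    (p,) = lengths
    names = feature_names
    if names is None:
        names = FEATURE_NAMES if p == N_FEATURES else [f"f{j+1:02d}" for j in range(p)]
    if len(names) != p:
        raise ValueError("feature_names length does not match scores")

    total = np.sum([np.asarray(s, float) for s in per_fold_scores], axis=0)
    order = np.lexsort((np.arange(p), -total))  # descending, index tiebreak
    rank = np.empty(p, int)
    rank[order] = np.arange(1, p + 1)
    grand = total.sum()
    table = pd.DataFrame(
        {
            "feature_index": np.arange(1, p + 1),
            "feature_name": names,
            "score": total,
            "rank": rank,
            "score_normalized": total / grand if grand > 0 else np.zeros(p),
        }
    )
    return ContributionTable(table=table)


def write_contributions(contrib: ContributionTable, path) -> None:
    """Write the contribution table sorted by rank."""
    contrib.table.sort_values("rank").to_csv(
        path, index=False, float_format="%.9g"
    )


def plot_contributions(contrib: ContributionTable, path) -> None:
    """Bar chart of contribution scores, highest first."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = contrib.table.sort_values("rank")
    fig, ax = plt.subplots(figsize=(10, 6))
    ax.bar(np.arange(len(df)), df["score"])
    ax.set_xticks(np.arange(len(df)))
    ax.set_xticklabels(
        [f"{i}" for i in df["feature_index"]], fontsize=7
    )
    ax.set_xlabel("feature index (sorted by contribution)")
    ax.set_ylabel("summed |loading| x explained variance")
    ax.set_title("Feature contributions across folds")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
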