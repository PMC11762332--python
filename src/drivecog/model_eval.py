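"""Leakage-free classifier evaluation under inter-subject cross-validation.

The central methodological requirement is that each subject's data live
in exactly one test fold and that every data-dependent statistic —
missing-feature imputation, z-scoring, PCA — is fit on the training
subjects of a fold only.  Pooling subjects' records across folds (or
fitting preprocessing globally) lets a model memorize individual driving
styles and inflates apparent diagnostic performance; this module makes
that failure mode structurally impossible.

Positive class is MCI throughout, so sensitivity is the ability to
identify impaired drivers and specificity the ability to clear healthy
ones.  Metrics with a zero denominator are recorded as missing (NaN),
never as zero, and are excluded from fold averages with the contributing
fold count reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.decomposition import PCA
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .turn_features import FEATURE_COLUMNS

__all__ = [
    "FoldAssignment",
    "PcaModel",
    "ConfusionCounts",
    "FoldMetrics",
    "CVResult",
    "MODEL_NAMES",
    "POSITIVE_CLASS",
    "assign_folds",
    "fit_preprocessor",
    "train_classifier",
    "evaluate_fold",
    "cross_validate",
]

POSITIVE_CLASS = "MCI"
METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class FoldAssignment:
    """Subject-level, stratified k-fold partition."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    # ((train_ids, test_ids), ...) per fold

    @property
    def k(self) -> int:
        return len(self.folds)

    def __post_init__(self) -> None:
        all_test: list[str] = []
        for train, test in self.folds:
            if set(train) & set(test):
                raise ValueError("train and test overlap within a fold")
            all_test.extend(test)
        if len(all_test) != len(set(all_test)):
            raise ValueError("a subject appears in more than one test fold")
        universe = set(all_test)
        for train, test in self.folds:
            if set(train) | set(test) != universe:
                raise ValueError("train + test must cover all subjects")


def assign_folds(
    roster: pd.DataFrame, k: int = 4, seed: int = 0
) -> FoldAssignment:
    """Stratified subject-level k-fold split, deterministic given ``seed``.

    Per-status test counts differ by at most one across folds.  Raises if
    ``k`` exceeds the number of subjects; warns when a status group has
    fewer than ``k`` members (some test folds then lack that status).
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    ids = roster["subject_id"].to_numpy()
    status = roster["status"].to_numpy()
    if k > len(ids):
        raise ValueError(
            f"k={k} exceeds the number of subjects ({len(ids)})"
        )
    counts = pd.Series(status).value_counts()
    scarce = counts[counts < k]
    if len(scarce):
        warnings.warn(
            f"status group(s) {list(scarce.index)} have fewer than k={k} "
            "members; some test folds will lack that status",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(ids, status):
        folds.append((tuple(ids[train_idx]), tuple(ids[test_idx])))
    return FoldAssignment(folds=tuple(folds))


@dataclass
class PcaModel:
    """Training-fold preprocessing state: impute -> scale -> project.

    ``loadings`` row i holds the unit-norm loadings of retained component
    i over the original features; ``explained_variance_ratio`` is the
    per-component fraction of total (scaled) variance.
    """

    impute_means: np.ndarray  # (p,)
    scale_mean: np.ndarray  # (p,)
    scale_std: np.ndarray  # (p,), zero-variance entries clamped to 1
    loadings: np.ndarray  # (n_components, p)
    explained_variance_ratio: np.ndarray  # (n_components,)

    def __post_init__(self) -> None:
        g = self.explained_variance_ratio
        if np.any(g < -1e-12) or np.any(g > 1 + 1e-12):
            raise ValueError("explained variance ratios must lie in [0, 1]")
        if np.any(np.diff(g) > 1e-12):
            raise ValueError("explained variance ratios must be non-increasing")
        if g.sum() > 1 + 1e-9:
            raise ValueError("explained variance ratios must sum to <= 1")
        norms = np.linalg.norm(self.loadings, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("each loading row must have unit Euclidean norm")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply the frozen impute/scale/project chain to new rows."""
        X = np.array(X, float)
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.broadcast_to(self.impute_means, X.shape)[nan]
        Z = (X - self.scale_mean) / self.scale_std
        return Z @ self.loadings.T


def fit_preprocessor(
    train_features: np.ndarray,
    n_components: int = 5,
    variance_threshold: float | None = None,
) -> PcaModel:
    """Fit imputation, z-scoring and PCA on training rows only.

    Missing entries are imputed with the training-fold column mean.  By
    default 5 components are retained; pass ``variance_threshold`` to
    instead keep the smallest number of components reaching that
    cumulative explained-variance fraction.
    """
    X = np.array(train_features, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with >= 2 training rows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        impute_means = np.nanmean(X, axis=0)
    impute_means = np.nan_to_num(impute_means, nan=0.0)
    nan = np.isnan(X)
    if nan.any():
        X[nan] = np.broadcast_to(impute_means, X.shape)[nan]

    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    zero_var = std == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature(s); scale std "
            "clamped to 1",
            stacklevel=2,
        )
        std = np.where(zero_var, 1.0, std)
    Z = (X - mean) / std

    max_comp = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=min(max(n_components, 1), max_comp))
    if variance_threshold is not None:
        pca = PCA(n_components=max_comp)
    pca.fit(Z)
    W = pca.components_
    # all-constant training data has zero total variance; report 0 ratios
    gamma = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
    if variance_threshold is not None:
        keep = int(np.searchsorted(np.cumsum(gamma), variance_threshold) + 1)
        keep = min(keep, len(gamma))
        W, gamma = W[:keep], gamma[:keep]
    return PcaModel(
        impute_means=impute_means,
        scale_mean=mean,
        scale_std=std,
        loadings=W,
        explained_variance_ratio=gamma,
    )


def _model_factory(name: str, seed: int):
    registry = {
        "SVM": lambda: SVC(C=1.0, kernel="rbf", gamma="scale"),
        "RandomForest": lambda: RandomForestClassifier(
            n_estimators=100,
            criterion="gini",
            max_depth=None,
            min_samples_split=2,
            min_samples_leaf=1,
            random_state=seed,
        ),
        "AdaBoost": lambda: AdaBoostClassifier(
            n_estimators=50, learning_rate=1.0, random_state=seed
        ),
        "KNN": lambda: KNeighborsClassifier(
            n_neighbors=5, algorithm="auto", metric="minkowski", p=2
        ),
        "QDA": lambda: QuadraticDiscriminantAnalysis(
            priors=None, reg_param=0.0
        ),
        # default penalty is the l2 ridge term, i.e. penalty='l2'
        "LogisticRegression": lambda: LogisticRegression(
            C=1.0, solver="lbfgs", max_iter=100
        ),
    }
    if name not in registry:
        raise ValueError(
            f"unknown model {name!r}; valid names: {sorted(registry)}"
        )
    return registry[name]()


MODEL_NAMES = (
    "SVM",
    "RandomForest",
    "AdaBoost",
    "KNN",
    "QDA",
    "LogisticRegression",
)


def train_classifier(
    name: str,
    train_scores: np.ndarray,
    train_labels: np.ndarray,
    seed: int = 0,
):
    """Fit one of the six standard classifiers on PCA scores.

    ``train_labels`` are status strings; MCI is the positive class.
    Stochastic learners are seeded.  Raises for unknown names or
    single-class training labels.
    """
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError(
            "training data contain a single class; a binary classifier "
            "needs both statuses"
        )
    model = _model_factory(name, seed)
    with warnings.catch_warnings():
        # QDA emits collinearity warnings on small folds; that is expected
        warnings.simplefilter("ignore", UserWarning)
        model.fit(np.asarray(train_scores, float), y)
    return model


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with MCI as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class FoldMetrics:
    """Diagnostic metrics for one fold; undefined values are NaN."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "FoldMetrics":
        def ratio(num: int, den: int) -> float:
            return num / den if den > 0 else float("nan")

        return cls(
            accuracy=ratio(c.tp + c.tn, c.total),
            sensitivity=ratio(c.tp, c.tp + c.fn),
            specificity=ratio(c.tn, c.tn + c.fp),
            ppv=ratio(c.tp, c.tp + c.fp),
            npv=ratio(c.tn, c.tn + c.fn),
        )


def evaluate_fold(
    model, test_scores: np.ndarray, test_labels: np.ndarray
) -> tuple[ConfusionCounts, FoldMetrics]:
    """Confusion counts and diagnostic metrics on one test fold."""
    y = np.asarray(test_labels)
    if len(y) == 0:
        raise ValueError("test set is empty")
    pred = model.predict(np.asarray(test_scores, float))
    pos = y == POSITIVE_CLASS
    hit = pred == y
    counts = ConfusionCounts(
        tp=int(np.sum(pos & hit)),
        fp=int(np.sum(~pos & ~hit)),
        tn=int(np.sum(~pos & hit)),
        fn=int(np.sum(pos & ~hit)),
    )
    return counts, FoldMetrics.from_counts(counts)


@dataclass
class CVResult:
    """Cross-validation output: per-fold detail plus summaries.

    ``per_fold`` has one row per (model, fold) with confusion counts and
    metrics; ``pca_models`` holds each fold's fitted preprocessing state
    (shared by all models within a fold) for downstream loading analysis.
    """

    per_fold: pd.DataFrame
    pca_models: dict[int, PcaModel]
    assignment: FoldAssignment

    def summary(self) -> pd.DataFrame:
        """Mean +/- std of each metric across folds, per model.

        NaN (undefined) fold values are excluded; ``<metric>_n`` reports
        how many folds contributed.  Standard deviation is the population
        std across contributing folds, matching fold-level reporting.
        """
        rows = []
        for model, grp in self.per_fold.groupby("model", sort=False):
            row: dict[str, float | str] = {"model": model}
            for m in METRICS:
                vals = grp[m].to_numpy(float)
                ok = ~np.isnan(vals)
                row[f"{m}_mean"] = float(np.mean(vals[ok])) if ok.any() else np.nan
                row[f"{m}_std"] = float(np.std(vals[ok])) if ok.any() else np.nan
                row[f"{m}_n"] = int(ok.sum())
            rows.append(row)
        return pd.DataFrame(rows)

    def per_class_accuracy(self) -> pd.DataFrame:
        """Pooled per-class accuracy (healthy, MCI, all) per model.

        Pools confusion counts across folds: healthy accuracy is
        TN/(TN+FP), MCI accuracy TP/(TP+FN), overall (TP+TN)/total.
        """
        rows = []
        for model, grp in self.per_fold.groupby("model", sort=False):
            tp, fp = grp["TP"].sum(), grp["FP"].sum()
            tn, fn = grp["TN"].sum(), grp["FN"].sum()
            rows.append(
                {
                    "model": model,
                    "healthy": tn / (tn + fp) if tn + fp else np.nan,
                    "mci": tp / (tp + fn) if tp + fn else np.nan,
                    "all": (tp + tn) / (tp + tn + fp + fn),
                }
            )
        return pd.DataFrame(rows)


def cross_validate(
    features: pd.DataFrame,
    roster: pd.DataFrame,
    model_names: tuple[str, ...] = MODEL_NAMES,
    k: int = 4,
    seed: int = 0,
    n_components: int = 5,
    variance_threshold: float | None = None,
) -> CVResult:
    """Run the full leakage-free evaluation.

    ``features`` is the per-subject feature table (``subject_id``,
    ``status``, ``f01``..``f26``).  All preprocessing (imputation,
    scaling, PCA) is fit inside each fold on training subjects only.
    """
    for name in model_names:
        _model_factory(name, 0)  # validate names up front
    feat = features.set_index("subject_id")
    missing_ids = set(roster["subject_id"]) - set(feat.index)
    if missing_ids:
        raise ValueError(
            f"roster subjects without feature rows: {sorted(missing_ids)}"
        )
    assignment = assign_folds(roster, k=k, seed=seed)
    status = roster.set_index("subject_id")["status"]

    rows = []
    pca_models: dict[int, PcaModel] = {}
    for fold_idx, (train_ids, test_ids) in enumerate(assignment.folds):
        try:
            X_train = feat.loc[list(train_ids), FEATURE_COLUMNS].to_numpy(float)
            X_test = feat.loc[list(test_ids), FEATURE_COLUMNS].to_numpy(float)
            y_train = status.loc[list(train_ids)].to_numpy()
            y_test = status.loc[list(test_ids)].to_numpy()

            pca = fit_preprocessor(
                X_train,
                n_components=n_components,
                variance_threshold=variance_threshold,
            )
            pca_models[fold_idx] = pca
            S_train = pca.transform(X_train)
            S_test = pca.transform(X_test)

            for name in model_names:
                model = train_classifier(name, S_train, y_train, seed=seed)
                counts, metrics = evaluate_fold(model, S_test, y_test)
                rows.append(
                    {
                        "model": name,
                        "fold": fold_idx,
                        "TP": counts.tp,
                        "FP": counts.fp,
                        "TN": counts.tn,
                        "FN": counts.fn,
                        **{m: getattr(metrics, m) for m in METRICS},
                    }
                )
        except Exception as err:
            raise RuntimeError(f"fold {fold_idx} failed: {err}") from err

    per_fold = pd.DataFrame(rows).sort_values(["model", "fold"]).reset_index(
        drop=True
    )
    return CVResult(
        per_fold=per_fold, pca_models=pca_models, assignment=assignment
    )


def write_results(result: CVResult, directory) -> None:
    """Write the display summary, full-precision summary and fold detail.

    ``results_display.csv`` mirrors a published-style table (percent, 0
    decimals); ``results_full.csv`` keeps full precision;
    ``folds.csv`` has per-(model, fold) confusion counts and metrics.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    summary = result.summary()
    display = summary[["model"]].copy()
    for m in METRICS:
        display[m] = [
            f"{mu * 100:.0f} ± {sd * 100:.0f}%"
            if np.isfinite(mu)
            else "undefined"
            for mu, sd in zip(summary[f"{m}_mean"], summary[f"{m}_std"])
        ]
    display.to_csv(directory / "results_display.csv", index=False)
    summary.to_csv(
        directory / "results_full.csv", index=False, float_format="%.9g"
    )
    result.per_fold.to_csv(
        directory / "folds.csv", index=False, float_format="%.9g"
    )
    result.per_class_accuracy().to_csv(
        directory / "per_class_accuracy.csv", index=False, float_format="%.9g"
    )
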