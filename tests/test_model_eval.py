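"""Fold assignment, preprocessing, classifiers, metrics, leakage guard."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from drivecog.datasets import pilot_roster
from drivecog.model_eval import (
    MODEL_NAMES,
    ConfusionCounts,
    FoldMetrics,
    assign_folds,
    cross_validate,
    evaluate_fold,
    fit_preprocessor,
    train_classifier,
)
from drivecog.turn_features import FEATURE_COLUMNS


def _feature_frame(roster, rng, shift_mci=0.0):
    """Random 26-feature table; optional mean shift for MCI rows."""
    rows = []
    for r in roster.itertuples(index=False):
        x = rng.normal(0, 1, 26)
        if r.status == "MCI":
            x = x + shift_mci
        rows.append(
            {"subject_id": r.subject_id, "status": r.status,
             **{c: v for c, v in zip(FEATURE_COLUMNS, x)}}
        )
    return pd.DataFrame(rows)


# --- fold assignment ---


def test_pilot_roster_fold_sizes_and_stratification():
    roster = pilot_roster()
    fa = assign_folds(roster, k=4, seed=0)
    sizes = sorted(len(test) for _, test in fa.folds)
    assert sizes == [5, 5, 5, 6]
    status = roster.set_index("subject_id")["status"]
    for _, test in fa.folds:
        assert sum(status[t] == "MCI" for t in test) == 2


def test_forced_stratification_tiny_roster():
    roster = pd.DataFrame(
        {
            "subject_id": list("ABCD"),
            "age": [70] * 4,
            "sex": ["Male"] * 4,
            "status": ["Healthy", "Healthy", "MCI", "MCI"],
        }
    )
    fa = assign_folds(roster, k=2, seed=1)
    status = roster.set_index("subject_id")["status"]
    for _, test in fa.folds:
        assert sorted(status[t] for t in test) == ["Healthy", "MCI"]


def test_folds_partition_roster_exactly():
    """Brute-force set verification: disjoint test folds covering everyone."""
    roster = pilot_roster()
    fa = assign_folds(roster, k=4, seed=3)
    all_ids = set(roster["subject_id"])
    seen: set[str] = set()
    for train, test in fa.folds:
        assert set(train) | set(test) == all_ids
        assert not set(train) & set(test)
        assert not seen & set(test)
        seen |= set(test)
    assert seen == all_ids


def test_fold_assignment_deterministic():
    roster = pilot_roster()
    assert assign_folds(roster, 4, 7) == assign_folds(roster, 4, 7)
    assert assign_folds(roster, 4, 7) != assign_folds(roster, 4, 8)


def test_k_exceeding_subjects_rejected():
    roster = pilot_roster()
    with pytest.raises(ValueError, match="exceeds the number of subjects"):
        assign_folds(roster, k=22, seed=0)


def test_scarce_status_warns():
    roster = pd.DataFrame(
        {
            "subject_id": list("ABCDE"),
            "age": [70] * 5,
            "sex": ["Male"] * 5,
            "status": ["Healthy"] * 4 + ["MCI"],
        }
    )
    with pytest.warns(UserWarning, match="fewer than k"):
        assign_folds(roster, k=4, seed=0)


# --- preprocessing ---


def test_rank_one_data_single_dominant_component():
    rng = np.random.default_rng(0)
    X = np.zeros((10, 4))
    X[:, 2] = rng.normal(0, 3, 10)  # variance only on feature 3
    pca = fit_preprocessor(X, n_components=1)
    assert pca.explained_variance_ratio[0] == pytest.approx(1.0)
    loading = np.abs(pca.loadings[0])
    assert loading[2] == pytest.approx(1.0, abs=1e-9)


def test_known_covariance_eigenstructure():
    """Four-point set with sample covariance [[2,1],[1,2]].

    Eigenvalues 3 and 1 give explained-variance ratios 0.75/0.25; after
    per-feature z-scoring the correlation [[1,.5],[.5,1]] has eigenvalues
    1.5/0.5 — the same ratios (closed-form eigendecomposition oracle).
    """
    u1 = np.array([1.0, 1.0]) / np.sqrt(2)
    u2 = np.array([1.0, -1.0]) / np.sqrt(2)
    c1, c2 = np.sqrt(6.0), np.sqrt(2.0)
    X = np.vstack([c1 * u1, -c1 * u1, c2 * u2, -c2 * u2])
    cov = (X.T @ X) / len(X)
    np.testing.assert_allclose(cov, [[2, 1], [1, 2]], atol=1e-12)
    pca = fit_preprocessor(X, n_components=2)
    np.testing.assert_allclose(
        pca.explained_variance_ratio, [0.75, 0.25], atol=1e-9
    )


def test_default_retains_five_components():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 1, (16, 26))
    pca = fit_preprocessor(X)
    assert pca.n_components == 5
    norms = np.linalg.norm(pca.loadings, axis=1)
    np.testing.assert_allclose(norms, 1.0, atol=1e-9)


def test_variance_threshold_selects_smallest_sufficient():
    rng = np.random.default_rng(2)
    X = rng.normal(0, 1, (20, 6)) * np.array([5, 3, 1, 0.5, 0.3, 0.1])
    pca = fit_preprocessor(X, variance_threshold=0.85)
    cum = np.cumsum(pca.explained_variance_ratio)
    assert cum[-1] >= 0.85
    assert pca.n_components >= 2
    smaller = fit_preprocessor(X, n_components=pca.n_components - 1)
    assert np.sum(smaller.explained_variance_ratio) < 0.85


def test_zero_variance_feature_clamped_with_warning():
    X = np.column_stack([np.arange(8.0), np.full(8, 3.0)])
    with pytest.warns(UserWarning, match="zero-variance"):
        pca = fit_preprocessor(X, n_components=1)
    assert pca.scale_std[1] == 1.0


def test_imputation_uses_training_means():
    X = np.array([[1.0, 10.0], [3.0, np.nan], [5.0, 30.0]])
    pca = fit_preprocessor(X, n_components=1)
    assert pca.impute_means[1] == pytest.approx(20.0)
    # transform imputes new missing entries with the frozen training mean
    out = pca.transform(np.array([[np.nan, np.nan]]))
    expected = pca.transform(np.array([[3.0, 20.0]]))
    np.testing.assert_allclose(out, expected)


# --- classifiers ---


def test_unknown_model_name_lists_valid_names():
    with pytest.raises(ValueError, match="SVM"):
        train_classifier("GradientBoost", np.zeros((4, 2)), ["a", "b", "a", "b"])


def test_single_class_training_rejected():
    with pytest.raises(ValueError, match="single class"):
        train_classifier("KNN", np.zeros((4, 2)), ["Healthy"] * 4)


@pytest.mark.parametrize("name", MODEL_NAMES)
def test_separated_clusters_memorized(name):
    rng = np.random.default_rng(0)
    X = np.vstack(
        [rng.normal(-5, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3))]
    )
    y = np.array(["Healthy"] * 10 + ["MCI"] * 10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = train_classifier(name, X, y, seed=0)
    assert np.mean(model.predict(X) == y) == 1.0


@pytest.mark.parametrize("name", ["KNN", "LogisticRegression", "SVM"])
def test_contradictory_duplicates_cap_training_accuracy(name):
    """Identical points with opposing labels: no deterministic classifier
    can exceed 50% training accuracy (counting argument on duplicates)."""
    X = np.tile(np.array([[1.0, 2.0]]), (10, 1))
    y = np.array(["Healthy", "MCI"] * 5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = train_classifier(name, X, y, seed=0)
    assert np.mean(model.predict(X) == y) <= 0.5


# --- metrics ---


class _Stub:
    def __init__(self, preds):
        self._p = np.asarray(preds)

    def predict(self, X):
        return self._p[: len(X)]


def test_hand_counted_confusion_metrics():
    y = ["MCI", "MCI", "Healthy", "Healthy", "Healthy", "Healthy"]
    pred = ["MCI", "Healthy", "MCI", "Healthy", "Healthy", "Healthy"]
    counts, metrics = evaluate_fold(_Stub(pred), np.zeros((6, 2)), y)
    assert (counts.tp, counts.fn, counts.fp, counts.tn) == (1, 1, 1, 3)
    assert metrics.sensitivity == pytest.approx(0.5)
    assert metrics.specificity == pytest.approx(0.75)
    assert metrics.accuracy == pytest.approx(4 / 6)
    assert metrics.ppv == pytest.approx(0.5)
    assert metrics.npv == pytest.approx(0.75)


def test_perfect_predictions_all_metrics_one():
    y = ["MCI", "Healthy", "MCI", "Healthy"]
    _, metrics = evaluate_fold(_Stub(y), np.zeros((4, 2)), y)
    for m in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
        assert getattr(metrics, m) == 1.0


def test_no_positive_predictions_ppv_undefined_not_zero():
    y = ["MCI", "MCI", "Healthy", "Healthy"]
    pred = ["Healthy"] * 4
    _, metrics = evaluate_fold(_Stub(pred), np.zeros((4, 2)), y)
    assert np.isnan(metrics.ppv)
    assert metrics.sensitivity == 0.0
    assert metrics.specificity == 1.0
    assert not np.isnan(metrics.npv)


def test_empty_test_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        evaluate_fold(_Stub([]), np.zeros((0, 2)), [])


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    tp=st.integers(0, 20),
    fp=st.integers(0, 20),
    tn=st.integers(0, 20),
    fn=st.integers(0, 20),
)
def test_metric_identities(tp, fp, tn, fn):
    """accuracy = (sens*P + spec*N) / (P+N) whenever both are defined."""
    if tp + fp + tn + fn == 0:
        return
    m = FoldMetrics.from_counts(ConfusionCounts(tp, fp, tn, fn))
    p, n = tp + fn, tn + fp
    if p > 0 and n > 0:
        assert m.accuracy == pytest.approx(
            (m.sensitivity * p + m.specificity * n) / (p + n)
        )
    for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
        v = getattr(m, name)
        assert np.isnan(v) or 0.0 <= v <= 1.0


# --- cross-validation ---


@pytest.fixture(scope="module")
def separable_cv():
    roster = pilot_roster()
    feats = _feature_frame(roster, np.random.default_rng(0), shift_mci=6.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return feats, roster, cross_validate(feats, roster, k=4, seed=0)


def test_no_subject_in_both_train_and_test(separable_cv):
    _, _, res = separable_cv
    for train, test in res.assignment.folds:
        assert not set(train) & set(test)


def test_preprocessing_fit_on_training_rows_only(separable_cv):
    """Scaler statistics equal the train-row mean and change if a test
    subject is added — proof they were not fit on test data."""
    feats, roster, res = separable_cv
    feat = feats.set_index("subject_id")
    train, test = res.assignment.folds[0]
    X_train = feat.loc[list(train), FEATURE_COLUMNS].to_numpy(float)
    np.testing.assert_allclose(
        res.pca_models[0].scale_mean, X_train.mean(axis=0), rtol=1e-12
    )
    X_aug = feat.loc[list(train) + [test[0]], FEATURE_COLUMNS].to_numpy(float)
    assert not np.allclose(X_aug.mean(axis=0), res.pca_models[0].scale_mean)


def test_summary_matches_brute_force_recomputation(separable_cv):
    _, _, res = separable_cv
    summary = res.summary().set_index("model")
    for model, grp in res.per_fold.groupby("model"):
        accs = []
        for r in grp.itertuples(index=False):
            accs.append((r.TP + r.TN) / (r.TP + r.TN + r.FP + r.FN))
        assert summary.loc[model, "accuracy_mean"] == pytest.approx(
            np.mean(accs)
        )
        assert summary.loc[model, "accuracy_std"] == pytest.approx(
            np.std(accs)
        )


def test_cross_validation_deterministic(separable_cv):
    feats, roster, res = separable_cv
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res2 = cross_validate(feats, roster, k=4, seed=0)
    pd.testing.assert_frame_equal(res.per_fold, res2.per_fold)


def test_undefined_fold_metrics_excluded_from_mean():
    """A never-positive model leaves PPV undefined in every fold; the
    summary must report 0 contributing folds, not a zero mean."""
    roster = pilot_roster()
    feats = _feature_frame(roster, np.random.default_rng(3), shift_mci=0.0)
    # make features constant: every model predicts the majority class
    for c in FEATURE_COLUMNS:
        feats[c] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = cross_validate(feats, roster, model_names=("KNN",), k=4, seed=0)
    s = res.summary().iloc[0]
    assert s["sensitivity_mean"] == 0.0
    assert s["specificity_mean"] == 1.0
    assert s["ppv_n"] == 0 and np.isnan(s["ppv_mean"])


def test_missing_feature_rows_rejected(separable_cv):
    feats, roster, _ = separable_cv
    with pytest.raises(ValueError, match="without feature rows"):
        cross_validate(feats.iloc[:-1], roster, k=4, seed=0)


def test_per_class_accuracy_breakdown(separable_cv):
    _, _, res = separable_cv
    pc = res.per_class_accuracy()
    assert set(pc.columns) == {"model", "healthy", "mci", "all"}
    assert len(pc) == len(MODEL_NAMES)
    assert pc[["healthy", "mci", "all"]].dropna().ge(0).all().all()
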