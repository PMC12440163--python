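"""Classifiers, vote aggregation, metrics and the nested LOSO driver."""

import numpy as np
import pandas as pd
import pytest

import mobilegait as mg
from mobilegait.crossval import (DEFAULT_SPACES, ModelSpec, _vote,
                                 build_estimator, compute_metrics,
                                 fit_predict_windows, fuse_views_vote,
                                 inner_tune, nested_loso_evaluate,
                                 per_class_report, sample_params,
                                 video_majority_vote)

CLASSES = np.array(["ANT", "CIR", "NOR"])


def toy_features(n_subjects=6, per=4, seed=0, signal=1.0):
    """Tiny separable window-feature table with full provenance metadata."""
    rng = np.random.default_rng(seed)
    rows, meta = [], []
    class_shift = {"ANT": (0, 0), "CIR": (3, 0), "NOR": (0, 3),
                   "CRO": (3, 3), "PAR": (-3, 0), "TRE": (0, -3),
                   "VAU": (-3, -3)}
    for s in range(n_subjects):
        for label in ("ANT", "CIR", "NOR", "CRO", "PAR", "TRE", "VAU"):
            for view in ("frontal", "sagittal"):
                for direction in ("left", "right"):
                    vid = f"S{s}_{label}_{view}_{direction}"
                    for w in range(per):
                        dx, dy = class_shift[label]
                        rows.append([signal * dx + rng.normal(),
                                     signal * dy + rng.normal(),
                                     rng.normal()])
                        meta.append({"video_id": vid, "subject_id": f"S{s}",
                                     "view": view, "direction": direction,
                                     "label": label, "start_frame": 15 * w})
    X = pd.DataFrame(rows, columns=["left_knee_x__mean", "right_ankle_y__mean",
                                    "nose_z__mean"])
    return X, pd.DataFrame(meta)


def test_sample_params_deterministic_and_in_space():
    spec = ModelSpec(family="gradient-boosted-trees", budget=3, seed=1)
    a = sample_params(spec, np.random.default_rng(9))
    b = sample_params(spec, np.random.default_rng(9))
    assert a == b
    assert 2 <= a["max_depth"] <= 8
    assert 0.01 <= a["learning_rate"] <= 0.3
    assert set(a) == set(DEFAULT_SPACES["gradient-boosted-trees"])


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(family="deep-net")
    with pytest.raises(ValueError):
        ModelSpec(budget=0)


FIXED_PARAMS = {
    "kernel-svm": {"C": 10.0, "gamma": 0.1, "kernel": "rbf"},
    "random-forest": {"n_estimators": 50},
    "gradient-boosted-trees": {"max_depth": 4, "learning_rate": 0.3,
                               "n_estimators": 60},
}


@pytest.mark.parametrize("family", ["kernel-svm", "random-forest",
                                    "gradient-boosted-trees"])
def test_fit_predict_memorizes_separable_toy(family):
    rng = np.random.default_rng(0)
    X = pd.DataFrame(np.vstack([rng.normal(loc=c * 4, size=(10, 3))
                                for c in range(3)]), columns=list("abc"))
    y = np.repeat(CLASSES, 10)
    est = build_estimator(family, FIXED_PARAMS[family], seed=0)
    labels, scores = fit_predict_windows(est, X, y, X, CLASSES)
    assert (labels == y).all()
    assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-6)
    assert scores.shape == (30, 3)


def test_fit_predict_rejects_column_mismatch():
    X = pd.DataFrame(np.zeros((4, 2)), columns=["a", "b"])
    X2 = pd.DataFrame(np.zeros((4, 2)), columns=["a", "c"])
    est = build_estimator("random-forest", {"n_estimators": 5}, 0)
    with pytest.raises(ValueError, match="columns differ"):
        fit_predict_windows(est, X, np.array(["x", "x", "y", "y"]), X2)


def test_permuted_labels_give_chance_level_windows():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(700, 5)))
    X.columns = [f"f{i}" for i in range(5)]
    y = rng.permutation(np.repeat(np.array(sorted(mg.GAIT_CLASSES)), 100))
    est = build_estimator("random-forest", {"n_estimators": 50}, 0)
    est.fit(X.iloc[:490], y[:490])
    acc = (est.predict(X.iloc[490:]) == y[490:]).mean()
    se = np.sqrt((1 / 7) * (6 / 7) / 210)
    assert abs(acc - 1 / 7) < 3 * se


def test_votes_and_ties():
    scores = np.array([[0.6, 0.3, 0.1], [0.5, 0.4, 0.1], [0.2, 0.3, 0.5]])
    assert video_majority_vote(["CIR", "CIR", "NOR"], scores, CLASSES) == "CIR"
    assert video_majority_vote(["NOR"], scores[:1], CLASSES) == "NOR"
    # tie broken by higher mean class score
    tie_scores = np.array([[0.0, 0.6, 0.4], [0.0, 0.6, 0.4]])
    assert _vote(np.array(["CIR", "NOR"]), tie_scores, CLASSES) == "CIR"
    # full tie (equal scores) falls back to lexicographic class code
    flat = np.full((2, 3), 1 / 3)
    assert _vote(np.array(["NOR", "CIR"]), flat, CLASSES) == "CIR"


def test_fuse_views_pooling_and_degradation():
    f_lab = ["NOR", "NOR"]
    s_lab = ["PAR", "PAR", "PAR"]
    f_sc = np.full((2, 3), 1 / 3)
    s_sc = np.full((3, 3), 1 / 3)
    classes = np.array(["NOR", "PAR"])
    fused = fuse_views_vote(f_lab, np.full((2, 2), 0.5), s_lab,
                            np.full((3, 2), 0.5), classes)
    assert fused == "PAR"                      # pooled vote 3-2
    assert fuse_views_vote(f_lab, f_sc[:, :2], None, None, classes) == "NOR"
    with pytest.raises(ValueError):
        fuse_views_vote([], None, None, None, classes)


def test_compute_metrics_worked_example():
    y_true = ["a", "a", "b", "b"]
    y_pred = ["a", "a", "a", "b"]
    m = compute_metrics(y_true, y_pred, np.array(["a", "b"]))
    assert np.array_equal(m["confusion"], [[2, 0], [1, 1]])
    assert m["accuracy"] == m["confusion"].trace() / m["confusion"].sum()
    rep = per_class_report(y_true, y_pred, np.array(["a", "b"]))
    assert rep.loc["a", "precision"] == pytest.approx(2 / 3)
    assert rep.loc["a", "recall"] == 1.0
    assert rep.loc["a", "f1"] == pytest.approx(0.8)


def test_perfect_predictions_score_one():
    y = ["x", "y", "z", "x"]
    m = compute_metrics(y, y)
    assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall", "f1"))
    with pytest.raises(ValueError):
        compute_metrics([], [])


def test_per_class_report_consistency_with_binary_reduction():
    rng = np.random.default_rng(2)
    y_true = rng.choice(list("abc"), 60)
    y_pred = rng.choice(list("abc"), 60)
    rep = per_class_report(y_true, y_pred)
    from sklearn.metrics import precision_recall_fscore_support
    for cls in "abc":
        p, r, f1, _ = precision_recall_fscore_support(
            y_true == cls, y_pred == cls, average="binary", zero_division=0)
        assert rep.loc[cls, "precision"] == pytest.approx(p)
        assert rep.loc[cls, "recall"] == pytest.approx(r)
        assert rep.loc[cls, "f1"] == pytest.approx(f1)
    absent = per_class_report(["a", "b"], ["b", "b"], np.array(["a", "b"]))
    assert absent.loc["a", "precision"] == 0.0


def test_inner_tune_budget_one_and_determinism():
    X, meta = toy_features(n_subjects=6, per=2)
    spec = ModelSpec(family="random-forest", budget=1, seed=0,
                     space={"n_estimators": ("int", 5, 10)})
    groups = meta["subject_id"].to_numpy()
    best = inner_tune(X, meta["label"].to_numpy(), groups, spec,
                      np.random.default_rng(3))
    expect = sample_params(spec, np.random.default_rng(3))
    assert best == expect     # single candidate wins by definition

    spec2 = ModelSpec(family="random-forest", budget=3, seed=0,
                      space={"n_estimators": ("int", 5, 10)})
    a = inner_tune(X, meta["label"].to_numpy(), groups, spec2,
                   np.random.default_rng(4))
    b = inner_tune(X, meta["label"].to_numpy(), groups, spec2,
                   np.random.default_rng(4))
    assert a == b


def test_inner_tune_separable_ties_keep_first_sampled():
    """All candidates reach validation accuracy 1; first sampled wins."""
    X, meta = toy_features(n_subjects=6, per=2, signal=10.0)
    # candidates differ only in tree count; every one separates the toy
    spec = ModelSpec(family="random-forest", budget=3, seed=0,
                     space={"n_estimators": ("int", 20, 30),
                            "max_depth": ("choice", [10]),
                            "min_samples_split": ("choice", [2]),
                            "min_samples_leaf": ("choice", [1]),
                            "max_features": ("choice", [1.0])})
    rng_seed = 11
    best = inner_tune(X, meta["label"].to_numpy(),
                      meta["subject_id"].to_numpy(), spec,
                      np.random.default_rng(rng_seed))
    first = sample_params(spec, np.random.default_rng(rng_seed))
    assert best == first


def test_inner_tune_few_subjects_falls_back_with_warning():
    X, meta = toy_features(n_subjects=4, per=1)
    spec = ModelSpec(family="random-forest", budget=2, seed=0,
                     space={"n_estimators": ("int", 5, 8)})
    with pytest.warns(UserWarning, match="falling back"):
        inner_tune(X, meta["label"].to_numpy(), meta["subject_id"].to_numpy(),
                   spec, np.random.default_rng(0))


@pytest.fixture(scope="module")
def toy_cv_result():
    X, meta = toy_features(n_subjects=6, per=3, seed=5, signal=2.0)
    spec = ModelSpec(family="random-forest", budget=1, seed=0,
                     space={"n_estimators": ("int", 30, 40)})
    return X, meta, nested_loso_evaluate(X, meta, spec, view="combined",
                                         trials=2, seed=0)


def test_nested_loso_structure(toy_cv_result):
    X, meta, res = toy_cv_result
    # 2 trials x 6 folds x 3 levels x 4 metrics
    assert len(res.records) == 2 * 6 * 3 * 4
    assert set(res.records["level"]) == {"window", "video", "fused"}
    assert sorted(res.records["fold"].unique()) == [f"S{i}" for i in range(6)]
    assert res.confusions["video"].sum() == 2 * 6 * 28  # videos per subject
    # separable toy: voting denoises, videos at least as good as windows
    assert res.mean("video") >= res.mean("window") - 0.05
    assert res.mean("fused") >= 0.9


def test_nested_loso_deterministic(toy_cv_result):
    X, meta, res = toy_cv_result
    spec = ModelSpec(family="random-forest", budget=1, seed=0,
                     space={"n_estimators": ("int", 30, 40)})
    again = nested_loso_evaluate(X, meta, spec, view="combined", trials=2,
                                 seed=0)
    pd.testing.assert_frame_equal(res.records, again.records)


def test_nested_loso_view_filter_and_min_subjects(toy_cv_result):
    X, meta, _ = toy_cv_result
    spec = ModelSpec(family="random-forest", budget=1, seed=0,
                     space={"n_estimators": ("int", 10, 15)})
    res_f = nested_loso_evaluate(X, meta, spec, view="frontal", trials=1,
                                 seed=0)
    assert res_f.confusions["video"].sum() == 6 * 14  # frontal videos only
    with pytest.raises(ValueError, match="need >= 6"):
        sub = meta["subject_id"].isin([f"S{i}" for i in range(5)]).to_numpy()
        nested_loso_evaluate(X.loc[sub], meta.loc[sub], spec, trials=1, seed=0)


def test_ci_width_shrinks_with_trials():
    X, meta = toy_features(n_subjects=6, per=2, seed=8, signal=0.35)
    spec = ModelSpec(family="random-forest", budget=1, seed=0,
                     space={"n_estimators": ("int", 10, 15)})
    r2 = nested_loso_evaluate(X, meta, spec, trials=2, seed=1)
    r10 = nested_loso_evaluate(X, meta, spec, trials=10, seed=1)
    w2 = r2.summary().loc[("window", "accuracy"), "ci_half"]
    w10 = r10.summary().loc[("window", "accuracy"), "ci_half"]
    # expected ratio sqrt(5) ~ 2.24, allow generous sampling slack
    assert w10 < w2
    assert 1.2 < w2 / w10 < 4.5
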