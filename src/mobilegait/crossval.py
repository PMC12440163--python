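"""Window classifiers, vote aggregation and nested subject-wise evaluation.

The evaluation protocol is user-independent nested cross-validation: the
outer loop is leave-one-subject-out (LOSO); inside each outer training set,
feature selection and SMOTE are fitted, hyperparameters are tuned by seeded
random search with subject-wise inner folds, and the tuned model predicts
every window of the held-out subject. Window predictions are aggregated to
video labels by majority vote and to fused labels by pooling window votes
across the frontal and sagittal videos of the same subject x class x
direction. The whole procedure is repeated for several trials that differ
only in random seed; summaries are mean +/- 1.96 SE across trial x fold
scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             precision_recall_fscore_support)
from sklearn.model_selection import GroupKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import LabelEncoder, StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .selection import fresh_select, smote_oversample

FAMILIES = ("kernel-svm", "random-forest", "gradient-boosted-trees")

#: hyperparameter search spaces; each entry is (kind, *args) with kind in
#: {"int", "float", "logfloat", "choice"}
DEFAULT_SPACES: dict[str, dict] = {
    "kernel-svm": {
        "C": ("logfloat", 1e-2, 1e3),
        "gamma": ("logfloat", 1e-4, 1e1),
        "kernel": ("choice", ["linear", "rbf"]),
    },
    "random-forest": {
        "n_estimators": ("int", 100, 300),
        "max_depth": ("int", 3, 15),
        "min_samples_split": ("int", 2, 10),
        "min_samples_leaf": ("int", 1, 5),
        "max_features": ("choice", ["sqrt", "log2", 0.5]),
    },
    "gradient-boosted-trees": {
        "max_depth": ("int", 2, 8),
        "learning_rate": ("logfloat", 0.01, 0.3),
        "n_estimators": ("int", 50, 200),
        "min_child_weight": ("int", 1, 10),
        "subsample": ("float", 0.6, 1.0),
        "colsample_bytree": ("float", 0.5, 1.0),
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """A model family, its finite search space and a tuning budget."""

    family: str = "gradient-boosted-trees"
    space: dict = field(default_factory=dict)
    budget: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        object.__setattr__(
            self, "space", {**DEFAULT_SPACES[self.family], **self.space})


def sample_params(spec: ModelSpec, rng: np.random.Generator) -> dict:
    """Draw one hyperparameter configuration from the spec's space."""
    out = {}
    for name, (kind, *args) in spec.space.items():
        if kind == "int":
            out[name] = int(rng.integers(args[0], args[1] + 1))
        elif kind == "float":
            out[name] = float(rng.uniform(*args))
        elif kind == "logfloat":
            out[name] = float(np.exp(rng.uniform(np.log(args[0]),
                                                 np.log(args[1]))))
        elif kind == "choice":
            out[name] = args[0][int(rng.integers(len(args[0])))]
        else:
            raise ValueError(f"unknown space kind {kind!r}")
    return out


class _EncodedClassifier:
    """Wraps a classifier that needs integer targets (string labels in/out)."""

    def __init__(self, est):
        self.est = est

    def fit(self, X, y):
        self._le = LabelEncoder().fit(y)
        self.classes_ = self._le.classes_
        self.est.fit(np.asarray(X, dtype=np.float32), self._le.transform(y))
        return self

    def predict(self, X):
        return self._le.inverse_transform(
            self.est.predict(np.asarray(X, dtype=np.float32)))

    def predict_proba(self, X):
        return self.est.predict_proba(np.asarray(X, dtype=np.float32))

    def score(self, X, y):
        return accuracy_score(y, self.predict(X))


def build_estimator(family: str, params: dict, seed: int = 0):
    """Instantiate a classifier of the given family with sampled parameters."""
    if family == "kernel-svm":
        return make_pipeline(StandardScaler(),
                             SVC(random_state=seed, **params))
    if family == "random-forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "gradient-boosted-trees":
        return _EncodedClassifier(XGBClassifier(
            random_state=seed, tree_method="hist", max_bin=64, n_jobs=1,
            verbosity=0, **params))
    raise ValueError(f"unknown family {family!r}")


def predict_scores(est, X, classes: np.ndarray) -> np.ndarray:
    """Per-class score matrix aligned with ``classes`` (rows sum to 1).

    Probabilistic models report predict_proba; margin models (SVM without
    probability calibration) report a softmax over decision values.
    """
    est_classes = np.asarray(est.classes_)
    if hasattr(est, "predict_proba"):
        raw = est.predict_proba(X)
    else:
        d = est.decision_function(X)
        if d.ndim == 1:
            d = np.stack([-d, d], axis=1)
        raw = softmax(d, axis=1)
    out = np.zeros((raw.shape[0], len(classes)))
    pos = {c: i for i, c in enumerate(classes)}
    for j, c in enumerate(est_classes):
        out[:, pos[c]] = raw[:, j]
    return out


def fit_predict_windows(est, X_train, y_train, X_test,
                        classes: np.ndarray | None = None):
    """Fit on training windows, return (labels, scores) for test windows."""
    if list(getattr(X_train, "columns", [])) != list(getattr(X_test, "columns", [])):
        raise ValueError("train and test feature columns differ")
    if classes is None:
        classes = np.unique(y_train)
    est.fit(X_train, y_train)
    labels = np.asarray(est.predict(X_test))
    scores = predict_scores(est, X_test, classes)
    return labels, scores


def _vote(labels: np.ndarray, scores: np.ndarray, classes: np.ndarray) -> str:
    """Modal label; ties broken by highest mean class score, then class name."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot vote over zero windows")
    counts = pd.Series(labels).value_counts()
    top = counts[counts == counts.max()].index.to_numpy()
    if len(top) == 1:
        return str(top[0])
    mean_scores = scores.mean(axis=0)
    pos = {c: i for i, c in enumerate(classes)}
    ranked = sorted(top, key=lambda c: (-mean_scores[pos[c]], str(c)))
    return str(ranked[0])


def video_majority_vote(window_labels, window_scores,
                        classes: np.ndarray) -> str:
    """Video label = majority vote over its window labels (deterministic ties)."""
    return _vote(np.asarray(window_labels), np.asarray(window_scores), classes)


def fuse_views_vote(frontal_labels, frontal_scores, sagittal_labels,
                    sagittal_scores, classes: np.ndarray) -> str:
    """Pooled window-label vote across both views of one subject walk.

    Window labels of both views are pooled before voting, so a view that
    produced more windows carries proportionally more weight. A missing view
    (None or empty) degrades to the single-view vote.
    """
    parts_l, parts_s = [], []
    for lab, sc in ((frontal_labels, frontal_scores),
                    (sagittal_labels, sagittal_scores)):
        if lab is not None and len(lab) > 0:
            parts_l.append(np.asarray(lab))
            parts_s.append(np.asarray(sc))
    if not parts_l:
        raise ValueError("need windows from at least one view")
    return _vote(np.concatenate(parts_l), np.vstack(parts_s), classes)


def compute_metrics(y_true, y_pred, classes: np.ndarray | None = None) -> dict:
    """Accuracy plus weighted precision/recall/F1 and the confusion matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average="weighted", zero_division=0)
    return {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": p,
        "recall": r,
        "f1": f1,
        "confusion": confusion_matrix(y_true, y_pred, labels=classes),
    }


def per_class_report(y_true, y_pred,
                     classes: np.ndarray | None = None) -> pd.DataFrame:
    """One-vs-rest precision/recall/F1 per gait class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f1, support = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average=None, zero_division=0)
    return pd.DataFrame({"precision": p, "recall": r, "f1": f1,
                         "support": support}, index=classes)


def inner_tune(X, y, groups, spec: ModelSpec,
               rng: np.random.Generator) -> dict:
    """Seeded random search over the spec's space with subject-wise folds.

    Splits are by subject, never by window. With fewer than 5 training
    subjects the inner loop falls back to 3 folds (with a warning). The
    winner is the configuration with highest mean validation accuracy; ties
    keep the first-sampled configuration.
    """
    groups = np.asarray(groups)
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        raise ValueError("inner tuning needs >= 2 training subjects")
    if n_groups >= 5:
        n_splits = 5
    else:
        warnings.warn(f"only {n_groups} training subjects; falling back to "
                      f"{min(3, n_groups)}-fold inner CV", stacklevel=2)
        n_splits = min(3, n_groups)
    candidates = [sample_params(spec, rng) for _ in range(spec.budget)]
    if spec.budget == 1:
        # a single candidate wins regardless of its validation score
        return candidates[0]
    cv = GroupKFold(n_splits=n_splits, shuffle=True,
                    random_state=int(rng.integers(2 ** 31)))
    X_arr = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
    y = np.asarray(y)

    best_params, best_score = None, -np.inf
    for params in candidates:
        scores = []
        for tr, va in cv.split(X_arr, y, groups):
            est = build_estimator(spec.family, params, seed=spec.seed)
            est.fit(X_arr[tr], y[tr])
            scores.append(accuracy_score(y[va], est.predict(X_arr[va])))
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_score, best_params = mean_score, params
    return best_params


@dataclass
class CVResult:
    """Nested-cross-validation outcome at window, video and fused levels."""

    records: pd.DataFrame          # trial, fold, level, metric, value
    confusions: dict               # level -> pooled confusion matrix
    chosen_params: pd.DataFrame    # trial, fold, params (one row per fold)
    classes: np.ndarray
    view: str

    def summary(self) -> pd.DataFrame:
        """Mean +/- 1.96 SE of each metric across trial x fold scores."""
        g = self.records.groupby(["level", "metric"])["value"]
        out = g.agg(["mean", "count", "std"]).rename(columns={"std": "sd"})
        se = out["sd"] / np.sqrt(out["count"])
        out["ci_half"] = 1.96 * se.fillna(0.0)
        out["ci_low"] = out["mean"] - out["ci_half"]
        out["ci_high"] = out["mean"] + out["ci_half"]
        return out

    def mean(self, level: str, metric: str = "accuracy") -> float:
        sel = self.records.query("level == @level and metric == @metric")
        return float(sel["value"].mean())


def _view_filter(meta: pd.DataFrame, view: str) -> np.ndarray:
    if view == "combined":
        return np.ones(len(meta), dtype=bool)
    if view in ("frontal", "sagittal"):
        return (meta["view"] == view).to_numpy()
    raise ValueError(f"view must be frontal, sagittal or combined; got {view!r}")


def select_columns(sel, max_features: int | None) -> list[str]:
    """Selected feature names, optionally capped to the most significant.

    With a cap, survivors are ranked by their smallest per-class p-value
    (ties by name) and only the top ``max_features`` kept — a compute budget
    for the model fit, not part of the selection statistics.
    """
    cols = sel.selected
    if max_features is None or len(cols) <= max_features:
        return cols
    min_p = sel.pvalues.loc[cols].min(axis=1)
    ranked = sorted(cols, key=lambda c: (min_p[c], c))
    return ranked[:max_features]


def nested_loso_evaluate(features: pd.DataFrame, meta: pd.DataFrame,
                         spec: ModelSpec, *, view: str = "combined",
                         trials: int = 10, seed: int = 0, fdr_q: float = 0.05,
                         smote_k: int = 5, min_subjects: int = 6,
                         max_features: int | None = None) -> CVResult:
    """Nested LOSO evaluation of the full pipeline on precomputed features.

    Per outer fold (one held-out subject): relevance selection and SMOTE are
    fitted on the training rows only, hyperparameters are tuned by seeded
    random search on subject-wise inner folds, and the tuned model labels the
    held-out subject's windows. Trials re-run the procedure under different
    seeds (inner-fold assignment, sampler and SMOTE draws change; the outer
    LOSO folds are fixed by design).
    """
    if len(features) != len(meta):
        raise ValueError("features and meta must be row-aligned")
    mask = _view_filter(meta, view)
    X = features.loc[mask].reset_index(drop=True)
    m = meta.loc[mask].reset_index(drop=True)
    subjects = np.sort(m["subject_id"].unique())
    if len(subjects) < min_subjects:
        raise ValueError(f"need >= {min_subjects} subjects; got {len(subjects)}")
    classes = np.sort(m["label"].unique())
    y_all = m["label"].to_numpy()

    records = []
    params_rows = []
    confusions = {level: 0 for level in ("window", "video", "fused")}

    for trial in range(trials):
        for fold, subject in enumerate(subjects):
            rng = np.random.default_rng([seed, trial, fold])
            test_rows = np.nonzero((m["subject_id"] == subject).to_numpy())[0]
            train_rows = np.nonzero((m["subject_id"] != subject).to_numpy())[0]
            # leakage guard: selection and balancing see training rows only
            assert not set(test_rows) & set(train_rows)

            X_train, y_train = X.iloc[train_rows], y_all[train_rows]
            sel = fresh_select(X_train, y_train, q=fdr_q)
            cols = select_columns(sel, max_features)
            Xb, yb, base = smote_oversample(X_train[cols], y_train, k=smote_k,
                                            rng=rng)
            groups_b = m["subject_id"].to_numpy()[train_rows][base]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                best = inner_tune(Xb, yb, groups_b, spec, rng)
            est = build_estimator(spec.family, best, seed=spec.seed + trial)
            est.fit(Xb, yb)
            params_rows.append({"trial": trial, "fold": subject, **best})

            X_test = X.iloc[test_rows][cols]
            y_test = y_all[test_rows]
            pred = np.asarray(est.predict(X_test))
            scores = predict_scores(est, X_test, classes)

            level_results = {"window": (y_test, pred)}

            m_test = m.iloc[test_rows]
            vid_true, vid_pred = [], []
            for vid, grp in m_test.groupby("video_id", sort=True):
                rows = grp.index.to_numpy()
                local = np.searchsorted(test_rows, rows)
                vid_true.append(grp["label"].iloc[0])
                vid_pred.append(video_majority_vote(pred[local], scores[local],
                                                    classes))
            level_results["video"] = (np.array(vid_true), np.array(vid_pred))

            fus_true, fus_pred = [], []
            for (lab, direction), grp in m_test.groupby(["label", "direction"],
                                                        sort=True):
                rows = grp.index.to_numpy()
                local = np.searchsorted(test_rows, rows)
                fus_true.append(lab)
                fus_pred.append(_vote(pred[local], scores[local], classes))
            level_results["fused"] = (np.array(fus_true), np.array(fus_pred))

            for level, (yt, yp) in level_results.items():
                metrics = compute_metrics(yt, yp, classes)
                confusions[level] = confusions[level] + metrics.pop("confusion")
                for metric, value in metrics.items():
                    records.append({"trial": trial, "fold": subject,
                                    "level": level, "metric": metric,
                                    "value": float(value)})

    return CVResult(records=pd.DataFrame(records), confusions=confusions,
                    chosen_params=pd.DataFrame(params_rows), classes=classes,
                    view=view)
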