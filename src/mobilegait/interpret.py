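"""Permutation feature importance and keypoint-level aggregation.

Importance of a feature is the drop in held-out accuracy when that feature's
column is randomly shuffled: positive means the model relied on it, negative
means the shuffled version scored higher (the feature confuses the model),
zero means no effect. Per-feature importances are summed per keypoint-channel
to rank body landmarks, and the top-k channels x top-k feature types are
exported as a heatmap table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score

from .crossval import ModelSpec, build_estimator, inner_tune, select_columns
from .features.catalog import parse_feature_name
from .selection import fresh_select, smote_oversample


def permutation_importance(est, X: pd.DataFrame, y, n_repeats: int = 10,
                           rng: np.random.Generator | int | None = None
                           ) -> pd.DataFrame:
    """Accuracy-based permutation importance with normal-approximation CIs.

    For each feature, the column is shuffled ``n_repeats`` times and the model
    re-scored; importance is baseline accuracy minus the mean permuted
    accuracy, with a 95% CI over repeats. The estimator must already be
    fitted on exactly X's columns.
    """
    if not (hasattr(est, "classes_") or hasattr(est, "n_features_in_")
            or hasattr(est, "steps")):
        raise ValueError("estimator must be fitted")
    try:
        baseline = accuracy_score(y, est.predict(X))
    except Exception as exc:  # unfitted sklearn models raise here
        raise ValueError("estimator must be fitted before importance") from exc
    rng = np.random.default_rng(rng)
    y = np.asarray(y)
    values = X.to_numpy()
    n = len(y)
    rows = []
    for j, name in enumerate(X.columns):
        drops = np.empty(n_repeats)
        col = values[:, j].copy()
        for rep in range(n_repeats):
            values[:, j] = col[rng.permutation(n)]
            drops[rep] = baseline - accuracy_score(
                y, est.predict(pd.DataFrame(values, columns=X.columns)))
        values[:, j] = col
        mean = drops.mean()
        se = drops.std(ddof=1) / np.sqrt(n_repeats) if n_repeats > 1 else 0.0
        rows.append({"feature": name, "importance": mean,
                     "ci_low": mean - 1.96 * se, "ci_high": mean + 1.96 * se,
                     "sd": drops.std(ddof=1) if n_repeats > 1 else 0.0,
                     "n_repeats": n_repeats})
    return pd.DataFrame(rows)


def keypoint_importance(records: pd.DataFrame) -> pd.Series:
    """Sum of per-feature importances grouped by keypoint-channel.

    Signs are preserved, so negative (confusing) features subtract from their
    channel's total. Raises on feature names that do not follow the canonical
    ``channel__type__params`` convention.
    """
    channels = [parse_feature_name(f)[0] for f in records["feature"]]
    return (records.assign(channel=channels)
            .groupby("channel")["importance"].sum()
            .sort_values(ascending=False))


def top_k_heatmap_table(records: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k keypoint-channels x top-k feature types, cumulative importance.

    Rows and columns are ranked by their cumulative importance (descending,
    ties broken by name); each cell is the summed importance of that
    channel/feature-type combination. Suitable for heatmap rendering.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    parsed = [parse_feature_name(f) for f in records["feature"]]
    df = records.assign(channel=[p[0] for p in parsed],
                        ftype=[p[1] for p in parsed])
    pivot = df.pivot_table(index="ftype", columns="channel",
                           values="importance", aggfunc="sum", fill_value=0.0)

    def _rank(totals: pd.Series) -> list:
        order = sorted(totals.index, key=lambda n: (-totals[n], str(n)))
        return order[:k]

    rows = _rank(pivot.sum(axis=1))
    cols = _rank(pivot.sum(axis=0))
    return pivot.loc[rows, cols]


def loso_permutation_importance(features: pd.DataFrame, meta: pd.DataFrame,
                                spec: ModelSpec, *, view: str = "combined",
                                n_repeats: int = 10, seed: int = 0,
                                fdr_q: float = 0.05, smote_k: int = 5,
                                max_features: int | None = None
                                ) -> pd.DataFrame:
    """Fold-averaged permutation importance under the LOSO protocol.

    Each outer fold trains the pipeline (selection, SMOTE, tuning) on the
    training subjects and scores importance on the held-out subject's
    windows; per-feature importances are then averaged across folds, with
    features outside a fold's selected set contributing exactly 0 there.
    """
    if view != "combined":
        keep = (meta["view"] == view).to_numpy()
        features = features.loc[keep].reset_index(drop=True)
        meta = meta.loc[keep].reset_index(drop=True)
    subjects = np.sort(meta["subject_id"].unique())
    y_all = meta["label"].to_numpy()
    totals = pd.Series(0.0, index=features.columns)
    for fold, subject in enumerate(subjects):
        rng = np.random.default_rng([seed, fold])
        test = (meta["subject_id"] == subject).to_numpy()
        X_train, y_train = features.loc[~test], y_all[~test]
        sel = fresh_select(X_train, y_train, q=fdr_q)
        cols = select_columns(sel, max_features)
        Xb, yb, base = smote_oversample(X_train[cols], y_train, k=smote_k,
                                        rng=rng)
        groups_b = meta["subject_id"].to_numpy()[~test][base]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best = inner_tune(Xb, yb, groups_b, spec, rng)
        est = build_estimator(spec.family, best, seed=spec.seed)
        est.fit(Xb, yb)
        imp = permutation_importance(est, features.loc[test, cols],
                                     y_all[test], n_repeats=n_repeats, rng=rng)
        totals[imp["feature"].to_numpy()] += imp["importance"].to_numpy()
    totals /= len(subjects)
    return pd.DataFrame({"feature": totals.index,
                         "importance": totals.to_numpy()})
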