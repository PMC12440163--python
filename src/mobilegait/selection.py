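"""Relevance-based feature selection and minority-class oversampling.

Selection follows the scalable-hypothesis-testing recipe: each feature is
tested per class (one-vs-rest, two-sided Mann-Whitney U), the resulting
feature x class p-value matrix is thresholded jointly by the
Benjamini-Yekutieli step-up procedure (valid under arbitrary dependence),
and a feature survives if it is rejected for at least one class.

Balancing is synthetic minority oversampling (SMOTE): each minority class is
grown to the majority count with points interpolated between a class member
and one of its k same-class nearest neighbours.

Both are fitted on training folds only; the cross-validation driver enforces
that no held-out row reaches them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.neighbors import NearestNeighbors

from .features.catalog import parse_feature_name


def _ranks_and_ties(VT: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise average ranks (1-based, ties averaged) and tie terms.

    ``VT`` holds one feature per row (contiguous), ``VT.shape = (m, n)``.
    Returns ``(ranks, tie)`` of shapes (m, n) and (m,), where
    ``tie[j] = sum(t^3 - t)`` over the tied groups of feature j. One argsort
    per feature, everything else vectorized — this is what keeps per-fold
    relevance testing on ~10^4 features cheap.
    """
    m, n = VT.shape
    order = np.argsort(VT, axis=1, kind="stable").astype(np.int32)
    S = np.take_along_axis(VT, order, axis=1)
    idx = np.arange(n, dtype=np.int32)[None, :]
    is_start = np.hstack([np.ones((m, 1), dtype=bool), S[:, 1:] != S[:, :-1]])
    is_end = np.hstack([is_start[:, 1:], np.ones((m, 1), dtype=bool)])
    start = np.maximum.accumulate(np.where(is_start, idx, np.int32(0)), axis=1)
    end = np.ascontiguousarray(np.flip(np.where(is_end, idx, np.int32(n - 1)),
                                       axis=1))
    np.minimum.accumulate(end, axis=1, out=end)
    end = np.flip(end, axis=1)
    avg_rank_sorted = (start + end) * 0.5 + 1.0
    ranks = np.empty_like(avg_rank_sorted)
    np.put_along_axis(ranks, order, avg_rank_sorted, axis=1)
    length = np.where(is_start, (end - start + 1).astype(np.float64), 0.0)
    tie = (length ** 3 - length).sum(axis=1)
    return ranks, tie


def relevance_pvalues(X: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
    """Two-sided Mann-Whitney U p-value of every feature for every class.

    For each feature and class the class's values are compared against the
    pooled rest via the normal approximation with tie correction and
    continuity correction (ranks are computed once per feature, so the whole
    feature x class table is a few rank sums). Constant features get p = 1
    for every class. Returns a (features x classes) DataFrame.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for relevance testing")
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples")
    VT = np.ascontiguousarray(X.to_numpy().T)
    n = VT.shape[1]
    constant = np.ptp(VT, axis=1) == 0
    ranks, tie = _ranks_and_ties(VT)

    out = np.ones((X.shape[1], len(classes)))
    for j, cls in enumerate(classes):
        mask = y == cls
        n1 = int(mask.sum())
        n2 = n - n1
        u1 = ranks[:, mask].sum(axis=1) - n1 * (n1 + 1) / 2
        mu = n1 * n2 / 2
        sd2 = n1 * n2 / 12 * ((n + 1) - tie / (n * (n - 1)))
        sd = np.sqrt(np.maximum(sd2, 0.0))
        ok = sd > 0
        # continuity correction toward the mean, as in the standard test
        num = np.abs(u1 - mu) - 0.5
        z = np.where(ok, np.maximum(num, 0.0) / np.where(ok, sd, 1.0), 0.0)
        p = np.minimum(2 * norm.sf(z), 1.0)
        out[:, j] = np.where(constant | ~ok, 1.0, p)
    return pd.DataFrame(out, index=X.columns, columns=classes)


def benjamini_yekutieli(pvals, q: float = 0.05) -> np.ndarray:
    """Step-up false-discovery-rate control under arbitrary dependence.

    Rejects the k smallest p-values where k is the largest index with
    p_(k) <= k * q / (m * c(m)) and c(m) = sum_{i<=m} 1/i. Returns a boolean
    mask aligned with the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    thresholds = np.arange(1, m + 1) * q / (m * c_m)
    passing = np.nonzero(p[order] <= thresholds)[0]
    mask = np.zeros(m, dtype=bool)
    if len(passing):
        k = passing[-1] + 1
        mask[order[:k]] = True
    return mask


@dataclass
class SelectionResult:
    """Outcome of relevance filtering on one training set."""

    pvalues: pd.DataFrame            # features x classes
    rejected: pd.DataFrame           # same shape, BY rejection mask
    selected: list[str]              # features rejected for >= 1 class
    survivors_per_type: pd.Series    # selected features counted per feature type
    fdr_level: float
    all_kept_fallback: bool = False  # empty selection -> full matrix passed on

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def fresh_select(X: pd.DataFrame, y, q: float = 0.05) -> SelectionResult:
    """Select features whose class relevance survives BY FDR control.

    The BY procedure is applied jointly across the flattened feature x class
    p-value matrix; a feature is kept if any class test is rejected. If no
    feature survives, selection falls back to keeping everything (flagged),
    so downstream models still receive a matrix.
    """
    pv = relevance_pvalues(X, np.asarray(y))
    flat_mask = benjamini_yekutieli(pv.to_numpy().ravel(), q=q)
    rej = pd.DataFrame(flat_mask.reshape(pv.shape), index=pv.index,
                       columns=pv.columns)
    keep = rej.any(axis=1)
    selected = list(pv.index[keep])
    fallback = False
    if not selected:
        warnings.warn("relevance selection rejected nothing; keeping all "
                      "features", stacklevel=2)
        selected = list(pv.index)
        fallback = True
    types = pd.Series([parse_feature_name(f)[1] for f in selected])
    survivors = types.value_counts().sort_index()
    return SelectionResult(pvalues=pv, rejected=rej, selected=selected,
                           survivors_per_type=survivors, fdr_level=q,
                           all_kept_fallback=fallback)


def smote_oversample(X, y, k: int = 5,
                     rng: np.random.Generator | int | None = None):
    """Oversample every minority class to the majority count.

    Synthetic rows are ``x + lam * (nn - x)`` with ``lam ~ U(0, 1)`` and
    ``nn`` one of the k nearest same-class neighbours (Euclidean) of a
    randomly drawn class member. k is reduced to n_class - 1 where needed;
    singleton classes are duplicated. Original rows are preserved verbatim
    and come first in the output.

    Returns ``(X_out, y_out, base_index)`` where ``base_index[i]`` is the
    input row each output row derives from (itself for originals).
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X
    values = X.to_numpy() if isinstance(X, pd.DataFrame) else X
    y = np.asarray(y)
    if values.shape[0] != len(y):
        raise ValueError("X and y lengths differ")
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 1).any() or len(classes) == 0:
        raise ValueError("every class needs at least one sample")
    n_major = counts.max()

    new_rows, new_labels, base_idx = [], [], []
    for cls, n_cls in zip(classes, counts):
        deficit = int(n_major - n_cls)
        if deficit == 0:
            continue
        idx = np.nonzero(y == cls)[0]
        Xc = values[idx]
        if n_cls == 1:
            picks = np.zeros(deficit, dtype=int)
            synth = np.repeat(Xc, deficit, axis=0)
        else:
            k_eff = min(k, n_cls - 1)
            nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
            _, neigh = nn.kneighbors(Xc)
            neigh = neigh[:, 1:]                     # drop self
            picks = rng.integers(0, n_cls, size=deficit)
            chosen = neigh[picks, rng.integers(0, k_eff, size=deficit)]
            lam = rng.random(deficit)[:, None]
            synth = Xc[picks] + lam * (Xc[chosen] - Xc[picks])
        new_rows.append(synth)
        new_labels.append(np.full(deficit, cls, dtype=y.dtype))
        base_idx.append(idx[picks])

    if not new_rows:
        base = np.arange(len(y))
        return (X.copy() if isinstance(X, pd.DataFrame) else values.copy(),
                y.copy(), base)

    stacked = np.vstack([values] + new_rows)
    y_out = np.concatenate([y] + new_labels)
    base = np.concatenate([np.arange(len(y))] + base_idx)
    if isinstance(X, pd.DataFrame):
        stacked = pd.DataFrame(stacked, columns=X.columns)
    return stacked, y_out, base
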