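"""Feature-matrix computation over analysis windows."""

from __future__ import annotations

import logging
from collections import OrderedDict

import numpy as np
import pandas as pd

from ..containers import AnalysisWindow
from ..skeleton import channel_names
from .calculators import compute_entries
from .catalog import FeatureCatalog, feature_name, reduced_catalog

log = logging.getLogger(__name__)

META_COLUMNS = ["video_id", "subject_id", "view", "direction", "label",
                "start_frame"]


def window_meta(windows: list[AnalysisWindow]) -> pd.DataFrame:
    """Row-provenance table aligned with the feature matrix."""
    return pd.DataFrame([{c: getattr(w, c) for c in META_COLUMNS}
                         for w in windows])


def _grouped(catalog: FeatureCatalog):
    """Catalog entries grouped by feature type, preserving entry order."""
    groups: OrderedDict[str, list[tuple[int, dict]]] = OrderedDict()
    for i, (ftype, params) in enumerate(catalog):
        groups.setdefault(ftype, []).append((i, params))
    return groups


def compute_feature_matrix(windows: list[AnalysisWindow],
                           catalog: FeatureCatalog | None = None) -> pd.DataFrame:
    """Evaluate every catalog entry on every keypoint-channel of every window.

    Returns a DataFrame with one row per window and one column per
    (channel, catalog entry), named ``channel__type__params`` in canonical
    (landmark-major channel, catalog) order. Non-finite results are replaced
    by 0 and counted in a log message.
    """
    if not windows:
        raise ValueError("no windows given")
    if catalog is None:
        catalog = reduced_catalog()
    shapes = {w.values.shape for w in windows}
    if len(shapes) != 1:
        raise ValueError(f"windows have mismatching shapes: {shapes}")

    W = len(windows)
    stack = np.stack([w.values for w in windows])      # (W, 30, 33, 3)
    chans = channel_names()
    n_entries = len(catalog)
    out = np.empty((W, len(chans) * n_entries))
    groups = _grouped(catalog)

    columns: list[str] = []
    for c_idx, chan in enumerate(chans):
        lm, ch = divmod(c_idx, 3)
        X = stack[:, :, lm, ch]                        # (W, 30)
        block = np.empty((n_entries, W))
        for ftype, items in groups.items():
            vals = compute_entries(X, ftype, [p for _, p in items])
            for row, (entry_idx, _) in enumerate(items):
                block[entry_idx] = vals[row]
        out[:, c_idx * n_entries:(c_idx + 1) * n_entries] = block.T
        columns.extend(feature_name(chan, t, p) for t, p in catalog)

    bad = ~np.isfinite(out)
    if bad.any():
        log.warning("replaced %d non-finite feature values with 0", int(bad.sum()))
        out[bad] = 0.0
    return pd.DataFrame(out, columns=columns)


# ---------------------------------------------------------------------------
# single-series convenience operations
# ---------------------------------------------------------------------------

def _single(series, ftype: str, params: dict) -> float:
    return float(compute_entries(np.asarray(series, dtype=float),
                                 ftype, [params])[0, 0])


def moment_statistics(series, n_absolute_max: int = 3) -> dict[str, float]:
    """Location/scale/energy summary statistics of one series."""
    out = {t: _single(series, t, {}) for t in
           ("mean", "median", "maximum", "minimum", "absolute_maximum",
            "standard_deviation", "variance", "variation_coefficient",
            "root_mean_square", "sum_values", "abs_energy")}
    out["mean_n_absolute_max"] = _single(series, "mean_n_absolute_max",
                                         {"n": n_absolute_max})
    return out


def change_statistics(series, **params) -> dict[str, float]:
    """Difference/complexity/counting statistics of one series.

    Keyword arguments supply the parameterized members, e.g. ``m=0.5`` for
    ``number_crossing_m`` or ``ql=0.2, qh=0.8, isabs=True, f_agg="mean"`` for
    ``change_quantiles``; members whose parameters are absent are skipped.
    """
    out = {
        "mean_abs_change": _single(series, "mean_abs_change", {}),
        "absolute_sum_of_changes": _single(series, "absolute_sum_of_changes", {}),
        "cid_ce": _single(series, "cid_ce",
                          {"normalize": params.get("normalize", False)}),
    }
    if "m" in params:
        out["number_crossing_m"] = _single(series, "number_crossing_m",
                                           {"m": params["m"]})
    if "n" in params:
        out["number_peaks"] = _single(series, "number_peaks", {"n": params["n"]})
    if "t" in params:
        out["count_above"] = _single(series, "count_above", {"t": params["t"]})
        out["count_below"] = _single(series, "count_below", {"t": params["t"]})
    if "min" in params and "max" in params:
        out["range_count"] = _single(series, "range_count",
                                     {"min": params["min"], "max": params["max"]})
    if "q" in params:
        out["quantile"] = _single(series, "quantile", {"q": params["q"]})
    if "ql" in params:
        out["change_quantiles"] = _single(
            series, "change_quantiles",
            {k: params[k] for k in ("ql", "qh", "isabs", "f_agg")})
    return out


def correlation_trend(series, lag: int = 1, maxlag: int = 29,
                      chunk_len: int = 5) -> dict[str, float]:
    """Autocorrelation, trend, nonlinearity and dynamics statistics."""
    out = {
        "autocorrelation": _single(series, "autocorrelation", {"lag": lag}),
        "c3": _single(series, "c3", {"lag": lag}),
        "benford_correlation": _single(series, "benford_correlation", {}),
        "max_langevin_fixed_point": _single(series, "max_langevin_fixed_point",
                                            {"m": 3, "r": 30}),
    }
    for agg in ("mean", "median", "var"):
        out[f"agg_autocorrelation_{agg}"] = _single(
            series, "agg_autocorrelation", {"f_agg": agg, "maxlag": maxlag})
    for attr in ("slope", "intercept", "rvalue", "pvalue", "stderr"):
        out[f"linear_trend_{attr}"] = _single(series, "linear_trend",
                                              {"attr": attr})
        out[f"agg_linear_trend_{attr}"] = _single(
            series, "agg_linear_trend",
            {"attr": attr, "chunk_len": chunk_len, "f_agg": "mean"})
    return out


def entropies(series, max_bins: int = 10, m: int = 2, r: float = 0.3,
              dimension: int = 3, tau: int = 1, bins: int = 10) -> dict[str, float]:
    """The five entropy measures of one series."""
    return {
        "binned_entropy": _single(series, "binned_entropy",
                                  {"max_bins": max_bins}),
        "approximate_entropy": _single(series, "approximate_entropy",
                                       {"m": m, "r": r}),
        "sample_entropy": _single(series, "sample_entropy", {}),
        "permutation_entropy": _single(series, "permutation_entropy",
                                       {"tau": tau, "dimension": dimension}),
        "fourier_entropy": _single(series, "fourier_entropy", {"bins": bins}),
    }


def spectral(series, k: int = 1, attr: str = "abs", w: float = 5,
             coeff: int = 5) -> dict[str, float]:
    """Fourier and wavelet statistics of one series."""
    out = {"fft_coefficient": _single(series, "fft_coefficient",
                                      {"k": k, "attr": attr}),
           "cwt_coefficients": _single(series, "cwt_coefficients",
                                       {"w": w, "coeff": coeff})}
    for aggtype in ("centroid", "variance", "skew", "kurtosis"):
        out[f"fft_aggregated_{aggtype}"] = _single(series, "fft_aggregated",
                                                   {"aggtype": aggtype})
    return out
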