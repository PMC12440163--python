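"""Pinned feature catalogues and canonical feature naming.

A catalogue is an ordered list of (feature_type, params) entries evaluated on
every keypoint-channel series of every window. Two catalogues are pinned:

* ``full_catalog()`` — the full-mirror grid: 783 entries per channel across
  the 37 feature types of the published selection table, hence
  99 x 783 = 77,517 candidate features per window. Grids respect 30-sample
  windows (e.g. Fourier coefficient order k <= 15 = floor(30/2)).
* ``reduced_catalog()`` — a ~1/10-size grid over the same feature types
  (minus the costly Langevin fixed point), the default for model fitting and
  tests.

Feature names follow ``<landmark>_<channel>__<type>__<param>=<value>__...``
so that importances can later be aggregated per keypoint-channel and per
feature type unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CatalogEntry = tuple[str, dict]


def _fmt(v) -> str:
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        if v == int(v) and abs(v) < 1e15:
            return str(int(v))
        return repr(round(v, 10))
    return str(v)


def entry_name(ftype: str, params: dict) -> str:
    parts = [ftype] + [f"{k}={_fmt(v)}" for k, v in params.items()]
    return "__".join(parts)


def feature_name(channel: str, ftype: str, params: dict) -> str:
    return f"{channel}__{entry_name(ftype, params)}"


def parse_feature_name(name: str) -> tuple[str, str]:
    """Split a feature column name into (keypoint_channel, feature_type)."""
    parts = name.split("__")
    if len(parts) < 2:
        raise ValueError(f"unparseable feature name {name!r}")
    return parts[0], parts[1]


@dataclass(frozen=True)
class FeatureCatalog:
    """An ordered, data-independent list of feature-type parameterizations."""

    entries: tuple[CatalogEntry, ...]
    name: str = "custom"

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def entry_names(self) -> list[str]:
        names = [entry_name(t, p) for t, p in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("catalog entry names are not unique")
        return names

    def feature_types(self) -> list[str]:
        return sorted({t for t, _ in self.entries})


def _corridor_pairs(step: float) -> list[tuple[float, float]]:
    qs = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    return [(float(ql), float(qh)) for ql in qs for qh in qs if ql < qh]


def full_catalog() -> FeatureCatalog:
    """The 783-entry-per-channel full-mirror grid."""
    e: list[CatalogEntry] = []
    add = e.append

    for t in ("abs_energy", "absolute_maximum", "absolute_sum_of_changes",
              "benford_correlation", "maximum", "mean", "mean_abs_change",
              "median", "minimum", "root_mean_square", "sample_entropy",
              "standard_deviation", "sum_values", "variance",
              "variation_coefficient"):
        add((t, {}))                                                    # 15
    add(("max_langevin_fixed_point", {"m": 3, "r": 30}))                # 1
    for agg in ("mean", "median", "var"):
        for maxlag in (10, 20, 29):
            add(("agg_autocorrelation", {"f_agg": agg, "maxlag": maxlag}))  # 9
    for attr in ("slope", "intercept", "rvalue", "stderr"):
        for chunk in (3, 5, 10, 15):
            for agg in ("max", "min", "mean", "var"):
                add(("agg_linear_trend",
                     {"attr": attr, "chunk_len": chunk, "f_agg": agg}))  # 64
    for r in (0.1, 0.3, 0.5, 0.7, 0.9):
        add(("approximate_entropy", {"m": 2, "r": r}))                  # 5
    for lag in range(1, 30):
        add(("autocorrelation", {"lag": lag}))                          # 29
    for b in (2, 5, 10, 20):
        add(("binned_entropy", {"max_bins": b}))                        # 4
    for lag in (1, 2, 3, 4, 5):
        add(("c3", {"lag": lag}))                                       # 5
    for ql, qh in _corridor_pairs(0.1):                                 # 55 pairs
        for isabs in (False, True):
            for agg in ("mean", "var", "median", "std"):
                add(("change_quantiles",
                     {"ql": ql, "qh": qh, "isabs": isabs, "f_agg": agg}))  # 440
    for norm in (True, False):
        add(("cid_ce", {"normalize": norm}))                            # 2
    for t_ in (-1.0, -0.5, 0.0, 0.5, 1.0):
        add(("count_above", {"t": t_}))                                 # 5
    for t_ in (-1.0, -0.5, 0.0, 0.5, 1.0):
        add(("count_below", {"t": t_}))                                 # 5
    for w in (2, 5, 10, 20):
        for coeff in range(20):
            add(("cwt_coefficients", {"w": w, "coeff": coeff}))         # 80
    for aggtype in ("centroid", "variance", "skew", "kurtosis"):
        add(("fft_aggregated", {"aggtype": aggtype}))                   # 4
    for k in range(16):
        for attr in ("real", "imag", "abs", "angle"):
            add(("fft_coefficient", {"k": k, "attr": attr}))            # 64
    for b in (2, 3, 5, 10, 100):
        add(("fourier_entropy", {"bins": b}))                           # 5
    for attr in ("slope", "intercept", "rvalue", "pvalue", "stderr"):
        add(("linear_trend", {"attr": attr}))                           # 5
    for n in (3, 5, 7):
        add(("mean_n_absolute_max", {"n": n}))                          # 3
    for m in (-1.0, 0.0, 1.0):
        add(("number_crossing_m", {"m": m}))                            # 3
    for n in (1, 2, 3, 5, 7, 10):
        add(("number_peaks", {"n": n}))                                 # 6
    for dim in (3, 4, 5, 6, 7):
        add(("permutation_entropy", {"tau": 1, "dimension": dim}))      # 5
    for q in np.round(np.arange(0.05, 1.0, 0.05), 10):
        if q != 0.5:
            add(("quantile", {"q": float(q)}))                          # 18
    for lo, hi in ((-1.0, 1.0), (-2.0, 2.0), (0.0, 1.0), (-1.0, 0.0),
                   (0.0, 1e12), (-1e12, 0.0)):
        add(("range_count", {"min": lo, "max": hi}))                    # 6
    return FeatureCatalog(entries=tuple(e), name="full")


def reduced_catalog() -> FeatureCatalog:
    """A compact grid over the same feature types (default for modelling).

    max_langevin_fixed_point is excluded here: it is the one calculator with
    no vectorized form and would dominate extraction time for a feature of
    marginal discriminative value; it remains in the full-mirror grid.
    """
    e: list[CatalogEntry] = []
    add = e.append

    for t in ("abs_energy", "absolute_maximum", "absolute_sum_of_changes",
              "benford_correlation", "maximum", "mean", "mean_abs_change",
              "median", "minimum", "root_mean_square", "sample_entropy",
              "standard_deviation", "sum_values", "variance",
              "variation_coefficient"):
        add((t, {}))                                                    # 15
    for agg in ("mean", "var"):
        add(("agg_autocorrelation", {"f_agg": agg, "maxlag": 29}))      # 2
    for attr in ("slope", "rvalue"):
        for chunk in (5, 10):
            add(("agg_linear_trend",
                 {"attr": attr, "chunk_len": chunk, "f_agg": "mean"}))  # 4
    add(("approximate_entropy", {"m": 2, "r": 0.3}))                    # 1
    for lag in (1, 2, 3, 5, 7):
        add(("autocorrelation", {"lag": lag}))                          # 5
    add(("binned_entropy", {"max_bins": 10}))                           # 1
    for lag in (1, 2, 3):
        add(("c3", {"lag": lag}))                                       # 3
    for ql, qh in ((0.0, 0.4), (0.0, 0.8), (0.2, 0.6), (0.4, 1.0), (0.6, 1.0)):
        for isabs in (False, True):
            add(("change_quantiles",
                 {"ql": ql, "qh": qh, "isabs": isabs, "f_agg": "mean"}))  # 10
    for norm in (True, False):
        add(("cid_ce", {"normalize": norm}))                            # 2
    add(("count_above", {"t": 0.0}))                                    # 1
    add(("count_below", {"t": 0.0}))                                    # 1
    for w, coeff in ((2, 2), (5, 5), (10, 10), (20, 14)):
        add(("cwt_coefficients", {"w": w, "coeff": coeff}))             # 4
    for aggtype in ("centroid", "variance", "skew", "kurtosis"):
        add(("fft_aggregated", {"aggtype": aggtype}))                   # 4
    for k in range(6):
        add(("fft_coefficient", {"k": k, "attr": "abs"}))               # 6
    for k in (1, 2, 3):
        for attr in ("real", "imag"):
            add(("fft_coefficient", {"k": k, "attr": attr}))            # 6
    add(("fourier_entropy", {"bins": 10}))                              # 1
    for attr in ("slope", "intercept", "rvalue", "stderr"):
        add(("linear_trend", {"attr": attr}))                           # 4
    for n in (3, 5):
        add(("mean_n_absolute_max", {"n": n}))                          # 2
    add(("number_crossing_m", {"m": 0.0}))                              # 1
    for n in (1, 3):
        add(("number_peaks", {"n": n}))                                 # 2
    for dim in (3, 5):
        add(("permutation_entropy", {"tau": 1, "dimension": dim}))      # 2
    for q in (0.1, 0.25, 0.75, 0.9):
        add(("quantile", {"q": q}))                                     # 4
    add(("range_count", {"min": -1.0, "max": 1.0}))                     # 1
    return FeatureCatalog(entries=tuple(e), name="reduced")
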