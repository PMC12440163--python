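"""Independent single-series reference implementations of the feature bank.

Each function is a direct, unvectorized transcription of the feature's
definition (plain loops, textbook formulas, scipy reference routines where
they exist). They share no code with the package's batch calculators and act
as the oracle the vectorized implementations are checked against.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats


def o_mean(x):
    return float(np.mean(x))


def o_median(x):
    return float(np.median(x))


def o_maximum(x):
    return float(max(x))


def o_minimum(x):
    return float(min(x))


def o_absolute_maximum(x):
    return float(max(abs(v) for v in x))


def o_standard_deviation(x):
    return float(np.std(x))


def o_variance(x):
    return float(np.var(x))


def o_variation_coefficient(x):
    m = np.mean(x)
    return float(np.std(x) / m) if m != 0 else 0.0


def o_root_mean_square(x):
    return float(math.sqrt(sum(v * v for v in x) / len(x)))


def o_sum_values(x):
    return float(sum(x))


def o_abs_energy(x):
    return float(sum(v * v for v in x))


def o_mean_n_absolute_max(x, n):
    return float(np.mean(sorted(abs(v) for v in x)[-n:]))


def o_mean_abs_change(x):
    return float(np.mean([abs(x[i + 1] - x[i]) for i in range(len(x) - 1)]))


def o_absolute_sum_of_changes(x):
    return float(sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1)))


def o_cid_ce(x, normalize):
    x = np.asarray(x, dtype=float)
    if normalize:
        s = np.std(x)
        if s == 0:
            x = np.zeros_like(x)
        else:
            x = (x - np.mean(x)) / s
    return float(math.sqrt(sum((x[i + 1] - x[i]) ** 2
                               for i in range(len(x) - 1))))


def o_number_crossing_m(x, m):
    above = [v > m for v in x]
    return float(sum(1 for i in range(len(x) - 1) if above[i] != above[i + 1]))


def o_number_peaks(x, n):
    count = 0
    for i in range(n, len(x) - n):
        if all(x[i] > x[i - j] and x[i] > x[i + j] for j in range(1, n + 1)):
            count += 1
    return float(count)


def o_count_above(x, t):
    return float(sum(1 for v in x if v >= t) / len(x))


def o_count_below(x, t):
    return float(sum(1 for v in x if v <= t) / len(x))


def o_range_count(x, lo, hi):
    return float(sum(1 for v in x if lo <= v < hi))


def o_quantile(x, q):
    return float(np.quantile(x, q))


def o_change_quantiles(x, ql, qh, isabs, f_agg):
    x = np.asarray(x, dtype=float)
    lo, hi = np.quantile(x, ql), np.quantile(x, qh)
    if lo == hi:
        return 0.0
    inside = (x >= lo) & (x <= hi)
    diffs = [x[i + 1] - x[i] for i in range(len(x) - 1)
             if inside[i] and inside[i + 1]]
    if not diffs:
        return 0.0
    diffs = np.abs(diffs) if isabs else np.asarray(diffs)
    agg = {"mean": np.mean, "var": np.var, "median": np.median,
           "std": np.std}[f_agg]
    return float(agg(diffs))


def o_autocorrelation(x, lag):
    x = np.asarray(x, dtype=float)
    n = len(x)
    mu, var = np.mean(x), np.var(x)
    if var == 0 or lag >= n:
        return 0.0
    if lag == 0:
        return 1.0
    s = sum((x[t] - mu) * (x[t + lag] - mu) for t in range(n - lag))
    return float(s / ((n - lag) * var))


def o_agg_autocorrelation(x, f_agg, maxlag):
    L = min(maxlag, len(x) - 1)
    acf = [o_autocorrelation(x, lag) for lag in range(1, L + 1)]
    return float({"mean": np.mean, "median": np.median, "var": np.var}[f_agg](acf))


def o_linear_trend(x, attr):
    y = np.asarray(x, dtype=float)
    if np.ptp(y) == 0:
        return {"slope": 0.0, "intercept": float(y[0]), "rvalue": 0.0,
                "pvalue": 1.0, "stderr": 0.0}[attr]
    res = spstats.linregress(np.arange(len(y)), y)
    return float(getattr(res, attr))


def o_agg_linear_trend(x, attr, chunk_len, f_agg):
    x = np.asarray(x, dtype=float)
    agg = {"max": np.max, "min": np.min, "mean": np.mean, "var": np.var}[f_agg]
    chunks = [agg(x[i:i + chunk_len]) for i in range(0, len(x), chunk_len)]
    return o_linear_trend(np.asarray(chunks), attr)


def o_c3(x, lag):
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= 2 * lag:
        return 0.0
    return float(np.mean([x[i + 2 * lag] * x[i + lag] * x[i]
                          for i in range(n - 2 * lag)]))


def o_benford_correlation(x):
    digits = []
    for v in x:
        v = abs(v)
        if v > 0 and np.isfinite(v):
            digits.append(int(v / 10 ** math.floor(math.log10(v))))
    if not digits:
        return 0.0
    freq = np.array([digits.count(d) for d in range(1, 10)]) / len(digits)
    benford = np.log10(1 + 1 / np.arange(1, 10))
    if np.std(freq) == 0:
        return 0.0
    return float(np.corrcoef(freq, benford)[0, 1])


def o_max_langevin_fixed_point(x, m, r):
    x = np.asarray(x, dtype=float)
    dx = np.diff(x)
    xs = x[:-1]
    if np.ptp(xs) == 0:
        return 0.0
    edges = np.unique(np.quantile(xs, np.linspace(0, 1, r + 1)))
    if len(edges) < max(m + 2, 3):
        return 0.0
    bx, bdx = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (xs >= a) & (xs < b) if b != edges[-1] else (xs >= a) & (xs <= b)
        if sel.any():
            bx.append(xs[sel].mean())
            bdx.append(dx[sel].mean())
    if len(bx) < m + 1:
        return 0.0
    try:
        roots = np.roots(np.polyfit(bx, bdx, m))
    except (np.linalg.LinAlgError, ValueError):
        return 0.0
    real = [rt.real for rt in roots if abs(rt.imag) < 1e-10]
    return float(max(real)) if real else 0.0


def o_binned_entropy(x, max_bins):
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    hist, _ = np.histogram(x, bins=max_bins, range=(x.min(), x.max()))
    p = hist / len(x)
    return float(-sum(pi * math.log(pi) for pi in p if pi > 0))


def o_approximate_entropy(x, m, r):
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1 or np.std(x) == 0:
        return 0.0
    tol = r * np.std(x)

    def phi(mm):
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in templates:
            c = sum(1 for b in templates if max(abs(a - b)) <= tol)
            total += math.log(c / len(templates))
        return total / len(templates)

    return float(phi(m) - phi(m + 1))


def o_sample_entropy(x):
    x = np.asarray(x, dtype=float)
    n = len(x)
    m = 2
    if n <= m + 1 or np.std(x) == 0:
        return 0.0
    tol = 0.2 * np.std(x)
    tm = [x[i:i + m] for i in range(n - m)]
    tm1 = [x[i:i + m + 1] for i in range(n - m)]

    def pairs(ts):
        return sum(1 for i in range(len(ts)) for j in range(len(ts))
                   if i != j and max(abs(ts[i] - ts[j])) <= tol)

    B, A = pairs(tm), pairs(tm1)
    if A == 0 or B == 0:
        return 0.0
    return float(-math.log(A / B))


def o_permutation_entropy(x, tau, dimension):
    x = np.asarray(x, dtype=float)
    count = len(x) - (dimension - 1) * tau
    if count < 1:
        return 0.0
    patterns = Counter()
    for i in range(count):
        window = x[i:i + dimension * tau:tau]
        patterns[tuple(np.argsort(window, kind="stable"))] += 1
    return float(-sum((c / count) * math.log(c / count)
                      for c in patterns.values()))


def o_fourier_entropy(x, bins):
    x = np.asarray(x, dtype=float)
    _, pxx = sps.welch(x, nperseg=min(len(x), 30))
    if pxx.max() == 0:
        return 0.0
    return o_binned_entropy(pxx / pxx.max(), bins)


def o_fft_coefficient(x, k, attr):
    c = np.fft.rfft(x)[k]
    return float({"real": c.real, "imag": c.imag, "abs": abs(c),
                  "angle": np.angle(c)}[attr])


def o_fft_aggregated(x, aggtype):
    mag = np.abs(np.fft.rfft(x))
    if mag.sum() == 0:
        return 0.0
    p = mag / mag.sum()
    i = np.arange(len(mag))
    centroid = float((p * i).sum())
    var = float((p * (i - centroid) ** 2).sum())
    if aggtype == "centroid":
        return centroid
    if aggtype == "variance":
        return var
    if var == 0:
        return 0.0
    m3 = float((p * (i - centroid) ** 3).sum())
    m4 = float((p * (i - centroid) ** 4).sum())
    return {"skew": m3 / var ** 1.5, "kurtosis": m4 / var ** 2}[aggtype]


def o_cwt_coefficients(x, w, coeff):
    x = np.asarray(x, dtype=float)
    n = len(x)
    points = min(int(10 * w), n)
    A = 2 / (math.sqrt(3 * w) * math.pi ** 0.25)
    t = np.arange(points) - (points - 1.0) / 2
    wavelet = A * (1 - (t / w) ** 2) * np.exp(-(t ** 2) / (2 * w ** 2))
    conv = np.convolve(x, wavelet, mode="same")
    return float(conv[coeff])


def oracle_value(x, ftype: str, params: dict) -> float:
    """Dispatch one (feature type, params) evaluation to its oracle."""
    fns = {
        "abs_energy": lambda: o_abs_energy(x),
        "absolute_maximum": lambda: o_absolute_maximum(x),
        "absolute_sum_of_changes": lambda: o_absolute_sum_of_changes(x),
        "agg_autocorrelation": lambda: o_agg_autocorrelation(
            x, params["f_agg"], params["maxlag"]),
        "agg_linear_trend": lambda: o_agg_linear_trend(
            x, params["attr"], params["chunk_len"], params["f_agg"]),
        "approximate_entropy": lambda: o_approximate_entropy(
            x, params["m"], params["r"]),
        "autocorrelation": lambda: o_autocorrelation(x, params["lag"]),
        "benford_correlation": lambda: o_benford_correlation(x),
        "binned_entropy": lambda: o_binned_entropy(x, params["max_bins"]),
        "c3": lambda: o_c3(x, params["lag"]),
        "change_quantiles": lambda: o_change_quantiles(
            x, params["ql"], params["qh"], params["isabs"], params["f_agg"]),
        "cid_ce": lambda: o_cid_ce(x, params["normalize"]),
        "count_above": lambda: o_count_above(x, params["t"]),
        "count_below": lambda: o_count_below(x, params["t"]),
        "cwt_coefficients": lambda: o_cwt_coefficients(
            x, params["w"], params["coeff"]),
        "fft_aggregated": lambda: o_fft_aggregated(x, params["aggtype"]),
        "fft_coefficient": lambda: o_fft_coefficient(
            x, params["k"], params["attr"]),
        "fourier_entropy": lambda: o_fourier_entropy(x, params["bins"]),
        "linear_trend": lambda: o_linear_trend(x, params["attr"]),
        "max_langevin_fixed_point": lambda: o_max_langevin_fixed_point(
            x, params["m"], params["r"]),
        "maximum": lambda: o_maximum(x),
        "mean": lambda: o_mean(x),
        "mean_abs_change": lambda: o_mean_abs_change(x),
        "mean_n_absolute_max": lambda: o_mean_n_absolute_max(x, params["n"]),
        "median": lambda: o_median(x),
        "minimum": lambda: o_minimum(x),
        "number_crossing_m": lambda: o_number_crossing_m(x, params["m"]),
        "number_peaks": lambda: o_number_peaks(x, params["n"]),
        "permutation_entropy": lambda: o_permutation_entropy(
            x, params["tau"], params["dimension"]),
        "quantile": lambda: o_quantile(x, params["q"]),
        "range_count": lambda: o_range_count(x, params["min"], params["max"]),
        "root_mean_square": lambda: o_root_mean_square(x),
        "sample_entropy": lambda: o_sample_entropy(x),
        "standard_deviation": lambda: o_standard_deviation(x),
        "sum_values": lambda: o_sum_values(x),
        "variance": lambda: o_variance(x),
        "variation_coefficient": lambda: o_variation_coefficient(x),
    }
    return fns[ftype]()


def assert_catalog_matches(series_list, catalog, rel_tol=1e-6):
    """Check every catalog entry against the oracle on every series."""
    from collections import defaultdict

    from mobilegait.features import compute_entries

    X = np.stack(series_list)
    groups = defaultdict(list)
    for ftype, params in catalog:
        groups[ftype].append(params)
    computed = {}
    for ftype, plist in groups.items():
        vals = compute_entries(X, ftype, plist)
        for params, row in zip(plist, vals):
            computed[(ftype, str(params))] = row

    mismatches = []
    for ftype, params in catalog:
        row = computed[(ftype, str(params))]
        for i, x in enumerate(series_list):
            expect = oracle_value(x, ftype, params)
            tol = rel_tol * max(1.0, abs(expect))
            if not (np.isfinite(row[i]) and abs(row[i] - expect) <= tol):
                mismatches.append((ftype, params, i, row[i], expect))
    assert not mismatches, mismatches[:10]
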