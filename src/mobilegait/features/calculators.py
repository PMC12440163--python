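"""Vectorized time-series feature calculators.

Every calculator is a batch function ``f(X, params_list) -> (n_entries, S)``
operating on ``X`` of shape (S, n): S series of length n. Batching lets
entries of one feature type share precomputation (one FFT for all Fourier
coefficients, one convolution per wavelet width, ...), which is what makes
extracting ~10^4 features per window set affordable.

Degenerate cases (zero variance, empty corridors, undefined correlations)
return 0 rather than NaN so downstream matrices stay finite; this convention
is applied inside each calculator and again as a safety net when the matrix
is assembled.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

__all__ = ["TYPE_FUNCS", "compute_entries", "ricker"]


def _as2d(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def _zeros(X: np.ndarray, k: int = 1) -> np.ndarray:
    return np.zeros((k, X.shape[0]))


# ---------------------------------------------------------------------------
# moment statistics
# ---------------------------------------------------------------------------

def _mean(X, ps):
    return np.tile(X.mean(axis=1), (len(ps), 1))


def _median(X, ps):
    return np.tile(np.median(X, axis=1), (len(ps), 1))


def _maximum(X, ps):
    return np.tile(X.max(axis=1), (len(ps), 1))


def _minimum(X, ps):
    return np.tile(X.min(axis=1), (len(ps), 1))


def _absolute_maximum(X, ps):
    return np.tile(np.abs(X).max(axis=1), (len(ps), 1))


def _standard_deviation(X, ps):
    return np.tile(X.std(axis=1), (len(ps), 1))


def _variance(X, ps):
    return np.tile(X.var(axis=1), (len(ps), 1))


def _variation_coefficient(X, ps):
    mean = X.mean(axis=1)
    std = X.std(axis=1)
    out = np.where(mean != 0, std / np.where(mean != 0, mean, 1.0), 0.0)
    return np.tile(out, (len(ps), 1))


def _root_mean_square(X, ps):
    return np.tile(np.sqrt((X ** 2).mean(axis=1)), (len(ps), 1))


def _sum_values(X, ps):
    return np.tile(X.sum(axis=1), (len(ps), 1))


def _abs_energy(X, ps):
    return np.tile((X ** 2).sum(axis=1), (len(ps), 1))


def _mean_n_absolute_max(X, ps):
    n = X.shape[1]
    a = np.sort(np.abs(X), axis=1)
    out = np.empty((len(ps), X.shape[0]))
    for i, p in enumerate(ps):
        k = int(p["n"])
        if not 1 <= k <= n:
            raise ValueError(f"mean_n_absolute_max needs 1 <= n <= {n}; got {k}")
        out[i] = a[:, -k:].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# change statistics
# ---------------------------------------------------------------------------

def _mean_abs_change(X, ps):
    return np.tile(np.abs(np.diff(X, axis=1)).mean(axis=1), (len(ps), 1))


def _absolute_sum_of_changes(X, ps):
    return np.tile(np.abs(np.diff(X, axis=1)).sum(axis=1), (len(ps), 1))


def _cid_ce(X, ps):
    out = np.empty((len(ps), X.shape[0]))
    for i, p in enumerate(ps):
        if p["normalize"]:
            s = X.std(axis=1)
            Z = np.where(s[:, None] > 0,
                         (X - X.mean(axis=1)[:, None]) / np.where(s[:, None] > 0,
                                                                  s[:, None], 1.0),
                         0.0)
        else:
            Z = X
        out[i] = np.sqrt((np.diff(Z, axis=1) ** 2).sum(axis=1))
    return out


def _number_crossing_m(X, ps):
    out = np.empty((len(ps), X.shape[0]))
    for i, p in enumerate(ps):
        pos = X > p["m"]
        out[i] = (pos[:, 1:] != pos[:, :-1]).sum(axis=1)
    return out


def _number_peaks(X, ps):
    # a peak of support n is strictly greater than its n neighbours on each side
    S, length = X.shape
    out = np.zeros((len(ps), S))
    for i, p in enumerate(ps):
        n = int(p["n"])
        if length < 2 * n + 1:
            continue
        core = X[:, n:length - n]
        is_peak = np.ones(core.shape, dtype=bool)
        for j in range(1, n + 1):
            is_peak &= core > X[:, n - j:length - n - j]
            is_peak &= core > X[:, n + j:length - n + j]
        out[i] = is_peak.sum(axis=1)
    return out


def _count_above(X, ps):
    return np.stack([(X >= p["t"]).mean(axis=1) for p in ps])


def _count_below(X, ps):
    return np.stack([(X <= p["t"]).mean(axis=1) for p in ps])


def _range_count(X, ps):
    return np.stack([((X >= p["min"]) & (X < p["max"])).sum(axis=1).astype(float)
                     for p in ps])


def _quantile(X, ps):
    qs = [p["q"] for p in ps]
    return np.quantile(X, qs, axis=1)


def _change_quantiles(X, ps):
    S = X.shape[0]
    d = np.diff(X, axis=1)
    out = np.zeros((len(ps), S))
    # group by corridor so the quantiles/mask are shared across aggregators
    corridors: dict[tuple, np.ndarray] = {}
    for i, p in enumerate(ps):
        ql, qh = p["ql"], p["qh"]
        if ql >= qh:
            raise ValueError("change_quantiles needs ql < qh")
        key = (ql, qh)
        if key not in corridors:
            lo = np.quantile(X, ql, axis=1)
            hi = np.quantile(X, qh, axis=1)
            inside = (X >= lo[:, None]) & (X <= hi[:, None])
            sel = inside[:, 1:] & inside[:, :-1]
            sel &= (hi > lo)[:, None]          # empty corridor -> 0
            corridors[key] = sel
        sel = corridors[key]
        dv = np.abs(d) if p["isabs"] else d
        cnt = sel.sum(axis=1)
        ok = cnt > 0
        safe = np.where(ok, cnt, 1)
        agg = p["f_agg"]
        if agg == "mean":
            out[i] = np.where(ok, (dv * sel).sum(axis=1) / safe, 0.0)
        elif agg in ("var", "std"):
            m1 = (dv * sel).sum(axis=1) / safe
            m2 = (dv ** 2 * sel).sum(axis=1) / safe
            v = np.maximum(m2 - m1 ** 2, 0.0)
            out[i] = np.where(ok, np.sqrt(v) if agg == "std" else v, 0.0)
        elif agg == "median":
            dm = np.where(sel, dv, np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                med = np.nanmedian(dm, axis=1)
            out[i] = np.where(ok, np.nan_to_num(med), 0.0)
        else:
            raise ValueError(f"unknown aggregator {agg!r}")
    return out


# ---------------------------------------------------------------------------
# correlation / trend
# ---------------------------------------------------------------------------

def _acf_lags(X: np.ndarray, lags: list[int]) -> np.ndarray:
    """Autocorrelation R(l) = sum((x_t-mu)(x_{t+l}-mu)) / ((n-l) sigma^2)."""
    S, n = X.shape
    mu = X.mean(axis=1, keepdims=True)
    Xc = X - mu
    var = (Xc ** 2).mean(axis=1)
    ok = var > 0
    out = np.zeros((len(lags), S))
    for i, lag in enumerate(lags):
        if lag == 0:
            out[i] = np.where(ok, 1.0, 0.0)
            continue
        if lag >= n:
            continue
        num = (Xc[:, :-lag] * Xc[:, lag:]).sum(axis=1)
        out[i] = np.where(ok, num / ((n - lag) * np.where(ok, var, 1.0)), 0.0)
    return out


def _autocorrelation(X, ps):
    return _acf_lags(X, [int(p["lag"]) for p in ps])


def _agg_autocorrelation(X, ps):
    n = X.shape[1]
    out = np.empty((len(ps), X.shape[0]))
    cache: dict[int, np.ndarray] = {}
    for i, p in enumerate(ps):
        maxlag = min(int(p["maxlag"]), n - 1)
        if maxlag not in cache:
            cache[maxlag] = _acf_lags(X, list(range(1, maxlag + 1)))
        acf = cache[maxlag]
        agg = p["f_agg"]
        if agg == "mean":
            out[i] = acf.mean(axis=0)
        elif agg == "median":
            out[i] = np.median(acf, axis=0)
        elif agg == "var":
            out[i] = acf.var(axis=0)
        else:
            raise ValueError(f"unknown aggregator {agg!r}")
    return out


_TREND_ATTRS = ("slope", "intercept", "rvalue", "pvalue", "stderr")


def _trend_attrs(Y: np.ndarray) -> dict[str, np.ndarray]:
    """Least-squares line of each row of Y against 0..n-1 (closed form)."""
    S, n = Y.shape
    if n < 2:
        z = np.zeros(S)
        return {a: z.copy() for a in _TREND_ATTRS} | {"intercept": Y[:, 0].copy()}
    x = np.arange(n, dtype=float)
    mx = x.mean()
    vx = x.var()
    my = Y.mean(axis=1)
    vy = Y.var(axis=1)
    cov = (Y * x).mean(axis=1) - mx * my
    slope = cov / vx
    intercept = my - slope * mx
    ok = vy > 0
    r = np.where(ok, cov / np.sqrt(vx * np.where(ok, vy, 1.0)), 0.0)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    if df > 0:
        one_minus_r2 = np.maximum(1.0 - r ** 2, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(df / np.where(one_minus_r2 > 0, one_minus_r2, np.inf))
        pvalue = 2 * spstats.t.sf(np.abs(t), df)
        pvalue = np.where(one_minus_r2 == 0, 0.0, pvalue)
        pvalue = np.where(ok, pvalue, 1.0)
        stderr = np.sqrt(one_minus_r2 * vy / vx / df)
    else:
        pvalue = np.zeros(S)
        stderr = np.zeros(S)
    return {"slope": slope, "intercept": intercept, "rvalue": r,
            "pvalue": pvalue, "stderr": stderr}


def _linear_trend(X, ps):
    attrs = _trend_attrs(X)
    return np.stack([attrs[p["attr"]] for p in ps])


def _aggregate_chunks(X: np.ndarray, chunk_len: int, f_agg: str) -> np.ndarray:
    S, n = X.shape
    bounds = list(range(0, n, chunk_len)) + [n]
    cols = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        chunk = X[:, a:b]
        if f_agg == "max":
            cols.append(chunk.max(axis=1))
        elif f_agg == "min":
            cols.append(chunk.min(axis=1))
        elif f_agg == "mean":
            cols.append(chunk.mean(axis=1))
        elif f_agg == "var":
            cols.append(chunk.var(axis=1))
        else:
            raise ValueError(f"unknown aggregator {f_agg!r}")
    return np.stack(cols, axis=1)


def _agg_linear_trend(X, ps):
    out = np.empty((len(ps), X.shape[0]))
    cache: dict[tuple, dict[str, np.ndarray]] = {}
    for i, p in enumerate(ps):
        key = (int(p["chunk_len"]), p["f_agg"])
        if key not in cache:
            cache[key] = _trend_attrs(_aggregate_chunks(X, *key))
        out[i] = cache[key][p["attr"]]
    return out


def _c3(X, ps):
    S, n = X.shape
    out = np.zeros((len(ps), S))
    for i, p in enumerate(ps):
        lag = int(p["lag"])
        if n <= 2 * lag:
            continue
        out[i] = (X[:, 2 * lag:] * X[:, lag:n - lag] * X[:, :n - 2 * lag]).mean(axis=1)
    return out


_BENFORD_P = np.log10(1 + 1 / np.arange(1, 10))


def _benford_correlation(X, ps):
    ax = np.abs(X)
    ok = np.isfinite(ax) & (ax > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        digit = np.floor(ax / 10.0 ** np.floor(np.log10(np.where(ok, ax, 1.0))))
    digit = np.where(ok, digit, 0)
    freq = np.stack([((digit == d) & ok).sum(axis=1) for d in range(1, 10)],
                    axis=1).astype(float)
    total = ok.sum(axis=1)
    valid = total > 0
    p = freq / np.where(valid, total, 1)[:, None]
    pc = p - p.mean(axis=1, keepdims=True)
    bc = _BENFORD_P - _BENFORD_P.mean()
    denom = np.sqrt((pc ** 2).sum(axis=1) * (bc ** 2).sum())
    good = valid & (denom > 0)
    corr = np.where(good, (pc * bc).sum(axis=1) / np.where(good, denom, 1.0), 0.0)
    return np.tile(corr, (len(ps), 1))


def _langevin_one(x: np.ndarray, m: int, r: int) -> float:
    """Largest real fixed point of polynomial drift fitted to (x_t, dx_t)."""
    dx = np.diff(x)
    xs = x[:-1]
    if np.ptp(xs) == 0:
        return 0.0
    edges = np.quantile(xs, np.linspace(0, 1, r + 1))
    edges = np.unique(edges)
    if len(edges) < max(m + 2, 3):
        return 0.0
    which = np.clip(np.searchsorted(edges, xs, side="right") - 1, 0, len(edges) - 2)
    bx, bdx = [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.any():
            bx.append(xs[sel].mean())
            bdx.append(dx[sel].mean())
    if len(bx) < m + 1:
        return 0.0
    try:
        coef = np.polyfit(np.asarray(bx), np.asarray(bdx), m)
        roots = np.roots(coef)
    except (np.linalg.LinAlgError, ValueError):
        return 0.0
    real = roots[np.abs(roots.imag) < 1e-10].real
    if len(real) == 0:
        return 0.0
    return float(real.max())


def _max_langevin_fixed_point(X, ps):
    out = np.empty((len(ps), X.shape[0]))
    for i, p in enumerate(ps):
        out[i] = [_langevin_one(x, int(p["m"]), int(p["r"])) for x in X]
    return out


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------

def _binned_entropy_values(V: np.ndarray, bins: int) -> np.ndarray:
    """Shannon entropy (nats) of each row of V binned into equidistant bins."""
    S, n = V.shape
    lo = V.min(axis=1, keepdims=True)
    span = V.max(axis=1, keepdims=True) - lo
    safe = np.where(span > 0, span, 1.0)
    idx = np.minimum((bins * (V - lo) / safe).astype(int), bins - 1)
    idx = np.where(span > 0, idx, 0)
    offsets = np.arange(S)[:, None] * bins
    counts = np.bincount((idx + offsets).ravel(), minlength=S * bins)
    counts = counts.reshape(S, bins)
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    return h


def _binned_entropy(X, ps):
    return np.stack([_binned_entropy_values(X, int(p["max_bins"])) for p in ps])


def _pair_dist(X: np.ndarray) -> np.ndarray:
    """|x_i - x_j| for every sample pair of every series: (S, n, n)."""
    return np.abs(X[:, :, None] - X[:, None, :])


def _template_dist(A: np.ndarray, m: int) -> np.ndarray:
    """Chebyshev distance between all length-m templates, from pair distances.

    d_m[i, j] = max_k |x_{i+k} - x_{j+k}| is the running maximum of A along
    shifted diagonals, so no (S, N, N, m) array is ever built.
    """
    n = A.shape[1]
    N = n - m + 1
    d = A[:, :N, :N].copy()
    for k in range(1, m):
        np.maximum(d, A[:, k:N + k, k:N + k], out=d)
    return d


def _approximate_entropy(X, ps):
    S, n = X.shape
    std = X.std(axis=1)
    A = _pair_dist(X)
    out = np.zeros((len(ps), S))
    for i, p in enumerate(ps):
        m = int(p["m"])
        if n <= m + 1:
            continue
        tol = p["r"] * std
        phis = []
        for mm in (m, m + 1):
            d = _template_dist(A, mm)
            C = (d <= tol[:, None, None]).mean(axis=2)
            phis.append(np.log(C).mean(axis=1))
        out[i] = np.where(std > 0, phis[0] - phis[1], 0.0)
    return out


def _sample_entropy(X, ps):
    S, n = X.shape
    m = 2
    out = np.zeros(S)
    if n > m + 1:
        std = X.std(axis=1)
        tol = (0.2 * std)[:, None, None]
        A = _pair_dist(X)
        N = n - m  # templates compared at both lengths, excluding the last
        dm = _template_dist(A, m)[:, :N, :N]
        dm1 = _template_dist(A, m + 1)
        B = (dm <= tol).sum(axis=(1, 2)) - N   # self-matches removed
        A_cnt = (dm1 <= tol).sum(axis=(1, 2)) - N
        good = (A_cnt > 0) & (B > 0) & (std > 0)
        val = -np.log(np.where(good, A_cnt, 1.0) / np.where(good, B, 1.0))
        out = np.where(good, val, 0.0)
    return np.tile(out, (len(ps), 1))


def _permutation_entropy(X, ps):
    S, n = X.shape
    out = np.zeros((len(ps), S))
    for i, p in enumerate(ps):
        tau, dim = int(p["tau"]), int(p["dimension"])
        count = n - (dim - 1) * tau
        if count < 1:
            continue
        idx = np.arange(0, dim * tau, tau)
        windows = X[:, np.arange(count)[:, None] + idx[None, :]]  # (S, count, dim)
        ranks = np.argsort(windows, axis=-1, kind="stable")
        # Lehmer code: lexicographic rank of the ordinal pattern, < dim!
        fact = np.cumprod([1] + list(range(1, dim)))[::-1]
        codes = np.zeros(ranks.shape[:2], dtype=np.int64)
        for j in range(dim):
            smaller_later = (ranks[..., j + 1:] < ranks[..., j:j + 1]).sum(axis=-1)
            codes += smaller_later * fact[j]
        ncodes = int(np.prod(np.arange(1, dim + 1)))
        offsets = np.arange(S)[:, None] * ncodes
        counts = np.bincount((codes + offsets).ravel(), minlength=S * ncodes)
        prob = counts.reshape(S, ncodes) / count
        with np.errstate(divide="ignore", invalid="ignore"):
            out[i] = -np.where(prob > 0, prob * np.log(prob), 0.0).sum(axis=1)
    return out


def _fourier_entropy(X, ps):
    n = X.shape[1]
    _, pxx = sps.welch(X, axis=1, nperseg=min(n, 30))
    pmax = pxx.max(axis=1, keepdims=True)
    ok = pmax[:, 0] > 0
    norm = pxx / np.where(pmax > 0, pmax, 1.0)
    out = np.empty((len(ps), X.shape[0]))
    for i, p in enumerate(ps):
        h = _binned_entropy_values(norm, int(p["bins"]))
        out[i] = np.where(ok, h, 0.0)
    return out


# ---------------------------------------------------------------------------
# spectral
# ---------------------------------------------------------------------------

def _fft_coefficient(X, ps):
    n = X.shape[1]
    F = np.fft.rfft(X, axis=1)
    out = np.empty((len(ps), X.shape[0]))
    for i, p in enumerate(ps):
        k = int(p["k"])
        if k > n // 2:
            raise ValueError(f"fft_coefficient needs k <= n//2 = {n // 2}; got {k}")
        c = F[:, k]
        attr = p["attr"]
        if attr == "real":
            out[i] = c.real
        elif attr == "imag":
            out[i] = c.imag
        elif attr == "abs":
            out[i] = np.abs(c)
        elif attr == "angle":
            out[i] = np.angle(c)
        else:
            raise ValueError(f"unknown attr {attr!r}")
    return out


def _fft_aggregated(X, ps):
    mag = np.abs(np.fft.rfft(X, axis=1))
    total = mag.sum(axis=1)
    ok = total > 0
    p_spec = mag / np.where(ok, total, 1.0)[:, None]
    idx = np.arange(mag.shape[1], dtype=float)
    centroid = (p_spec * idx).sum(axis=1)
    var = (p_spec * (idx[None, :] - centroid[:, None]) ** 2).sum(axis=1)
    dev = idx[None, :] - centroid[:, None]
    m3 = (p_spec * dev ** 3).sum(axis=1)
    m4 = (p_spec * dev ** 4).sum(axis=1)
    pos = var > 0
    skew = np.where(pos, m3 / np.where(pos, var, 1.0) ** 1.5, 0.0)
    kurt = np.where(pos, m4 / np.where(pos, var, 1.0) ** 2, 0.0)
    values = {"centroid": np.where(ok, centroid, 0.0),
              "variance": np.where(ok, var, 0.0),
              "skew": np.where(ok, skew, 0.0),
              "kurtosis": np.where(ok, kurt, 0.0)}
    return np.stack([values[p["aggtype"]] for p in ps])


def ricker(points: int, a: float) -> np.ndarray:
    """Ricker (Mexican-hat) wavelet, the normalized second Gaussian derivative."""
    A = 2 / (np.sqrt(3 * a) * np.pi ** 0.25)
    t = np.arange(points) - (points - 1.0) / 2
    return A * (1 - (t / a) ** 2) * np.exp(-(t ** 2) / (2 * a ** 2))


def _cwt_coefficients(X, ps):
    n = X.shape[1]
    conv_cache: dict[float, np.ndarray] = {}
    out = np.empty((len(ps), X.shape[0]))
    for i, p in enumerate(ps):
        w = float(p["w"])
        if w not in conv_cache:
            kernel = ricker(min(int(10 * w), n), w)
            conv_cache[w] = sps.fftconvolve(X, kernel[None, :], mode="same", axes=1)
        coeff = int(p["coeff"])
        if coeff >= n:
            raise ValueError(f"cwt coefficient index {coeff} >= series length {n}")
        out[i] = conv_cache[w][:, coeff]
    return out


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

TYPE_FUNCS = {
    "abs_energy": _abs_energy,
    "absolute_maximum": _absolute_maximum,
    "absolute_sum_of_changes": _absolute_sum_of_changes,
    "agg_autocorrelation": _agg_autocorrelation,
    "agg_linear_trend": _agg_linear_trend,
    "approximate_entropy": _approximate_entropy,
    "autocorrelation": _autocorrelation,
    "benford_correlation": _benford_correlation,
    "binned_entropy": _binned_entropy,
    "c3": _c3,
    "change_quantiles": _change_quantiles,
    "cid_ce": _cid_ce,
    "count_above": _count_above,
    "count_below": _count_below,
    "cwt_coefficients": _cwt_coefficients,
    "fft_aggregated": _fft_aggregated,
    "fft_coefficient": _fft_coefficient,
    "fourier_entropy": _fourier_entropy,
    "linear_trend": _linear_trend,
    "max_langevin_fixed_point": _max_langevin_fixed_point,
    "maximum": _maximum,
    "mean": _mean,
    "mean_abs_change": _mean_abs_change,
    "mean_n_absolute_max": _mean_n_absolute_max,
    "median": _median,
    "minimum": _minimum,
    "number_crossing_m": _number_crossing_m,
    "number_peaks": _number_peaks,
    "permutation_entropy": _permutation_entropy,
    "quantile": _quantile,
    "range_count": _range_count,
    "root_mean_square": _root_mean_square,
    "sample_entropy": _sample_entropy,
    "standard_deviation": _standard_deviation,
    "sum_values": _sum_values,
    "variance": _variance,
    "variation_coefficient": _variation_coefficient,
}


def compute_entries(X: np.ndarray, ftype: str,
                    params_list: list[dict]) -> np.ndarray:
    """Evaluate all parameterizations of one feature type on a series batch.

    Returns an array of shape (len(params_list), S).
    """
    X = _as2d(X)
    if X.shape[1] < 1:
        raise ValueError("series must be non-empty")
    if ftype not in TYPE_FUNCS:
        raise ValueError(f"unknown feature type {ftype!r}")
    return TYPE_FUNCS[ftype](X, params_list)
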