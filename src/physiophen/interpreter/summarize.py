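"""Stage 6 — summary statistics of time-varying marker series.

Sixteen statistics describe each per-beat/per-pulse/per-cycle series
over the 5-minute window; five of them (mean, 25th/75th percentiles,
skewness, Shannon entropy) are retained for the feature table to limit
redundancy.  Scalar HRV indices bypass summarization entirely — they
are already window-level aggregates.
"""

from __future__ import annotations

import numpy as np

from .hrv import histogram_entropy

__all__ = ["summarize", "ALL_STATS", "RETAINED_STATS", "select_retained"]

ALL_STATS = ["mean", "median", "sd", "mad", "iqr", "min", "max", "p25", "p75",
             "skewness", "kurtosis", "entropy", "slope", "lag1_ac", "gini",
             "n_valid"]
RETAINED_STATS = ["mean", "p25", "p75", "skewness", "entropy"]


def _gini(x: np.ndarray) -> float:
    # mean absolute difference normalised by twice the mean; 0 for constants
    mu = np.mean(np.abs(x))
    if mu == 0 or len(x) < 2:
        return 0.0
    xs = np.sort(x)
    n = len(xs)
    cum = np.cumsum(xs)
    mad = 2.0 / (n * n) * np.sum((2 * np.arange(1, n + 1) - n - 1) * xs)
    return float(mad / (2.0 * np.mean(xs))) if np.mean(xs) != 0 else 0.0


def summarize(series: np.ndarray) -> dict[str, float]:
    """The 16 summary statistics of one time-varying marker series.

    Requires at least two valid (finite) values; otherwise every
    statistic is NaN (``n_valid`` still reports the count).
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        out = {k: np.nan for k in ALL_STATS}
        out["n_valid"] = float(n)
        return out
    const = np.ptp(x) == 0
    mu = float(x.mean())
    dev = x - mu
    m2 = float(np.mean(dev ** 2))
    # Fisher-Pearson skewness / excess kurtosis from raw moments
    if const or m2 == 0:
        skew = kurt = 0.0
    else:
        skew = float(np.mean(dev ** 3) / m2 ** 1.5)
        kurt = float(np.mean(dev ** 4) / m2 ** 2 - 3.0)
    p25, med, p75 = (float(v) for v in np.percentile(x, [25, 50, 75]))
    # least-squares slope against the sample index, in closed form
    idx = np.arange(n)
    slope = float(np.cov(idx, x, bias=True)[0, 1] / np.var(idx))
    if const:
        lag1 = 0.0
    else:
        a, b = x[:-1], x[1:]
        denom = np.sqrt(np.var(a) * np.var(b))
        lag1 = float(np.mean((a - a.mean()) * (b - b.mean())) / denom) if denom > 0 else 0.0
    out = {
        "mean": mu,
        "median": med,
        "sd": float(np.sqrt(m2 * n / (n - 1))),
        "mad": float(np.mean(np.abs(dev))),
        "iqr": p75 - p25,
        "min": float(x.min()),
        "max": float(x.max()),
        "p25": p25,
        "p75": p75,
        "skewness": skew,
        "kurtosis": kurt,
        "entropy": histogram_entropy(x),
        "slope": slope,
        "lag1_ac": lag1,
        "gini": _gini(x),
        "n_valid": float(n),
    }
    return out


def select_retained(summary: dict[str, float]) -> dict[str, float]:
    """The five retained statistics of a full summary."""
    return {k: summary[k] for k in RETAINED_STATS}
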