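"""Stage 5a — heart-rate-variability indices from beat intervals.

All indices operate on NN (normal-to-normal) intervals: detected RR
intervals pass an artifact filter first (absolute range [300, 2000] ms
and successive relative change <= 30% against the last accepted
interval), which removes ectopic pauses and missed/extra detections.

Time domain follows the standard definitions (sample SD with n-1 for
SDNN).  Frequency domain uses the Lomb-Scargle periodogram of the
irregularly sampled NN tachogram, reported as normalized power
fractions of the full spectral grid so indices stay dimensionless.
Nonlinear indices: Shannon entropy of the NN histogram, sample entropy,
fuzzy entropy (exponential membership), composite multiscale sample
entropy (scales 1-3), Grassberger-Procaccia correlation dimension
(embeddings 2-5) and the Katz fractal dimension.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist

__all__ = ["nn_filter", "compute_hrv", "sample_entropy", "fuzzy_entropy",
           "correlation_dimension", "katz_fd", "histogram_entropy", "HRV_NAMES"]

HRV_NAMES = [
    "MeanNN", "MedianNN", "SDNN", "RMSSD", "SDSD", "pNN50", "pNN20",
    "MinNN", "MaxNN", "CVNN", "IQRNN",
    "VLF", "LF", "HF", "TP", "LFHF", "LFnu", "HFnu",
    "ShanEn", "SampEn", "FuzzyEn", "CMSEn", "CD", "KFD",
    "SD1", "SD2", "SD1SD2",
]

_BANDS = {"VLF": (0.003, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.40),
          "TP": (0.003, 0.40)}


def nn_filter(rr_ms: np.ndarray, lo: float = 300.0, hi: float = 2000.0,
              max_rel_change: float = 0.30) -> np.ndarray:
    """Drop non-NN intervals (out of range or abrupt successive change)."""
    rr = np.asarray(rr_ms, dtype=float)
    keep: list[float] = []
    prev = None
    for v in rr:
        if not np.isfinite(v) or not (lo <= v <= hi):
            continue
        if prev is not None and abs(v - prev) / prev > max_rel_change:
            continue
        keep.append(v)
        prev = v
    return np.asarray(keep)


def histogram_entropy(x: np.ndarray, max_bins: int = 512) -> float:
    """Shannon entropy (nats) of the Freedman-Diaconis-binned histogram.

    The bin count is capped: a near-zero IQR with a wide range would
    otherwise request an astronomical number of bins.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2 or np.ptp(x) == 0:
        return 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    h = 2.0 * iqr / len(x) ** (1.0 / 3.0)
    n_bins = int(np.ceil(np.ptp(x) / h)) if h > 0 else max_bins
    n_bins = min(max(n_bins, 1), max_bins)
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    n = len(x) - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): -ln of the conditional template-match probability."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x)
    if len(x) < m + 2 or r <= 0:
        return np.nan
    b = np.count_nonzero(pdist(_embed(x, m), "chebyshev") <= r)
    a = np.count_nonzero(pdist(_embed(x, m + 1), "chebyshev") <= r)
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def fuzzy_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """FuzzyEn with exponential membership exp(-(d/r)^2) on centred templates."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x)
    if len(x) < m + 2 or r <= 0:
        return np.nan
    phis = []
    for mm in (m, m + 1):
        t = _embed(x, mm)
        t = t - t.mean(axis=1, keepdims=True)
        d = pdist(t, "chebyshev")
        phis.append(np.mean(np.exp(-((d / r) ** 2))))
    if phis[1] == 0 or phis[0] == 0:
        return np.nan
    return float(np.log(phis[0] / phis[1]))


def composite_multiscale_entropy(x: np.ndarray, m: int = 2,
                                 scales: tuple[int, ...] = (1, 2, 3)) -> float:
    """CMSEn: SampEn of every coarse-grain offset, averaged over scales 1-3."""
    x = np.asarray(x, dtype=float)
    r = 0.2 * np.std(x)
    vals = []
    for tau in scales:
        ses = []
        for off in range(tau):
            n_cg = (len(x) - off) // tau
            if n_cg < m + 2:
                continue
            cg = x[off:off + n_cg * tau].reshape(-1, tau).mean(axis=1)
            se = sample_entropy(cg, m=m, r=r)
            if np.isfinite(se):
                ses.append(se)
        if ses:
            vals.append(np.mean(ses))
    return float(np.mean(vals)) if vals else np.nan


def correlation_dimension(x: np.ndarray, m_range: tuple[int, ...] = (2, 3, 4, 5)) -> float:
    """Grassberger-Procaccia correlation dimension.

    For each embedding dimension the correlation sum C(r) is evaluated on
    a log-spaced radius grid inside the scaling region (10th-60th
    percentile of pairwise distances) and the log-log least-squares slope
    is taken; the estimate is the mean slope across embeddings.
    """
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0 or len(x) < max(m_range) + 5:
        return np.nan
    slopes = []
    for m in m_range:
        d = pdist(_embed(x, m), "chebyshev")
        d = d[d > 0]
        if len(d) < 20:
            continue
        r_lo, r_hi = np.percentile(d, [10, 60])
        if r_hi <= r_lo or r_lo <= 0:
            continue
        radii = np.geomspace(r_lo, r_hi, 10)
        c = np.array([np.mean(d <= r) for r in radii])
        ok = c > 0
        if ok.sum() < 3:
            continue
        slope = np.polyfit(np.log(radii[ok]), np.log(c[ok]), 1)[0]
        slopes.append(slope)
    return float(np.mean(slopes)) if slopes else np.nan


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension log10(n) / (log10(n) + log10(d/L))."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return np.nan
    length = np.abs(np.diff(x)).sum()
    d = np.abs(x - x[0]).max()
    if length == 0 or d == 0:
        return 1.0  # straight/degenerate waveform
    return float(np.log10(n) / (np.log10(n) + np.log10(d / length)))


def _lomb_scargle(t: np.ndarray, x: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Classic (unnormalised) Lomb-Scargle periodogram, vectorised over freqs."""
    w = 2 * np.pi * freqs[:, None]
    wt = w * t[None, :]
    s2 = np.sin(2 * wt).sum(axis=1)
    c2 = np.cos(2 * wt).sum(axis=1)
    tau = np.arctan2(s2, c2) / 2.0
    arg = wt - tau[:, None]
    cosa = np.cos(arg)
    sina = np.sin(arg)
    xc = (x[None, :] * cosa).sum(axis=1)
    xs = (x[None, :] * sina).sum(axis=1)
    cc = (cosa ** 2).sum(axis=1)
    ss = (sina ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 0.5 * (np.where(cc > 0, xc ** 2 / cc, 0.0)
                   + np.where(ss > 0, xs ** 2 / ss, 0.0))
    return p


def _spectral(nn: np.ndarray) -> dict[str, float]:
    t = np.cumsum(nn) / 1000.0
    x = nn - nn.mean()
    out = {k: 0.0 for k in _BANDS} | {"LFHF": np.nan, "LFnu": np.nan, "HFnu": np.nan}
    if np.std(x) == 0 or len(nn) < 10:
        return out
    freqs = np.arange(0.003, 0.5, 0.002)
    power = _lomb_scargle(t, x, freqs)
    total = power.sum()
    if total <= 0:
        return out
    for name, (lo, hi) in _BANDS.items():
        sel = (freqs >= lo) & (freqs < hi)
        out[name] = float(power[sel].sum() / total)
    if out["HF"] > 0:
        out["LFHF"] = out["LF"] / out["HF"]
    denom = out["LF"] + out["HF"]
    if denom > 0:
        out["LFnu"] = out["LF"] / denom
        out["HFnu"] = out["HF"] / denom
    return out


def compute_hrv(rr_ms: np.ndarray, min_intervals: int = 10) -> dict[str, float]:
    """All scalar HRV indices from a detected RR sequence (ms).

    NN filtering happens internally; fewer than ``min_intervals``
    surviving intervals yields a row of NaNs.
    """
    nn = nn_filter(rr_ms)
    if len(nn) < min_intervals:
        return {k: np.nan for k in HRV_NAMES}
    d = np.diff(nn)
    sdnn = float(np.std(nn, ddof=1))
    rmssd = float(np.sqrt(np.mean(d ** 2))) if len(d) else np.nan
    out: dict[str, float] = {
        "MeanNN": float(nn.mean()),
        "MedianNN": float(np.median(nn)),
        "SDNN": sdnn,
        "RMSSD": rmssd,
        "SDSD": float(np.std(d, ddof=1)) if len(d) > 1 else np.nan,
        "pNN50": float(100.0 * np.mean(np.abs(d) > 50.0)) if len(d) else np.nan,
        "pNN20": float(100.0 * np.mean(np.abs(d) > 20.0)) if len(d) else np.nan,
        "MinNN": float(nn.min()),
        "MaxNN": float(nn.max()),
        "CVNN": sdnn / float(nn.mean()),
        "IQRNN": float(np.subtract(*np.percentile(nn, [75, 25]))),
    }
    out.update(_spectral(nn))
    out["ShanEn"] = histogram_entropy(nn)
    out["SampEn"] = sample_entropy(nn)
    out["FuzzyEn"] = fuzzy_entropy(nn)
    out["CMSEn"] = composite_multiscale_entropy(nn)
    out["CD"] = correlation_dimension(nn)
    out["KFD"] = katz_fd(nn)
    sd1 = rmssd / np.sqrt(2.0) if np.isfinite(rmssd) else np.nan
    sd2sq = 2 * sdnn ** 2 - sd1 ** 2 if np.isfinite(sd1) else np.nan
    sd2 = np.sqrt(sd2sq) if np.isfinite(sd2sq) and sd2sq >= 0 else np.nan
    out["SD1"] = float(sd1)
    out["SD2"] = float(sd2)
    out["SD1SD2"] = float(sd1 / sd2) if np.isfinite(sd2) and sd2 > 0 else np.nan
    return out
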