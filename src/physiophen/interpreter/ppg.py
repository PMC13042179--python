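"""Stage 5b — PPG morphology, timing and ECG-PPG coupling markers.

Per-pulse measurements are taken between delineated onset and offset
with the onset amplitude as the local baseline, which makes amplitude
markers invariant to additive shifts of the raw PPG and normalized-area
and width markers invariant to positive rescaling.
"""

from __future__ import annotations

import numpy as np

from ..types import Channel, FiducialSet

__all__ = ["compute_ppg_markers", "PPG_SERIES_NAMES", "N_EIGENVALUES"]

PPG_SERIES_NAMES = [
    "A_AC", "A_DC", "AUCos", "AUCso", "AUC_total", "AUCos_nu", "AUCso_nu",
    "PW_25", "PW_50", "PW_75", "T_sys", "T_dia", "T_pulse", "sys_dia_ratio",
    "mean_slope_os", "mean_slope_so", "notch_time_frac", "notch_rel_amp",
    "VPG_max", "APG_max", "reflection_index",
]
N_EIGENVALUES = 5
MIN_PULSES = 5
_RESAMPLE_LEN = 100


def _pulse_width(y: np.ndarray, sys_idx: int, level: float, fs: float) -> float:
    """Width (ms) at an amplitude level, interpolated on both flanks."""
    above = y >= level
    if not above[sys_idx]:
        return np.nan
    left = above[: sys_idx + 1][::-1]
    i = sys_idx - (int(np.argmin(left)) - 1) if not left.all() else 0
    right = above[sys_idx:]
    j = sys_idx + (int(np.argmin(right)) - 1) if not right.all() else len(y) - 1
    # sub-sample linear interpolation on each flank
    t_left = float(i)
    if i > 0 and y[i] != y[i - 1]:
        t_left = i - (y[i] - level) / (y[i] - y[i - 1])
    t_right = float(j)
    if j < len(y) - 1 and y[j] != y[j + 1]:
        t_right = j + (y[j] - level) / (y[j] - y[j + 1])
    return float((t_right - t_left) / fs * 1000.0)


def compute_ppg_markers(
    ppg: Channel,
    fiducials: FiducialSet,
    rpeaks: np.ndarray | None = None,
    ecg_fs: float | None = None,
    vpg: np.ndarray | None = None,
    apg: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-pulse marker series and interbeat covariance eigenvalues.

    Returns ``(series, eigenvalues)`` where ``series`` maps each marker
    name to one value per delineated pulse (NaN where undefined, e.g. no
    dicrotic notch) and ``eigenvalues`` holds the descending eigenvalues
    of the covariance matrix of pulses resampled to a fixed length.
    PAT markers need R peaks (in ECG sample indices) and the ECG rate;
    each pulse is matched to the closest preceding R peak within one
    cardiac cycle, unmatched pulses are skipped.
    """
    pulses = fiducials.ppg_pulses
    series: dict[str, list[float]] = {k: [] for k in PPG_SERIES_NAMES + ["PAT_ms", "PAT_peak_ms"]}
    if len(pulses) < MIN_PULSES:
        nan = np.array([])
        return {k: nan for k in series}, np.full(N_EIGENVALUES, np.nan)

    x = ppg.samples
    fs = ppg.fs
    # pulse validity: a merged (missed-onset) or otherwise implausible
    # pulse whose duration strays far from the typical inter-onset
    # interval distorts normalized-shape statistics; exclude it the same
    # way NN filtering excludes non-normal beats
    durations = np.array([p.offset - p.onset for p in pulses], dtype=float)
    med_dur = np.median(durations)
    pulses = [p for p, d in zip(pulses, durations)
              if 0.4 * med_dur <= d <= 1.8 * med_dur]
    if len(pulses) < MIN_PULSES:
        nan = np.array([])
        return {k: nan for k in series}, np.full(N_EIGENVALUES, np.nan)
    if vpg is None:
        vpg = np.gradient(x) * fs
    if apg is None:
        apg = np.gradient(vpg) * fs
    t_r = np.asarray(rpeaks) / ecg_fs if rpeaks is not None and ecg_fs else None
    median_cycle = np.median(np.diff([p.onset for p in pulses])) / fs

    grid = np.linspace(0.0, 1.0, _RESAMPLE_LEN)
    dt = 1.0 / fs
    shapes = []
    for p in pulses:
        seg = x[p.onset:p.offset + 1]
        base = x[p.onset]
        y = seg - base
        sys_rel = p.systolic - p.onset
        a_ac = float(y[sys_rel])
        dur = (p.offset - p.onset) / fs
        t_sys = (p.systolic - p.onset) / fs
        t_dia = (p.offset - p.systolic) / fs
        y_os = y[:sys_rel + 1]
        y_so = y[sys_rel:]
        auc_os = float((y_os.sum() - 0.5 * (y_os[0] + y_os[-1])) * dt)
        auc_so = float((y_so.sum() - 0.5 * (y_so[0] + y_so[-1])) * dt)
        denom = dur * a_ac if a_ac > 0 else np.nan
        series["A_AC"].append(a_ac)
        series["A_DC"].append(float(base))
        series["AUCos"].append(auc_os)
        series["AUCso"].append(auc_so)
        series["AUC_total"].append(auc_os + auc_so)
        series["AUCos_nu"].append(auc_os / denom if np.isfinite(denom) else np.nan)
        series["AUCso_nu"].append(auc_so / denom if np.isfinite(denom) else np.nan)
        for pct in (25, 50, 75):
            series[f"PW_{pct}"].append(
                _pulse_width(y, sys_rel, a_ac * pct / 100.0, fs) if a_ac > 0 else np.nan)
        series["T_sys"].append(t_sys * 1000.0)
        series["T_dia"].append(t_dia * 1000.0)
        series["T_pulse"].append(dur * 1000.0)
        series["sys_dia_ratio"].append(t_sys / t_dia if t_dia > 0 else np.nan)
        series["mean_slope_os"].append(a_ac / t_sys if t_sys > 0 else np.nan)
        series["mean_slope_so"].append(a_ac / t_dia if t_dia > 0 else np.nan)
        if p.notch is not None:
            series["notch_time_frac"].append((p.notch - p.onset) / (p.offset - p.onset))
            series["notch_rel_amp"].append(
                float((x[p.notch] - base) / a_ac) if a_ac > 0 else np.nan)
        else:
            series["notch_time_frac"].append(np.nan)
            series["notch_rel_amp"].append(np.nan)
        series["VPG_max"].append(float(vpg[p.onset:p.offset + 1].max()))
        series["APG_max"].append(float(apg[p.onset:p.offset + 1].max()))
        if p.diastolic is not None and a_ac > 0:
            series["reflection_index"].append(float((x[p.diastolic] - base) / a_ac))
        else:
            series["reflection_index"].append(np.nan)
        # ECG-PPG coupling: onset (foot) relative to the preceding R peak
        if t_r is not None and len(t_r):
            t_on = p.onset / fs
            prev = np.searchsorted(t_r, t_on) - 1
            if prev >= 0 and (t_on - t_r[prev]) <= 1.5 * median_cycle:
                series["PAT_ms"].append((t_on - t_r[prev]) * 1000.0)
                series["PAT_peak_ms"].append((p.systolic / fs - t_r[prev]) * 1000.0)
            else:
                series["PAT_ms"].append(np.nan)
                series["PAT_peak_ms"].append(np.nan)
        else:
            series["PAT_ms"].append(np.nan)
            series["PAT_peak_ms"].append(np.nan)
        shapes.append(np.interp(grid * (len(y) - 1), np.arange(len(y)), y))

    out = {k: np.asarray(v, dtype=float) for k, v in series.items()}
    shapes_arr = np.asarray(shapes)
    cov = np.cov(shapes_arr, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1][:N_EIGENVALUES]
    eig = np.maximum(eig, 0.0)
    if len(eig) < N_EIGENVALUES:
        eig = np.pad(eig, (0, N_EIGENVALUES - len(eig)))
    return out, eig
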