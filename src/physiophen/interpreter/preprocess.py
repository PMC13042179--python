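"""Stage 1 — quality control and resampling.

Flatline segments (rolling-window variance collapse), rail clipping runs
and amplitude outliers (|z| above a threshold) are masked; outlier
samples are additionally bridged by linear interpolation, and each
channel is resampled to its configured uniform rate.  A record whose
worst channel falls below the usable-fraction floor is flagged low
quality; downstream extraction then reports missing markers rather than
raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import resample_poly
from fractions import Fraction

from ..types import Channel, ChannelQuality, QualityReport, WaveformRecord

__all__ = ["QCConfig", "preprocess"]


@dataclass
class QCConfig:
    flatline_window_s: float = 2.0
    flatline_rel_eps: float = 1e-6     # variance threshold relative to channel variance
    clip_run_s: float = 0.2
    z_threshold: float = 6.0
    min_usable_fraction: float = 0.5
    target_fs: dict = field(default_factory=dict)  # channel -> fs; empty = keep


def _rolling_var(x: np.ndarray, win: int) -> np.ndarray:
    m = uniform_filter1d(x, size=win, mode="nearest")
    m2 = uniform_filter1d(x * x, size=win, mode="nearest")
    return np.maximum(m2 - m * m, 0.0)


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Length of the run each True sample belongs to (0 where False)."""
    out = np.zeros(len(mask), dtype=int)
    if not mask.any():
        return out
    padded = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    for s, e in zip(starts, ends):
        out[s:e] = e - s
    return out


def preprocess(record: WaveformRecord, rules: QCConfig | None = None
               ) -> tuple[WaveformRecord, QualityReport]:
    """Apply QC masking and uniform resampling to every channel."""
    rules = rules or QCConfig()
    if not record.channels:
        raise ValueError("record has no channels")
    out_channels: dict[str, Channel] = {}
    qualities: dict[str, ChannelQuality] = {}
    for name, ch in record.channels.items():
        x = ch.samples.astype(float)
        n = len(x)
        fs = ch.fs
        var = float(np.var(x))

        win = max(int(round(rules.flatline_window_s * fs)), 2)
        eps = max(rules.flatline_rel_eps * var, 1e-24)
        flat = _rolling_var(x, win) < eps
        if var < 1e-24:
            flat = np.ones(n, dtype=bool)

        lo, hi = x.min(), x.max()
        tol = 1e-9 * max(hi - lo, 1.0)
        run_min = max(int(round(rules.clip_run_s * fs)), 1)
        clip = np.zeros(n, dtype=bool)
        if hi - lo > tol:
            for rail in (lo, hi):
                at_rail = np.abs(x - rail) <= tol
                clip |= _run_lengths(at_rail) >= run_min

        good = ~(flat | clip)
        outl = np.zeros(n, dtype=bool)
        if good.sum() > 10:
            mu = x[good].mean()
            sd = x[good].std()
            if sd > 0:
                outl = good & (np.abs(x - mu) / sd > rules.z_threshold)
        if outl.any():
            keep = ~outl
            x = x.copy()
            x[outl] = np.interp(np.flatnonzero(outl), np.flatnonzero(keep), x[keep])

        mask = ~(flat | clip | outl)
        q = ChannelQuality(
            flatline_fraction=float(flat.mean()),
            clipping_fraction=float(clip.mean()),
            outlier_fraction=float(outl.mean()),
            usable_fraction=float(mask.mean()),
        )
        qualities[name] = q

        new_fs = rules.target_fs.get(name, fs)
        if abs(new_fs - fs) > 1e-9:
            frac = Fraction(new_fs / fs).limit_denominator(1000)
            x = resample_poly(x, frac.numerator, frac.denominator)
            idx = np.minimum((np.arange(len(x)) * fs / new_fs).astype(int), n - 1)
            mask = mask[idx]
            fs = new_fs
        out_channels[name] = Channel(x, fs=fs, units=ch.units, quality_mask=mask)

    low_q = any(q.usable_fraction < rules.min_usable_fraction for q in qualities.values())
    report = QualityReport(channels=qualities, low_quality=low_q)
    out = WaveformRecord(channels=out_channels, start_time=record.start_time,
                         patient_id=record.patient_id, meta=dict(record.meta))
    out.meta["low_quality"] = low_q
    return out, report
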