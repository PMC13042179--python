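"""Stage 2 — despiking and zero-phase band-pass filtering.

Per-channel pass bands follow standard monitoring practice: ECG
0.5-40 Hz, PPG 0.5-8 Hz, RESP 0.1-0.5 Hz.  A short median filter first
suppresses impulse artifacts; its kernel must stay well below the
narrowest physiological deflection of the channel (the ~80 ms QRS for
ECG), so kernels are per-channel rather than one global value.
Filtering is zero-phase (forward-backward), preserving landmark timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import butter, sosfiltfilt

from ..types import Channel, WaveformRecord

__all__ = ["DenoiseConfig", "denoise"]

_DEFAULT_BANDS = {"ecg": (0.5, 40.0), "ppg": (0.5, 8.0), "resp": (0.1, 0.5)}
_DEFAULT_MEDIAN_S = {"ecg": 0.012, "ppg": 0.04, "resp": 0.2}


@dataclass
class DenoiseConfig:
    bands: dict = field(default_factory=lambda: dict(_DEFAULT_BANDS))
    median_kernel_s: dict = field(default_factory=lambda: dict(_DEFAULT_MEDIAN_S))
    order: int = 4


def denoise(record: WaveformRecord, config: DenoiseConfig | None = None) -> WaveformRecord:
    """Band-limit every named channel; unknown channels pass through."""
    config = config or DenoiseConfig()
    out = record.copy()
    for name, ch in out.channels.items():
        band = config.bands.get(name)
        if band is None:
            continue
        lo, hi = band
        fs = ch.fs
        nyq = fs / 2.0
        hi = min(hi, 0.95 * nyq)
        sos = butter(config.order, [lo / nyq, hi / nyq], btype="band", output="sos")
        # padlen used by sosfiltfilt; treat shorter channels as unusable
        padlen = 3 * (2 * config.order + 1)
        if len(ch.samples) <= 3 * padlen:
            ch.quality_mask[:] = False
            continue
        x = ch.samples
        k = int(round(config.median_kernel_s.get(name, 0.0) * fs))
        if k >= 3:
            x = median_filter(x, size=k | 1, mode="nearest")
        ch.samples = sosfiltfilt(sos, x)
    return out
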