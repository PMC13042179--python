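"""Stage 3 — derived signals: EDR, VPG, APG.

EDR (ECG-derived respiration) interpolates the per-beat R amplitudes
onto a uniform low-rate time base; respiration modulates R amplitude,
so this series tracks the respiratory waveform.  VPG/APG are the first
and second time derivatives of the PPG (lightly smoothed), used by the
delineator to locate pulse feet and dicrotic notches.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from ..types import Channel, WaveformRecord

__all__ = ["derive_signals"]

_EDR_FS = 4.0


def derive_signals(record: WaveformRecord, rpeaks: np.ndarray) -> dict[str, Channel]:
    """Compute {EDR, VPG, APG} from a denoised record.

    Missing PPG simply omits VPG/APG; EDR requires >= 3 R peaks.
    """
    derived: dict[str, Channel] = {}
    rpeaks = np.asarray(rpeaks, dtype=int)
    if "ecg" in record and len(rpeaks) >= 3:
        ecg = record["ecg"]
        t_r = rpeaks / ecg.fs
        amps = ecg.samples[rpeaks]
        t_out = np.arange(t_r[0], t_r[-1], 1.0 / _EDR_FS)
        if len(t_out) >= 2:
            edr = CubicSpline(t_r, amps)(t_out)
            derived["edr"] = Channel(edr, fs=_EDR_FS, units=ecg.units)
    if "ppg" in record:
        ppg = record["ppg"]
        fs = ppg.fs
        smooth = max(int(round(0.02 * fs)) | 1, 1)  # odd: no half-sample shift
        vpg = uniform_filter1d(np.gradient(ppg.samples) * fs, size=smooth, mode="nearest")
        apg = uniform_filter1d(np.gradient(vpg) * fs, size=smooth, mode="nearest")
        derived["vpg"] = Channel(vpg, fs=fs, units=f"{ppg.units}/s")
        derived["apg"] = Channel(apg, fs=fs, units=f"{ppg.units}/s^2")
    return derived
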