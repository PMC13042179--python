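"""Stage 4 — fiducial-point delineation.

R peaks: derivative-square-moving-integral energy transform with an
adaptive threshold and a 200 ms refractory period (the classic
real-time QRS detector recipe), refined to the local ECG maximum.

PPG pulses: candidate upstrokes from VPG maxima; the onset (foot) is the
signal minimum preceding the maximal upstroke, the systolic peak the
maximum before the next onset, the dicrotic notch the first
negative-to-positive APG zero crossing (fallback: VPG local minimum)
inside the 40-70% span of the pulse, followed by the diastolic wave
peak; the offset is the next onset.

RESP: inspiration/expiration transitions from zero crossings of the
mean-removed signal, with per-cycle extrema (troughs = end-expiration).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from ..types import Channel, FiducialSet, PulseFiducials, WaveformRecord

__all__ = ["delineate", "detect_r_peaks"]

MIN_BEATS = 10  # fewer detected beats marks beat-dependent markers missing


def detect_r_peaks(ecg: Channel) -> np.ndarray:
    """Energy-transform R-peak detector with 200 ms refractory period."""
    x = ecg.samples
    fs = ecg.fs
    d = np.gradient(x) * fs
    energy = uniform_filter1d(d * d, size=max(int(0.15 * fs), 1), mode="nearest")
    dist = max(int(0.2 * fs), 1)
    peaks, props = find_peaks(energy, distance=dist)
    if len(peaks) == 0:
        return np.array([], dtype=int)
    heights = energy[peaks]
    thr = 0.25 * np.percentile(heights, 75)
    peaks = peaks[heights > thr]
    # refine to the ECG local maximum within +/- 60 ms
    half = int(0.06 * fs)
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, len(x))
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.asarray(sorted(set(refined)), dtype=int)
    # enforce refractory period after refinement
    if len(refined) > 1:
        keep = [0]
        for i in range(1, len(refined)):
            if refined[i] - refined[keep[-1]] >= dist:
                keep.append(i)
            elif x[refined[i]] > x[refined[keep[-1]]]:
                keep[-1] = i
        refined = refined[keep]
    return refined


def _delineate_ppg(ppg: Channel, vpg: Channel, apg: Channel) -> list[PulseFiducials]:
    x, v, a = ppg.samples, vpg.samples, apg.samples
    fs = ppg.fs
    up, _ = find_peaks(v, distance=max(int(0.25 * fs), 1))
    if len(up) == 0:
        return []
    up = up[v[up] > 0.25 * np.percentile(v[up], 90)]
    pulses: list[PulseFiducials] = []
    onsets = []
    for u in up:
        lo = max(u - int(0.3 * fs), 0)
        onsets.append(lo + int(np.argmin(x[lo:u + 1])))
    onsets = np.asarray(sorted(set(onsets)), dtype=int)
    for i, on in enumerate(onsets[:-1]):
        off = onsets[i + 1]
        if off - on < max(int(0.2 * fs), 2):
            continue
        seg = x[on:off]
        sys_i = on + int(np.argmax(seg))
        if sys_i <= on or sys_i >= off:
            continue
        d = off - on
        w0, w1 = on + int(0.40 * d), on + int(0.70 * d)
        notch = dia = None
        if w1 > w0 > sys_i:
            aw = a[w0:w1]
            a_scale = np.abs(a[on:off]).max()
            crossings = np.flatnonzero((aw[:-1] < 0) & (aw[1:] >= 0))
            # a genuine notch needs a real deceleration dip before the
            # zero crossing, not just filter ripple around zero
            if len(crossings) and aw[: crossings[0] + 1].min() < -0.02 * a_scale:
                notch = w0 + int(crossings[0]) + 1
            else:
                vw = v[w0:w1]
                dv = np.diff(vw)
                minima = np.flatnonzero((dv[:-1] < 0) & (dv[1:] >= 0)) + 1
                # fallback only when the deceleration is a genuine local feature
                if len(minima) and vw[minima[0]] < -0.05 * np.abs(v[on:off]).max():
                    notch = w0 + int(minima[0])
            if notch is not None and notch < off - 2:
                tail = x[notch:off]
                dt_ = np.diff(tail)
                tail_peaks = np.flatnonzero((dt_[:-1] > 0) & (dt_[1:] <= 0)) + 1
                if len(tail_peaks):
                    dia = notch + int(tail_peaks[0])
        pulses.append(PulseFiducials(onset=int(on), systolic=int(sys_i),
                                     offset=int(off), notch=notch, diastolic=dia))
    return pulses


def _delineate_resp(resp: Channel):
    x = resp.samples - resp.samples.mean()
    fs = resp.fs
    sm = uniform_filter1d(x, size=max(int(0.5 * fs), 1), mode="nearest")
    crossings = np.flatnonzero(np.diff(np.signbit(sm)))
    dist = max(int(1.0 * fs), 1)
    peaks, _ = find_peaks(sm, distance=dist, prominence=0.2 * np.std(sm))
    troughs, _ = find_peaks(-sm, distance=dist, prominence=0.2 * np.std(sm))
    return peaks.astype(int), troughs.astype(int), crossings.astype(int)


def delineate(record: WaveformRecord, derived: dict[str, Channel] | None = None,
              rpeaks: np.ndarray | None = None) -> FiducialSet:
    """Detect all fiducial points of a denoised record.

    Precomputed R peaks may be passed to avoid re-detection.
    """
    fid = FiducialSet()
    if rpeaks is not None:
        fid.r_peaks = np.asarray(rpeaks, dtype=int)
    elif "ecg" in record:
        fid.r_peaks = detect_r_peaks(record["ecg"])
    if "ppg" in record and derived and "vpg" in derived and "apg" in derived:
        fid.ppg_pulses = _delineate_ppg(record["ppg"], derived["vpg"], derived["apg"])
    if "resp" in record:
        fid.resp_peaks, fid.resp_troughs, fid.resp_transitions = _delineate_resp(record["resp"])
    return fid
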