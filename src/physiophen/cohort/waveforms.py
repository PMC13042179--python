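"""Synthetic ECG / PPG / respiratory waveform channels.

Each synthesizer turns an RR-interval sequence (plus shape parameters)
into a uniformly sampled channel.  The goal is not biophysical realism
but controllable morphology: every landmark the delineator must find
(R peaks, pulse onsets/systolic peaks/dicrotic notches, respiratory
extrema) is planted at a known location so extraction can be validated
against ground truth.
"""

from __future__ import annotations

import numpy as np

from ..types import Channel
from .archetypes import PPGMorphology

__all__ = ["synthesize_ecg", "synthesize_ppg", "synthesize_resp", "beat_times_s"]

# PQRST as a Gaussian sum: (offset ms, amplitude, sigma ms)
_ECG_WAVES = (
    (-180.0, 0.12, 30.0),   # P
    (-22.0, -0.15, 9.0),    # Q
    (0.0, 1.00, 11.0),      # R
    (25.0, -0.22, 9.0),     # S
    (230.0, 0.32, 55.0),    # T
)


def beat_times_s(rr_ms: np.ndarray) -> np.ndarray:
    """Beat (R-peak) times implied by an RR sequence; beat k at cumsum(rr)[k]."""
    return np.cumsum(np.asarray(rr_ms, dtype=float)) / 1000.0


def _add_windows(signal: np.ndarray, starts: np.ndarray, values: np.ndarray) -> None:
    """Scatter-add per-beat windows (n_beats, W) into the signal."""
    n = len(signal)
    w = values.shape[1]
    idx = starts[:, None] + np.arange(w)[None, :]
    ok = (idx >= 0) & (idx < n)
    np.add.at(signal, idx[ok], values[ok])


def synthesize_ecg(
    rr_ms: np.ndarray,
    fs: float,
    resp_phase: np.ndarray | None = None,
    seed: int = 0,
    *,
    modulation_depth: float = 0.1,
    snr_db: float | None = None,
    wander_amp: float = 0.0,
    duration_s: float | None = None,
) -> Channel:
    """Synthesize a single-lead ECG from an RR sequence.

    One PQRST Gaussian-sum template is placed per beat at the cumulative
    RR times.  The R amplitude is modulated sinusoidally by the
    respiratory phase (``1 + depth*sin(phase)``), which is what
    ECG-derived respiration recovers downstream.  Optional additive
    baseline wander (<0.3 Hz) and white noise at a configurable SNR.

    ``fs`` must be >= 100 Hz; lower rates undersample the QRS complex.
    """
    if fs < 100:
        raise ValueError("fs below Nyquist for QRS content (need >= 100 Hz)")
    rr_ms = np.asarray(rr_ms, dtype=float)
    t_beats = beat_times_s(rr_ms)
    if duration_s is None:
        duration_s = float(rr_ms.sum() / 1000.0 + 0.5)
    n = int(round(duration_s * fs))
    sig = np.zeros(n)
    rng = np.random.default_rng(seed)

    amps = np.ones(len(t_beats))
    if resp_phase is not None and modulation_depth > 0:
        beat_idx = np.clip((t_beats * fs).astype(int), 0, len(resp_phase) - 1)
        amps = 1.0 + modulation_depth * np.sin(resp_phase[beat_idx])

    w = int(round(0.7 * fs)) + 1
    starts = np.round((t_beats - 0.3) * fs).astype(int)
    t_rel = (starts[:, None] + np.arange(w)[None, :]) / fs - t_beats[:, None]  # s
    tmpl = np.zeros_like(t_rel)
    for off_ms, amp, sig_ms in _ECG_WAVES:
        tmpl += amp * np.exp(-0.5 * ((t_rel - off_ms / 1000.0) / (sig_ms / 1000.0)) ** 2)
    tmpl *= amps[:, None]
    _add_windows(sig, starts, tmpl)

    t = np.arange(n) / fs
    if wander_amp > 0:
        sig += wander_amp * np.sin(2 * np.pi * 0.18 * t + rng.uniform(0, 2 * np.pi))
        sig += 0.5 * wander_amp * np.sin(2 * np.pi * 0.28 * t + rng.uniform(0, 2 * np.pi))
    if snr_db is not None and np.isfinite(snr_db):
        p_sig = np.var(sig)
        sig += rng.normal(0.0, np.sqrt(p_sig * 10 ** (-snr_db / 10.0)), size=n)
    return Channel(sig, fs=fs, units="mV")


def synthesize_ppg(
    rr_ms: np.ndarray,
    morph: PPGMorphology,
    fs: float,
    seed: int = 0,
    *,
    snr_db: float | None = None,
    wander_amp: float = 0.0,
    duration_s: float | None = None,
) -> Channel:
    """Synthesize a PPG channel with one pulse per beat.

    Each pulse is delayed from its beat time by the pulse-arrival delay
    and built from a systolic Gaussian wave plus a dicrotic (reflected)
    Gaussian scaled by the notch prominence; prominence 0 yields a pulse
    with no dicrotic notch at all.  Per-beat pulsatile (AC) amplitudes
    are drawn from a skew-controllable distribution (standardised gamma)
    whose sample skewness approaches ``morph.ac_skew`` in expectation.
    """
    if fs < 25:
        raise ValueError("fs must be >= 25 Hz for PPG synthesis")
    if not (0.0 <= morph.notch_prominence < 1.0):
        raise ValueError("notch prominence must lie in [0, 1)")
    rr_ms = np.asarray(rr_ms, dtype=float)
    t_beats = beat_times_s(rr_ms)
    if duration_s is None:
        duration_s = float(rr_ms.sum() / 1000.0 + 1.0)
    n = int(round(duration_s * fs))
    sig = np.zeros(n)
    rng = np.random.default_rng(seed)

    nb = len(rr_ms)
    amps = _skewed_amplitudes(rng, nb, morph.ac_mean, morph.ac_sd, morph.ac_skew)
    # pulse k spans from its onset to the next onset
    durs = np.empty(nb)
    durs[:-1] = rr_ms[1:] / 1000.0
    durs[-1] = rr_ms[-1] / 1000.0
    onsets = t_beats + morph.pat_ms / 1000.0

    for k in range(nb):
        d = durs[k]
        t_on = onsets[k]
        i0 = int(np.ceil(t_on * fs))
        win = 2.5 * d
        i1 = int(np.ceil((t_on + win) * fs))
        i0c, i1c = max(i0, 0), min(i1, n)
        if i1c <= i0c:
            continue
        t = np.arange(i0c, i1c) / fs - t_on
        tp = morph.rise_frac * d
        # raised-cosine systolic upstroke (exactly 0 at the foot), then an
        # exponential diastolic runoff that keeps decaying into the next
        # foot, so the onset stays the local minimum of the composite
        # signal; the decay is shifted to end exactly at zero so window
        # truncation leaves no step artifact
        tau = 0.30 * d
        end = np.exp(-(win - tp) / tau)
        shape = np.where(t < tp,
                         0.5 * (1.0 - np.cos(np.pi * np.clip(t, 0, tp) / tp)),
                         np.exp(-(t - tp) / tau))
        shape = np.clip(shape - end, 0.0, None) / (1.0 - end)
        if morph.notch_prominence > 0:
            td, sd = 0.50 * d, 0.07 * d
            shape = shape + (0.35 * morph.notch_prominence
                             * np.exp(-0.5 * ((t - td) / sd) ** 2))
        sig[i0c:i1c] += amps[k] * shape

    sig += 1.0  # DC perfusion baseline
    t_all = np.arange(n) / fs
    if wander_amp > 0:
        sig += wander_amp * np.sin(2 * np.pi * 0.12 * t_all + rng.uniform(0, 2 * np.pi))
    if snr_db is not None and np.isfinite(snr_db):
        p_sig = np.var(sig)
        sig += rng.normal(0.0, np.sqrt(p_sig * 10 ** (-snr_db / 10.0)), size=n)
    return Channel(sig, fs=fs, units="a.u.")


def _skewed_amplitudes(rng: np.random.Generator, n: int, mean: float, sd: float,
                       skew: float) -> np.ndarray:
    """AC amplitudes with controllable skewness.

    A gamma variate with shape k has skewness 2/sqrt(k); standardising
    and sign-flipping covers arbitrary negative/positive targets.
    """
    if abs(skew) < 0.05:
        x = rng.normal(0.0, 1.0, size=n)
    else:
        shape = (2.0 / abs(skew)) ** 2
        g = rng.gamma(shape, 1.0, size=n)
        x = np.sign(skew) * (g - shape) / np.sqrt(shape)
    return np.clip(mean + sd * x, 0.02, None)


def synthesize_resp(
    resp_rate: float,
    fs: float,
    duration_s: float,
    seed: int = 0,
    *,
    period_jitter: float = 0.05,
    noise_sd: float = 0.0,
    return_phase: bool = False,
):
    """Synthesize a quasi-sinusoidal respiratory (impedance) channel.

    Cycles start at a trough (end-expiration); each cycle's period is
    jittered multiplicatively, and the instantaneous phase advances
    linearly within a cycle, so the mean cycle rate stays within a few
    percent of ``resp_rate``.  With ``return_phase=True`` the phase
    series (radians) is returned alongside the channel for use as the
    ECG amplitude-modulation input.
    """
    if not (4.0 < resp_rate < 60.0):
        raise ValueError("resp_rate must lie in (4, 60) breaths/min")
    rng = np.random.default_rng(seed)
    t0 = 60.0 / resp_rate
    n = int(round(duration_s * fs))
    periods = []
    total = 0.0
    while total < duration_s + 2 * t0:
        p = t0 * float(np.clip(1.0 + period_jitter * rng.normal(), 0.5, 1.5))
        periods.append(p)
        total += p
    bounds = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(n) / fs
    cyc = np.searchsorted(bounds, t, side="right") - 1
    frac = (t - bounds[cyc]) / np.asarray(periods)[cyc]
    phase = 2 * np.pi * (cyc + frac)
    sig = -np.cos(phase)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=n)
    ch = Channel(sig, fs=fs, units="a.u.")
    if return_phase:
        return ch, phase
    return ch
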