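"""RR-interval (tachogram) generation for synthetic archetypes.

The generative model is additive: a base period set by the mean heart
rate, low-frequency (~0.1 Hz) and high-frequency (~0.25 Hz) sinusoidal
modulation whose amplitudes are calibrated against the archetype's LF/HF
and short-term variability targets, white beat-to-beat jitter, and a
sparse positive "ectopic pause" jump process that produces the long-tail
RR distributions (high SDNN / skewness / MaxNN) seen in arrhythmic
segments.  It is a statistical emulator, not a cardiovascular model.
"""

from __future__ import annotations

import numpy as np

from .archetypes import ArchetypeSpec, RRModelParams, calibrate_rr_model, _LF_HZ, _HF_HZ

__all__ = ["generate_rr_series", "rr_from_params"]

_MIN_RR_MS = 250.0


def rr_from_params(params: RRModelParams, duration_s: float, seed: int) -> np.ndarray:
    """Draw one RR sequence (ms) from calibrated model parameters.

    Beats are generated sequentially (the sinusoidal modulation is a
    function of cumulative time) until the summed intervals cover the
    requested duration.
    """
    rng = np.random.default_rng(seed)
    base = params.base_ms
    # generous upper bound on the number of beats
    n_max = int(np.ceil(duration_s * 1000.0 / _MIN_RR_MS)) + 2
    jit = (rng.normal(0.0, params.jitter_sd, size=n_max)
           if params.jitter_sd > 0 else np.zeros(n_max))
    jumps = np.zeros(n_max)
    if params.jump_prob > 0:
        hit = rng.random(n_max) < params.jump_prob
        jumps[hit] = params.jump_mag * rng.uniform(0.7, 1.3, size=int(hit.sum()))
    phase_lf = rng.uniform(0, 2 * np.pi)
    phase_hf = rng.uniform(0, 2 * np.pi)

    rr = np.empty(n_max)
    t_ms = 0.0
    k = 0
    while t_ms < duration_s * 1000.0 and k < n_max:
        t_s = t_ms / 1000.0
        mod = (params.lf_amp * np.sin(2 * np.pi * _LF_HZ * t_s + phase_lf)
               + params.hf_amp * np.sin(2 * np.pi * _HF_HZ * t_s + phase_hf))
        rr[k] = max(base + mod + jit[k] + jumps[k], _MIN_RR_MS)
        t_ms += rr[k]
        k += 1
    return rr[:k].copy()


def generate_rr_series(archetype: ArchetypeSpec, duration_s: float, seed: int) -> np.ndarray:
    """Generate an RR-interval sequence (ms) for one archetype.

    Parameters
    ----------
    archetype : ArchetypeSpec
        Target signature; calibrated once per archetype and cached.
    duration_s : float
        Length of the segment; must be >= 60 s.  The summed intervals
        always cover the duration.
    seed : int
        Any fixed seed reproduces the sequence bit-identically.
    """
    if duration_s < 60:
        raise ValueError("duration_s must be >= 60 s")
    params = calibrate_rr_model(archetype, warn=False)
    return rr_from_params(params, duration_s, seed)
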