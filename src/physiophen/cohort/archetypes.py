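"""Archetype parameter tables for the synthetic sepsis cohort.

Four physiological archetypes (SP1..SP4) emulate the autonomic/vascular
signatures of the phenotypes the package is designed to recover:

* **SP1** — profoundly reduced beat-to-beat variability with irregular
  (entropy-rich) residual dynamics; near-absent pNN50.
* **SP2** — large apparent HRV magnitude driven by occasional long
  ectopic pauses (strongly right-skewed RR distribution), modest
  short-term variability, strongly negative PPG amplitude skewness.
* **SP3** — the largest HRV magnitude and pauses, higher pNN50, slow
  systolic upstroke (low PPG onset-to-systolic slope), positive PPG
  amplitude skewness.
* **SP4** — dominant parasympathetic (high-frequency) variability with
  the highest pNN50 and the lowest LF/HF ratio; oldest / frailest group.

Outcome probabilities (28-day mortality, septic shock / vasopressor /
ventilation support at days 2, 7 and 28) and covariate-abnormality
prevalences are part of each archetype, so a generated cohort carries
ground-truth labels together with archetype-linked outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import norm

__all__ = ["ArchetypeSpec", "PPGMorphology", "RRModelParams", "DEFAULT_ARCHETYPES",
           "calibrate_rr_model"]


@dataclass(frozen=True)
class PPGMorphology:
    """Shape parameters of the synthetic PPG pulse.

    rise_frac: systolic-peak time as fraction of the cardiac cycle.
    notch_prominence: relative amplitude of the dicrotic (reflected) wave
        in [0, 1); 0 removes the dicrotic notch entirely.
    pat_ms: pulse-arrival delay from the ECG R peak to the pulse onset.
    ac_mean, ac_sd, ac_skew: moments of the per-beat pulsatile (AC)
        amplitude distribution.
    """

    rise_frac: float = 0.18
    notch_prominence: float = 0.35
    pat_ms: float = 220.0
    ac_mean: float = 0.37
    ac_sd: float = 0.05
    ac_skew: float = -0.6


@dataclass(frozen=True)
class ArchetypeSpec:
    """Target signature of one synthetic phenotype archetype."""

    id: str
    hr_mean: float            # beats/min
    sdnn_target: float        # ms, as recovered by the HRV extractor
    rmssd_target: float       # ms
    pnn50_target: float       # percent
    lfhf_target: float        # dimensionless
    rr_skew_target: float     # skewness of the raw RR series
    rr_irregularity: str      # {"low", "mid", "high"}
    ppg_ac_skew_target: float
    ppg_morphology: PPGMorphology
    resp_rate: float          # breaths/min
    mortality_28d: float
    shock_probs: tuple[float, float, float]   # cumulative by day 2/7/28
    vp_probs: tuple[float, float, float]
    mv_probs: tuple[float, float, float]
    covariate_probs: tuple[float, float, float]  # P(SBP<=100), P(RR>=22), P(GCS<15)

    def __post_init__(self) -> None:
        probs = [self.mortality_28d, *self.shock_probs, *self.vp_probs,
                 *self.mv_probs, *self.covariate_probs]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        numeric = (self.hr_mean, self.sdnn_target, self.rmssd_target,
                   self.pnn50_target, self.lfhf_target, self.rr_skew_target,
                   self.ppg_ac_skew_target, self.resp_rate)
        if not all(np.isfinite(v) for v in numeric):
            raise ValueError("archetype targets must be finite")
        if self.sdnn_target < 0 or self.rmssd_target < 0:
            raise ValueError("sdnn_target and rmssd_target must be >= 0")
        if not (0.0 <= self.pnn50_target <= 100.0):
            raise ValueError("pnn50_target must lie in [0, 100]")
        if not (20.0 < self.hr_mean < 250.0):
            raise ValueError("hr_mean must lie in (20, 250) beats/min")
        if self.rr_irregularity not in ("low", "mid", "high"):
            raise ValueError("rr_irregularity must be low, mid or high")
        for seq in (self.shock_probs, self.vp_probs, self.mv_probs):
            if not (seq[0] <= seq[1] <= seq[2]):
                raise ValueError("support probabilities must be monotone in time")


# Default archetype table.  HRV statistic targets (SDNN, RMSSD, pNN50,
# LF/HF, RR skewness, heart rate) and 28-day mortality are the per-group
# medians/rates of a reference ICU sepsis cohort; PPG morphology, respiratory
# rates, support-flag and covariate prevalences are package choices consistent
# with the qualitative group descriptions (see docs/methods.md).
DEFAULT_ARCHETYPES: dict[str, ArchetypeSpec] = {
    "SP1": ArchetypeSpec(
        id="SP1", hr_mean=87.9,
        sdnn_target=9.280,        # reference group median, ms
        rmssd_target=8.879,       # ms
        pnn50_target=0.0,         # percent
        lfhf_target=0.790,
        rr_skew_target=0.107,
        rr_irregularity="high",
        ppg_ac_skew_target=-0.384,
        ppg_morphology=PPGMorphology(rise_frac=0.16, notch_prominence=0.30,
                                     pat_ms=200.0, ac_mean=0.373, ac_sd=0.045,
                                     ac_skew=-0.384),
        resp_rate=19.0,
        mortality_28d=0.2429,
        shock_probs=(0.20, 0.26, 0.30),
        vp_probs=(0.24, 0.30, 0.34),
        mv_probs=(0.30, 0.37, 0.42),
        covariate_probs=(0.40, 0.50, 0.40),
    ),
    "SP2": ArchetypeSpec(
        id="SP2", hr_mean=86.1,
        sdnn_target=184.614,
        rmssd_target=249.684,
        pnn50_target=9.028,
        lfhf_target=0.781,
        rr_skew_target=5.965,
        rr_irregularity="low",
        ppg_ac_skew_target=-1.345,
        ppg_morphology=PPGMorphology(rise_frac=0.13, notch_prominence=0.45,
                                     pat_ms=240.0, ac_mean=0.382, ac_sd=0.040,
                                     ac_skew=-1.345),
        resp_rate=16.0,
        mortality_28d=0.1902,
        shock_probs=(0.14, 0.18, 0.21),
        vp_probs=(0.16, 0.20, 0.23),
        mv_probs=(0.18, 0.22, 0.25),
        covariate_probs=(0.30, 0.35, 0.30),
    ),
    "SP3": ArchetypeSpec(
        id="SP3", hr_mean=78.5,
        sdnn_target=271.662,
        rmssd_target=373.849,
        pnn50_target=25.362,
        lfhf_target=0.781,
        rr_skew_target=3.293,
        rr_irregularity="mid",
        ppg_ac_skew_target=-0.167,
        ppg_morphology=PPGMorphology(rise_frac=0.26, notch_prominence=0.15,
                                     pat_ms=280.0, ac_mean=0.370, ac_sd=0.055,
                                     ac_skew=-0.167),
        resp_rate=23.0,
        mortality_28d=0.2877,
        shock_probs=(0.30, 0.38, 0.44),
        vp_probs=(0.32, 0.40, 0.46),
        mv_probs=(0.34, 0.42, 0.47),
        covariate_probs=(0.55, 0.65, 0.50),
    ),
    "SP4": ArchetypeSpec(
        id="SP4", hr_mean=91.5,
        sdnn_target=219.034,
        rmssd_target=320.049,
        pnn50_target=71.455,
        lfhf_target=0.590,
        rr_skew_target=2.364,
        rr_irregularity="mid",
        ppg_ac_skew_target=-0.386,
        ppg_morphology=PPGMorphology(rise_frac=0.20, notch_prominence=0.25,
                                     pat_ms=230.0, ac_mean=0.336, ac_sd=0.050,
                                     ac_skew=-0.386),
        resp_rate=17.5,
        mortality_28d=0.2652,
        shock_probs=(0.26, 0.33, 0.38),
        vp_probs=(0.28, 0.35, 0.40),
        mv_probs=(0.24, 0.29, 0.33),
        covariate_probs=(0.45, 0.45, 0.45),
    ),
}


@dataclass(frozen=True)
class RRModelParams:
    """Calibrated parameters of the additive RR-interval model."""

    base_ms: float          # mean NN period
    jitter_sd: float        # white beat-to-beat jitter, ms
    lf_amp: float           # ~0.1 Hz sinusoidal modulation amplitude, ms
    hf_amp: float           # ~0.25 Hz modulation amplitude, ms
    jump_prob: float        # per-beat probability of an ectopic pause
    jump_mag: float         # mean added pause length, ms
    warnings: tuple[str, ...] = field(default=())


_LF_HZ = 0.1
_HF_HZ = 0.25
# beat-to-beat increment factor of a sinusoid of amplitude a sampled at the
# beat period T: delta ~ 2*a*sin(pi*f*T)
def _sin_diff_factor(f_hz: float, period_ms: float) -> float:
    return 2.0 * abs(np.sin(np.pi * f_hz * period_ms / 1000.0))


@lru_cache(maxsize=64)
def _calibrate_cached(key: tuple) -> RRModelParams:
    (hr, sdnn_t, pnn50_t, lfhf, skew_t, irregularity) = key
    msgs: list[str] = []
    base = 60000.0 / hr
    # irregularity controls how much of the short-term variance is white
    # (unstructured) versus sinusoidal (structured)
    white_share = {"low": 0.45, "mid": 0.65, "high": 0.9}[irregularity]

    # -- short-term variability from the pNN50 target ------------------
    # successive differences are ~N(0, sd_d); pNN50 = 2*(1-Phi(50/sd_d))
    if pnn50_t > 0.5:
        sd_d = 50.0 / norm.ppf(1.0 - pnn50_t / 200.0)
    else:
        sd_d = 0.0

    # fixed-point: split short-term variance between jitter and sinusoids
    jitter = sdnn_t * np.sqrt(white_share)
    lf_amp = hf_amp = 0.0
    lf_share = lfhf / (1.0 + lfhf)
    c_lf = _sin_diff_factor(_LF_HZ, base)
    c_hf = _sin_diff_factor(_HF_HZ, base)
    for _ in range(6):
        if sd_d > 0.0:
            # allocate the successive-difference variance
            var_d = sd_d ** 2
            var_d_white = var_d * white_share
            jitter = np.sqrt(var_d_white / 2.0)
            var_d_sin = var_d - var_d_white
            # sinusoid diff variances: (c*a)^2/2 each; split LF/HF by target
            hf_var = var_d_sin / (1.0 + lfhf * (c_lf / c_hf) ** 2)
            lf_var = var_d_sin - hf_var
            hf_amp = np.sqrt(2.0 * hf_var) / c_hf
            lf_amp = np.sqrt(2.0 * lf_var) / max(c_lf, 1e-6)
        else:
            # variance budget comes from the SDNN target instead
            var_tot = sdnn_t ** 2
            jitter = np.sqrt(var_tot * white_share)
            var_sin = var_tot * (1.0 - white_share)
            lf_amp = np.sqrt(2.0 * var_sin * lf_share)
            hf_amp = np.sqrt(2.0 * var_sin * (1.0 - lf_share))
            break

    # achievable SDNN from the continuous components alone
    var_cont = jitter ** 2 + 0.5 * lf_amp ** 2 + 0.5 * hf_amp ** 2
    sdnn_cont = np.sqrt(var_cont)

    # -- ectopic pauses from the skewness target ------------------------
    jump_prob = 0.0
    jump_mag = 0.0
    var_needed = max(sdnn_t ** 2 - var_cont, 0.0)
    if skew_t > 0.5 or var_needed > (0.5 * sdnn_t) ** 2:
        # rare positive pauses: var = p*M^2, third moment ~ p*M^3
        v_j = max(var_needed, (0.2 * max(sdnn_t, 1.0)) ** 2)
        sd_raw = np.sqrt(var_cont + v_j)
        jump_mag = float(np.clip(max(skew_t, 0.5) * sd_raw ** 3 / v_j, 250.0, 3500.0))
        jump_prob = float(np.clip(v_j / jump_mag ** 2, 0.0, 0.15))
    if var_needed > 0 and sdnn_cont < 0.75 * sdnn_t:
        msgs.append(
            f"SDNN target {sdnn_t:.1f} ms is not reachable by normal-to-normal "
            f"variability consistent with pNN50={pnn50_t:.1f}%; continuous "
            f"components deliver ~{sdnn_cont:.1f} ms and the remainder is "
            "carried by ectopic pauses (excluded by NN artifact filtering)."
        )
    return RRModelParams(base_ms=base, jitter_sd=float(jitter),
                         lf_amp=float(lf_amp), hf_amp=float(hf_amp),
                         jump_prob=jump_prob, jump_mag=jump_mag,
                         warnings=tuple(msgs))


def calibrate_rr_model(spec: ArchetypeSpec, warn: bool = True) -> RRModelParams:
    """Solve the RR-model parameters that approach an archetype's targets.

    Matching is in expectation, not exact: the white-jitter SD is solved
    from the pNN50 target (Gaussian successive differences), sinusoid
    amplitudes from the LF/HF target and the remaining short-term variance,
    and the pause process from the skewness/SDNN residual.  Infeasible
    combinations (large SDNN with small pNN50 under NN artifact filtering)
    fall back to a best-effort solution with a warning.
    """
    targets = (spec.hr_mean, spec.sdnn_target, spec.pnn50_target,
               spec.lfhf_target, spec.rr_skew_target)
    if not all(np.isfinite(t) for t in targets):
        raise ValueError("archetype targets must be finite")
    params = _calibrate_cached(targets + (spec.rr_irregularity,))
    if warn:
        for m in params.warnings:
            warnings.warn(m, stacklevel=2)
    return params
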