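"""Cohort assembly: waveforms + covariates + outcomes with ground truth.

`generate_cohort` draws archetype memberships from the configured
mixture, synthesizes each patient's three-channel waveform record, and
samples covariates (SBP / respiratory rate / GCS) and outcomes (28-day
death or censoring; septic-shock, vasopressor and ventilation support
flags at days 2/7/28) from the archetype's probabilities.  Support flags
are sampled as a first-activation day, so a flag set at day 2 is set at
days 7 and 28 (monotone exposure).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from ..types import Channel, WaveformRecord
from .archetypes import ArchetypeSpec, DEFAULT_ARCHETYPES, calibrate_rr_model
from .rr import rr_from_params
from .waveforms import synthesize_ecg, synthesize_ppg, synthesize_resp

__all__ = ["CohortConfig", "SyntheticPatient", "CohortBundle",
           "generate_cohort", "save_cohort", "load_cohort"]

DEFAULT_MIXTURE = (0.267, 0.332, 0.276, 0.125)


@dataclass
class CohortConfig:
    n_patients: int = 400
    mixture_weights: tuple = DEFAULT_MIXTURE
    duration_s: float = 300.0
    fs: dict = field(default_factory=lambda: {"ecg": 250.0, "ppg": 125.0, "resp": 62.5})
    seed: int = 0
    archetypes: dict = field(default_factory=lambda: dict(DEFAULT_ARCHETYPES))
    ecg_snr_db: float = 25.0
    ppg_snr_db: float = 30.0
    resp_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, dtype=float)
        if len(w) != len(self.archetypes):
            raise ValueError("one mixture weight per archetype required")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("mixture weights must sum to 1")
        max_hr = max(a.hr_mean for a in self.archetypes.values())
        if self.duration_s <= 10 * 60.0 / max_hr:
            raise ValueError("duration_s must cover at least ~10 heart periods")


@dataclass
class SyntheticPatient:
    patient_id: str
    archetype_id: str
    waveforms: WaveformRecord
    covariates: tuple[float, float, int]          # (SBP mmHg, RR breaths/min, GCS)
    outcome: dict


@dataclass
class CohortBundle:
    patients: list[SyntheticPatient]
    metadata: pd.DataFrame                        # one row per patient incl. ground truth
    config: CohortConfig


def _sample_covariates(rng: np.random.Generator, spec: ArchetypeSpec):
    p_sbp, p_rr, p_gcs = spec.covariate_probs
    sbp = round(float(rng.normal(100.0 - 15.0 * norm.ppf(p_sbp), 15.0)), 1)
    rr = round(float(rng.normal(22.0 - 4.0 * norm.ppf(1.0 - p_rr), 4.0)), 1)
    rr = max(rr, 6.0)
    gcs = 15 if rng.random() >= p_gcs else int(rng.integers(8, 15))
    return sbp, rr, gcs


def _sample_outcome(rng: np.random.Generator, spec: ArchetypeSpec) -> dict:
    out: dict = {}
    p = spec.mortality_28d
    if p <= 0:
        t, ev = 28.0, 0
    else:
        lam = -np.log(1.0 - p) / 28.0  # exponential rate matching P(death<=28)=p
        t = float(rng.exponential(1.0 / lam))
        ev = int(t <= 28.0)
        t = min(t, 28.0) if ev else 28.0
        t = max(t, 1e-3)
    out["death_time"] = round(t, 3)
    out["death_event"] = ev
    for name, probs in (("ss", spec.shock_probs), ("vp", spec.vp_probs),
                        ("mv", spec.mv_probs)):
        u = rng.random()
        first = 2 if u < probs[0] else 7 if u < probs[1] else 28 if u < probs[2] else None
        for day in (2, 7, 28):
            out[f"{name}{day}"] = int(first is not None and first <= day)
    return out


def generate_patient(spec: ArchetypeSpec, config: CohortConfig,
                     seed: int, patient_id: str) -> SyntheticPatient:
    """Synthesize one patient: RR dynamics, three channels, covariates, outcome."""
    ss = np.random.SeedSequence(seed)
    s_rr, s_resp, s_ecg, s_ppg, s_cov = [int(c.generate_state(1)[0] % (2 ** 31))
                                         for c in ss.spawn(5)]
    params = calibrate_rr_model(spec, warn=False)
    rr = rr_from_params(params, config.duration_s, s_rr)
    resp, phase = synthesize_resp(spec.resp_rate, config.fs["resp"], config.duration_s,
                                  s_resp, noise_sd=config.resp_noise_sd,
                                  return_phase=True)
    # respiratory phase resampled onto the ECG time base for R-amplitude modulation
    n_ecg = int(round(config.duration_s * config.fs["ecg"]))
    phase_ecg = np.interp(np.arange(n_ecg) / config.fs["ecg"],
                          np.arange(len(phase)) / config.fs["resp"], phase)
    ecg = synthesize_ecg(rr, config.fs["ecg"], resp_phase=phase_ecg, seed=s_ecg,
                         snr_db=config.ecg_snr_db, wander_amp=0.05,
                         duration_s=config.duration_s)
    ppg = synthesize_ppg(rr, spec.ppg_morphology, config.fs["ppg"], seed=s_ppg,
                         snr_db=config.ppg_snr_db, wander_amp=0.02,
                         duration_s=config.duration_s)
    rng = np.random.default_rng(s_cov)
    cov = _sample_covariates(rng, spec)
    outcome = _sample_outcome(rng, spec)
    record = WaveformRecord(channels={"ecg": ecg, "ppg": ppg, "resp": resp},
                            patient_id=patient_id,
                            meta={"archetype": spec.id})
    return SyntheticPatient(patient_id, spec.id, record, cov, outcome)


def generate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate a full synthetic cohort with ground-truth archetype labels."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    names = list(config.archetypes)
    if config.n_patients == 0:
        meta = pd.DataFrame(columns=["patient_id", "archetype"])
        return CohortBundle([], meta, config)
    members = rng.choice(len(names), size=config.n_patients,
                         p=np.asarray(config.mixture_weights, dtype=float))
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_patients) % (2 ** 31)
    patients, rows = [], []
    for i in range(config.n_patients):
        spec = config.archetypes[names[members[i]]]
        pid = f"P{i:04d}"
        pat = generate_patient(spec, config, int(seeds[i]), pid)
        patients.append(pat)
        sbp, rr_cov, gcs = pat.covariates
        rows.append({"patient_id": pid, "archetype": spec.id,
                     "sbp": sbp, "resp_rate": rr_cov, "gcs": gcs, **pat.outcome})
    meta = pd.DataFrame(rows)
    return CohortBundle(patients, meta, config)


# ---------------------------------------------------------------------------
# On-disk container: metadata.csv + per-patient per-channel CSV with a JSON
# sidecar carrying sampling rates and units.
# ---------------------------------------------------------------------------

def save_cohort(bundle: CohortBundle, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "waveforms").mkdir(parents=True, exist_ok=True)
    bundle.metadata.to_csv(out / "metadata.csv", index=False)
    for pat in bundle.patients:
        sidecar = {}
        for name, ch in pat.waveforms.channels.items():
            fn = out / "waveforms" / f"{pat.patient_id}_{name}.csv"
            np.savetxt(fn, ch.samples, fmt="%.6g")
            sidecar[name] = {"fs": ch.fs, "units": ch.units}
        with open(out / "waveforms" / f"{pat.patient_id}.json", "w") as fh:
            json.dump(sidecar, fh)
    return out


def load_cohort(in_dir: str | Path) -> tuple[list[WaveformRecord], pd.DataFrame]:
    src = Path(in_dir)
    meta = pd.read_csv(src / "metadata.csv")
    records = []
    for pid in meta["patient_id"]:
        with open(src / "waveforms" / f"{pid}.json") as fh:
            sidecar = json.load(fh)
        channels = {}
        for name, info in sidecar.items():
            samples = np.loadtxt(src / "waveforms" / f"{pid}_{name}.csv")
            channels[name] = Channel(samples, fs=info["fs"], units=info["units"])
        records.append(WaveformRecord(channels=channels, patient_id=pid))
    return records, meta
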