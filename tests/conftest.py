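"""Shared fixtures.

The heavy end-to-end discovery runs (10 seeds of a 400-patient cohort
through extraction, cleaning, transformer embedding, UMAP and consensus
clustering) are computed once per session and shared by every test that
needs them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from physiophen.cohort import (CohortConfig, DEFAULT_ARCHETYPES, PPGMorphology,
                               generate_cohort, synthesize_ecg, synthesize_ppg,
                               synthesize_resp)
from physiophen.types import WaveformRecord

E2E_SEEDS = tuple(range(10))
# representation-training budget for the end-to-end runs (problem-size
# scaling documented in docs/methods.md)
E2E_FT_KWARGS = {"max_epochs": 3, "max_train_rows": 96, "val_fraction": 0.08}


@pytest.fixture(scope="session")
def e2e_runs():
    """Full-pipeline discovery on ten independently seeded 400-patient cohorts."""
    from sklearn.metrics import adjusted_rand_score

    from physiophen.workflow import DiscoveryConfig, run_discovery

    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in E2E_SEEDS:
            bundle = generate_cohort(CohortConfig(n_patients=400, seed=seed))
            cfg = DiscoveryConfig(seed=seed, method="ft_t",
                                  method_kwargs=dict(E2E_FT_KWARGS))
            res = run_discovery(bundle, cfg)
            truth = bundle.metadata.set_index("patient_id") \
                .loc[res.features.index, "archetype"]
            results.append({
                "seed": seed,
                "k_selected": res.clusterer.k_selected_,
                "ari": float(adjusted_rand_score(truth, res.labels)),
                "silhouette": res.metrics.get("silhouette", np.nan),
            })
    return results


@pytest.fixture(scope="session")
def clean_record():
    """A noise-free three-channel record with fully known ground truth:
    60 beats at exactly 1000 ms, pulse arrival 200 ms, 15 breaths/min."""
    rr = np.full(60, 1000.0)
    morph = PPGMorphology(pat_ms=200.0, ac_skew=0.0, notch_prominence=0.35)
    resp, phase = synthesize_resp(15.0, 62.5, 61.0, seed=0, period_jitter=0.0,
                                  return_phase=True)
    n_ecg = int(61.0 * 250.0)
    phase_ecg = np.interp(np.arange(n_ecg) / 250.0,
                          np.arange(len(phase)) / 62.5, phase)
    ecg = synthesize_ecg(rr, 250.0, resp_phase=phase_ecg, duration_s=61.0)
    ppg = synthesize_ppg(rr, morph, 125.0, duration_s=61.0)
    return WaveformRecord(channels={"ecg": ecg, "ppg": ppg, "resp": resp},
                          patient_id="CLEAN")


@pytest.fixture(scope="session")
def sp2_patient():
    """One default-noise SP2 archetype patient (5-minute record)."""
    from physiophen.cohort import generate_patient

    cfg = CohortConfig(n_patients=1, seed=0)
    return generate_patient(DEFAULT_ARCHETYPES["SP2"], cfg, seed=42,
                            patient_id="SP2-0")
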