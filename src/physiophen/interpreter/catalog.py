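"""Physiomarker catalog: the manifest of per-patient feature definitions.

The default manifest enumerates 192 unique physiomarkers across five
domain groups: scalar HRV indices and PPG interbeat eigenvalues are
window-level scalars; every time-varying marker (per-beat, per-pulse or
per-cycle series) contributes its five retained summary statistics.
The manifest is data-driven — pipeline code iterates over it rather
than hard-coding names — and the total is asserted in tests.
"""

from __future__ import annotations

import pandas as pd

from .hrv import HRV_NAMES
from .ppg import PPG_SERIES_NAMES, N_EIGENVALUES
from .resp import RESP_SERIES_NAMES
from .summarize import RETAINED_STATS

__all__ = ["build_catalog", "CARDIAC_SERIES_NAMES", "COUPLING_SERIES_NAMES"]

CARDIAC_SERIES_NAMES = ["T_rr_ms", "HR_bpm", "R_amp"]
COUPLING_SERIES_NAMES = ["PAT_ms", "PAT_peak_ms"]

_GROUP_PREFIX = {
    "hrv": "HRV",
    "cardiac_electrical": "ECG",
    "ppg_morphology_timing": "PPG",
    "respiratory": "RESP",
    "ecg_ppg_coupling": "ECGPPG",
}

_SERIES_UNITS = {
    "T_rr_ms": "ms", "HR_bpm": "bpm", "R_amp": "mV",
    "A_AC": "a.u.", "A_DC": "a.u.", "AUCos": "a.u.*s", "AUCso": "a.u.*s",
    "AUC_total": "a.u.*s", "AUCos_nu": "nu", "AUCso_nu": "nu",
    "PW_25": "ms", "PW_50": "ms", "PW_75": "ms", "T_sys": "ms", "T_dia": "ms",
    "T_pulse": "ms", "sys_dia_ratio": "ratio", "mean_slope_os": "a.u./s",
    "mean_slope_so": "a.u./s", "notch_time_frac": "fraction",
    "notch_rel_amp": "fraction", "VPG_max": "a.u./s", "APG_max": "a.u./s^2",
    "reflection_index": "fraction",
    "breath_period_s": "s", "insp_dur_s": "s", "exp_dur_s": "s",
    "ie_ratio": "ratio", "resp_rate_inst": "breaths/min", "resp_width": "a.u.",
    "PAT_ms": "ms", "PAT_peak_ms": "ms",
}

_HRV_UNITS = {
    "MeanNN": "ms", "MedianNN": "ms", "SDNN": "ms", "RMSSD": "ms", "SDSD": "ms",
    "pNN50": "%", "pNN20": "%", "MinNN": "ms", "MaxNN": "ms", "CVNN": "ratio",
    "IQRNN": "ms", "VLF": "nu", "LF": "nu", "HF": "nu", "TP": "nu",
    "LFHF": "ratio", "LFnu": "nu", "HFnu": "nu", "ShanEn": "nats",
    "SampEn": "nats", "FuzzyEn": "nats", "CMSEn": "nats", "CD": "dimensionless",
    "KFD": "dimensionless", "SD1": "ms", "SD2": "ms", "SD1SD2": "ratio",
}


def build_catalog() -> pd.DataFrame:
    """Build the default physiomarker manifest.

    Columns: ``name`` (feature-row column name), ``group``, ``kind``
    (scalar | time_varying), ``source`` (underlying marker), ``statistic``
    (retained summary statistic, empty for scalars) and ``units``.
    """
    rows = []
    for name in HRV_NAMES:
        rows.append(dict(name=f"HRV_{name}", group="hrv", kind="scalar",
                         source=name, statistic="", units=_HRV_UNITS[name]))
    for i in range(1, N_EIGENVALUES + 1):
        rows.append(dict(name=f"PPG_ppgInterbeat_eigval{i}",
                         group="ppg_morphology_timing", kind="scalar",
                         source=f"interbeat_eigval{i}", statistic="",
                         units="a.u.^2"))
    groups = [
        ("cardiac_electrical", CARDIAC_SERIES_NAMES),
        ("ppg_morphology_timing", PPG_SERIES_NAMES),
        ("respiratory", RESP_SERIES_NAMES),
        ("ecg_ppg_coupling", COUPLING_SERIES_NAMES),
    ]
    for group, names in groups:
        prefix = _GROUP_PREFIX[group]
        for src in names:
            for stat in RETAINED_STATS:
                rows.append(dict(name=f"{prefix}_{src}_{stat}", group=group,
                                 kind="time_varying", source=src, statistic=stat,
                                 units=_SERIES_UNITS[src]))
    cat = pd.DataFrame(rows)
    assert cat["name"].is_unique
    return cat
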