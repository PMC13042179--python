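"""The full stage 1-6 chain: record -> named physiomarker feature row.

`extract_features` chains preprocessing, denoising, signal derivation,
delineation, marker computation and summarization for one record;
:class:`WaveformFeatureExtractor` applies it across a cohort and returns
a patients x features DataFrame aligned with the default catalog.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ..types import WaveformRecord
from .catalog import (build_catalog, CARDIAC_SERIES_NAMES, COUPLING_SERIES_NAMES,
                      _GROUP_PREFIX)
from .delineate import delineate, MIN_BEATS
from .denoise import DenoiseConfig, denoise
from .derive import derive_signals
from .hrv import compute_hrv
from .ppg import compute_ppg_markers, PPG_SERIES_NAMES, N_EIGENVALUES
from .preprocess import QCConfig, preprocess
from .resp import compute_resp_markers, RESP_SERIES_NAMES
from .summarize import summarize, RETAINED_STATS

__all__ = ["extract_features", "extract_all", "WaveformFeatureExtractor"]


def _empty_row(catalog: pd.DataFrame) -> pd.Series:
    return pd.Series(np.nan, index=catalog["name"].tolist(), dtype=float)


def _fill_series_stats(row: pd.Series, prefix: str, name: str, series: np.ndarray) -> None:
    stats = summarize(series) if len(series) else {s: np.nan for s in RETAINED_STATS}
    for stat in RETAINED_STATS:
        row[f"{prefix}_{name}_{stat}"] = stats[stat]


def extract_features(
    record: WaveformRecord,
    qc: QCConfig | None = None,
    denoise_config: DenoiseConfig | None = None,
    catalog: pd.DataFrame | None = None,
) -> pd.Series:
    """One patient's physiomarker row (NaN where markers are unavailable)."""
    catalog = catalog if catalog is not None else build_catalog()
    row = _empty_row(catalog)
    clean, report = preprocess(record, qc)
    if report.low_quality:
        row.attrs["quality"] = "low"
        return row
    clean = denoise(clean, denoise_config)
    rpeaks = np.array([], dtype=int)
    if "ecg" in clean:
        from .delineate import detect_r_peaks
        rpeaks = detect_r_peaks(clean["ecg"])
    derived = derive_signals(clean, rpeaks)
    fid = delineate(clean, derived, rpeaks=rpeaks)

    if "ecg" in clean and len(rpeaks) >= MIN_BEATS:
        fs = clean["ecg"].fs
        rr = np.diff(rpeaks) / fs * 1000.0
        for k, v in compute_hrv(rr).items():
            row[f"HRV_{k}"] = v
        _fill_series_stats(row, "ECG", "T_rr_ms", rr)
        _fill_series_stats(row, "ECG", "HR_bpm", 60000.0 / rr)
        _fill_series_stats(row, "ECG", "R_amp", clean["ecg"].samples[rpeaks])

    if "ppg" in clean and fid is not None:
        ecg_fs = clean["ecg"].fs if "ecg" in clean else None
        series, eig = compute_ppg_markers(
            clean["ppg"], fid, rpeaks, ecg_fs,
            vpg=derived["vpg"].samples if "vpg" in derived else None,
            apg=derived["apg"].samples if "apg" in derived else None)
        for name in PPG_SERIES_NAMES:
            _fill_series_stats(row, "PPG", name, series.get(name, np.array([])))
        for name in COUPLING_SERIES_NAMES:
            _fill_series_stats(row, "ECGPPG", name, series.get(name, np.array([])))
        for i in range(N_EIGENVALUES):
            row[f"PPG_ppgInterbeat_eigval{i + 1}"] = eig[i]

    if "resp" in clean and fid is not None:
        rseries = compute_resp_markers(clean["resp"], fid)
        for name in RESP_SERIES_NAMES:
            _fill_series_stats(row, "RESP", name, rseries.get(name, np.array([])))
    return row


def extract_all(record: WaveformRecord, **kwargs) -> tuple[pd.Series, pd.DataFrame]:
    """Feature row plus the catalog manifest it is aligned to."""
    catalog = kwargs.pop("catalog", None)
    catalog = catalog if catalog is not None else build_catalog()
    return extract_features(record, catalog=catalog, **kwargs), catalog


class WaveformFeatureExtractor(BaseEstimator, TransformerMixin):
    """Cohort-level physiomarker extraction as a sklearn transformer.

    ``transform`` accepts a list of :class:`WaveformRecord` and returns a
    DataFrame with one row per record, columns ordered by the catalog.
    Stateless (``fit`` is a no-op) but follows the transformer protocol so
    it composes with sklearn pipelines.
    """

    def __init__(self, qc: QCConfig | None = None,
                 denoise_config: DenoiseConfig | None = None):
        self.qc = qc
        self.denoise_config = denoise_config

    def fit(self, X, y=None):
        self.catalog_ = build_catalog()
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "catalog_"):
            self.fit(X)
        rows = []
        index = []
        for rec in X:
            rows.append(extract_features(rec, qc=self.qc,
                                         denoise_config=self.denoise_config,
                                         catalog=self.catalog_))
            index.append(rec.patient_id)
        return pd.DataFrame(rows, index=index)
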