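"""Feature cleaning pipeline: raw physiomarker rows -> standardized matrix.

Steps run in a fixed order — extreme-cell rejection (|z| > 6),
high-missingness column removal (>15%), chained-equation imputation with
predictive mean matching, near-constant column removal, iterative
correlation reduction (|r| > 0.85), and standard scaling — each exposed
as a sklearn-style transformer so the stages compose with sklearn
pipelines and can be applied to held-out rows with the fitted state.

Covariate indicator columns (``cov_`` prefix) are exempt from the
variance and correlation filters by default: the composite score
correlates with its components by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "encode_covariates", "OutlierMasker", "MissingnessFilter", "MiceImputer",
    "LowVarianceFilter", "CorrelationFilter", "Standardizer", "FeaturePipeline",
    "PipelineReport", "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS = ["cov_sbp_low", "cov_rr_high", "cov_gcs_low", "cov_composite"]


def encode_covariates(sbp, rr, gcs) -> pd.DataFrame:
    """Encode SBP / respiratory rate / GCS as abnormality indicators.

    Thresholds are the quick bedside criteria: SBP <= 100 mmHg,
    RR >= 22 breaths/min, GCS < 15; the composite is their sum (0-3).
    Accepts scalars or aligned arrays; missing inputs yield missing
    indicators.  GCS outside [3, 15] raises.
    """
    sbp = np.atleast_1d(np.asarray(sbp, dtype=float))
    rr = np.atleast_1d(np.asarray(rr, dtype=float))
    gcs = np.atleast_1d(np.asarray(gcs, dtype=float))
    finite_gcs = gcs[np.isfinite(gcs)]
    if len(finite_gcs) and ((finite_gcs < 3) | (finite_gcs > 15)).any():
        raise ValueError("GCS must lie in [3, 15]")
    out = pd.DataFrame({
        "cov_sbp_low": np.where(np.isfinite(sbp), (sbp <= 100).astype(float), np.nan),
        "cov_rr_high": np.where(np.isfinite(rr), (rr >= 22).astype(float), np.nan),
        "cov_gcs_low": np.where(np.isfinite(gcs), (gcs < 15).astype(float), np.nan),
    })
    out["cov_composite"] = out.sum(axis=1, skipna=False)
    return out


class _TableTransformer(BaseEstimator, TransformerMixin):
    """Base for DataFrame-in / DataFrame-out transformers."""

    def _validate(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        if X.columns.duplicated().any():
            raise ValueError("duplicate column names")
        return X


class OutlierMasker(_TableTransformer):
    """Mask cells with |z| strictly above the threshold (per-column moments
    of observed values; zero-variance columns untouched)."""

    def __init__(self, z_threshold: float = 6.0):
        self.z_threshold = z_threshold

    def fit(self, X, y=None):
        X = self._validate(X)
        self.means_ = X.mean()
        self.stds_ = X.std(ddof=1)
        self.n_masked_ = 0
        return self

    def transform(self, X):
        X = self._validate(X).copy()
        z = (X - self.means_) / self.stds_.replace(0.0, np.nan)
        mask = z.abs() > self.z_threshold
        self.n_masked_ = int(mask.to_numpy().sum())
        return X.mask(mask)


class MissingnessFilter(_TableTransformer):
    """Drop columns whose missing fraction exceeds ``max_frac`` (strict)."""

    def __init__(self, max_frac: float = 0.15):
        self.max_frac = max_frac

    def fit(self, X, y=None):
        X = self._validate(X)
        frac = X.isna().mean()
        self.missing_fractions_ = frac
        self.dropped_ = list(frac.index[frac > self.max_frac])
        self.kept_ = [c for c in X.columns if c not in self.dropped_]
        return self

    def transform(self, X):
        return self._validate(X)[self.kept_]


class MiceImputer(_TableTransformer):
    """Chained-equation imputation with predictive mean matching.

    Missing cells start at column means; each sweep regresses every
    incomplete column on the others (ridge-stabilised least squares),
    predicts the missing entries and replaces them with the observed
    value of one of ``pmm_donors`` donors closest in predicted value.
    Imputed values therefore always come from the column's observed
    support.  One completed dataset is returned; deterministic under
    ``random_state``.
    """

    def __init__(self, n_iterations: int = 10, pmm_donors: int = 5,
                 random_state: int = 0, ridge: float = 1e-6):
        self.n_iterations = n_iterations
        self.pmm_donors = pmm_donors
        self.random_state = random_state
        self.ridge = ridge

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = self._validate(X)
        if X.isna().all().any():
            bad = list(X.columns[X.isna().all()])
            raise ValueError(f"columns with 100% missingness cannot be imputed: {bad}")
        rng = np.random.default_rng(self.random_state)
        data = X.to_numpy(dtype=float).copy()
        miss = np.isnan(data)
        if not miss.any():
            return X.copy()
        col_means = np.nanmean(data, axis=0)
        filled = np.where(miss, col_means[None, :], data)
        # visit incomplete columns in order of increasing missingness
        order = [j for j in np.argsort(miss.sum(axis=0)) if miss[:, j].any()]
        for _ in range(self.n_iterations):
            for j in order:
                obs = ~miss[:, j]
                others = np.delete(filled, j, axis=1)
                a = np.column_stack([np.ones(len(filled)), others])
                ata = a[obs].T @ a[obs] + self.ridge * np.eye(a.shape[1])
                beta = np.linalg.solve(ata, a[obs].T @ data[obs, j])
                pred = a @ beta
                donors_pool = np.flatnonzero(obs)
                k = min(self.pmm_donors, len(donors_pool))
                for i in np.flatnonzero(miss[:, j]):
                    dist = np.abs(pred[donors_pool] - pred[i])
                    nearest = donors_pool[np.argpartition(dist, k - 1)[:k]]
                    filled[i, j] = data[rng.choice(nearest), j]
        return pd.DataFrame(filled, index=X.index, columns=X.columns)


class LowVarianceFilter(_TableTransformer):
    """Drop near-constant columns (dominant value >99% or raw SD ~ 0)."""

    def __init__(self, dominant_freq: float = 0.99, sd_eps: float = 1e-8,
                 exempt: tuple = ()):
        self.dominant_freq = dominant_freq
        self.sd_eps = sd_eps
        self.exempt = exempt

    def fit(self, X, y=None):
        X = self._validate(X)
        dropped = []
        for c in X.columns:
            if c in self.exempt:
                continue
            col = X[c].dropna()
            if len(col) == 0:
                continue
            top = col.value_counts(normalize=True).iloc[0]
            if top > self.dominant_freq or col.std(ddof=1) < self.sd_eps:
                dropped.append(c)
        self.dropped_ = dropped
        self.kept_ = [c for c in X.columns if c not in dropped]
        return self

    def transform(self, X):
        return self._validate(X)[self.kept_]


class CorrelationFilter(_TableTransformer):
    """Iteratively drop one member of every pair with |r| above threshold.

    While any pair exceeds the threshold, the worst pair is resolved by
    dropping its member with the higher mean absolute correlation to all
    remaining columns (``keep_higher_mean=True`` flips the rule); ties
    drop the lexicographically later name, so the result is
    deterministic given the column order.
    """

    def __init__(self, threshold: float = 0.85, keep_higher_mean: bool = False,
                 exempt: tuple = ()):
        self.threshold = threshold
        self.keep_higher_mean = keep_higher_mean
        self.exempt = exempt

    def fit(self, X, y=None):
        X = self._validate(X)
        cols = [c for c in X.columns if c not in self.exempt]
        corr = X[cols].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)
        active = list(range(len(cols)))
        dropped = []
        while True:
            sub = corr[np.ix_(active, active)]
            if sub.size == 0 or sub.max() <= self.threshold:
                break
            i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
            mean_i = sub[i_loc].mean()
            mean_j = sub[j_loc].mean()
            if mean_i == mean_j:
                # tie: drop the lexicographically later column name
                drop_loc = max(i_loc, j_loc,
                               key=lambda l: cols[active[l]])
            elif self.keep_higher_mean:
                drop_loc = i_loc if mean_i < mean_j else j_loc
            else:
                drop_loc = i_loc if mean_i > mean_j else j_loc
            dropped.append(cols[active[drop_loc]])
            del active[drop_loc]
        self.dropped_ = dropped
        self.kept_ = [c for c in X.columns if c not in dropped]
        return self

    def transform(self, X):
        return self._validate(X)[self.kept_]


class Standardizer(_TableTransformer):
    """Column-wise z-scoring with stored moments and exact inverse."""

    def fit(self, X, y=None):
        X = self._validate(X)
        self.means_ = X.mean()
        self.stds_ = X.std(ddof=0).replace(0.0, 1.0)
        return self

    def transform(self, X):
        X = self._validate(X)
        return (X[self.means_.index] - self.means_) / self.stds_

    def inverse_transform(self, X):
        X = self._validate(X)
        return X * self.stds_ + self.means_


@dataclass
class PipelineReport:
    """Per-step accounting of the cleaning pipeline."""

    initial_columns: int = 0
    steps: list = field(default_factory=list)   # (step, dropped columns, detail)
    masked_cells: int = 0
    imputed_cells: int = 0
    final_columns: int = 0

    def dropped_by(self, step: str) -> list:
        for name, dropped, _ in self.steps:
            if name == step:
                return dropped
        return []

    def to_dict(self) -> dict:
        return {
            "initial_columns": self.initial_columns,
            "final_columns": self.final_columns,
            "masked_cells": self.masked_cells,
            "imputed_cells": self.imputed_cells,
            "steps": [{"step": s, "dropped": d, "detail": det}
                      for s, d, det in self.steps],
        }


class FeaturePipeline(_TableTransformer):
    """The full cleaning chain with exact drop accounting.

    ``fit_transform`` returns the standardized matrix; the fitted object
    retains every stage (``report_``, ``scaler_``) so new rows can be
    pushed through with the stored state.
    """

    def __init__(self, z_threshold: float = 6.0, max_missing_frac: float = 0.15,
                 corr_threshold: float = 0.85, keep_higher_mean: bool = False,
                 mice_iterations: int = 10, pmm_donors: int = 5,
                 random_state: int = 0, exempt_covariates: bool = True,
                 standardize: bool = True):
        self.z_threshold = z_threshold
        self.max_missing_frac = max_missing_frac
        self.corr_threshold = corr_threshold
        self.keep_higher_mean = keep_higher_mean
        self.mice_iterations = mice_iterations
        self.pmm_donors = pmm_donors
        self.random_state = random_state
        self.exempt_covariates = exempt_covariates
        self.standardize = standardize

    def fit_transform(self, X, y=None, **kwargs):
        X = self._validate(X)
        report = PipelineReport(initial_columns=X.shape[1])
        exempt = tuple(c for c in COVARIATE_COLUMNS if c in X.columns) \
            if self.exempt_covariates else ()

        self.outlier_ = OutlierMasker(self.z_threshold).fit(X)
        X = self.outlier_.transform(X)
        report.masked_cells = self.outlier_.n_masked_
        report.steps.append(("outlier_rejection", [],
                             {"masked_cells": self.outlier_.n_masked_}))

        self.missing_ = MissingnessFilter(self.max_missing_frac).fit(X)
        fr = self.missing_.missing_fractions_
        report.steps.append(("missingness_filter", list(self.missing_.dropped_),
                             {c: float(fr[c]) for c in self.missing_.dropped_}))
        X = self.missing_.transform(X)

        n_missing = int(X.isna().to_numpy().sum())
        self.imputer_ = MiceImputer(self.mice_iterations, self.pmm_donors,
                                    self.random_state)
        X = self.imputer_.fit(X).transform(X)
        report.imputed_cells = n_missing
        report.steps.append(("mice_imputation", [], {"imputed_cells": n_missing}))

        self.variance_ = LowVarianceFilter(exempt=exempt).fit(X)
        report.steps.append(("low_variance_filter", list(self.variance_.dropped_), {}))
        X = self.variance_.transform(X)

        self.correlation_ = CorrelationFilter(self.corr_threshold,
                                              self.keep_higher_mean,
                                              exempt=exempt).fit(X)
        report.steps.append(("correlation_reduction",
                             list(self.correlation_.dropped_), {}))
        X = self.correlation_.transform(X)

        self.scaler_ = Standardizer().fit(X)
        if self.standardize:
            X = self.scaler_.transform(X)
        report.final_columns = X.shape[1]
        dropped_total = sum(len(d) for _, d, _ in report.steps)
        assert report.final_columns == report.initial_columns - dropped_total
        self.report_ = report
        self.columns_ = list(X.columns)
        return X

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def transform(self, X):
        """Apply the fitted stages (stored moments/drops) to new rows."""
        X = self._validate(X)
        X = self.outlier_.transform(X)
        X = X[self.missing_.kept_]
        X = self.imputer_.transform(X)
        X = self.variance_.transform(X)
        X = self.correlation_.transform(X)
        return self.scaler_.transform(X) if self.standardize else X
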