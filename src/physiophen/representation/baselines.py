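"""Linear and identity representation baselines."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = ["PCAEmbedding", "IdentityEmbedding"]


class PCAEmbedding(BaseEstimator, TransformerMixin):
    """PCA to ``d_latent`` components, with mean reconstruction error."""

    def __init__(self, d_latent: int = 32, random_state: int | None = None):
        self.d_latent = d_latent
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float)
        k = min(self.d_latent, min(x.shape))
        self.pca_ = PCA(n_components=k, random_state=self.random_state).fit(x)
        recon = self.pca_.inverse_transform(self.pca_.transform(x))
        self.reconstruction_error_ = float(np.mean((x - recon) ** 2))
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "pca_")
        return self.pca_.transform(np.asarray(X, dtype=float))

    def inverse_transform(self, Z) -> np.ndarray:
        return self.pca_.inverse_transform(Z)


class IdentityEmbedding(BaseEstimator, TransformerMixin):
    """No-transformation baseline: the standardized matrix itself."""

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float)
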