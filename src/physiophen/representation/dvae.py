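"""Deep variational autoencoder baseline.

Gaussian-latent VAE with a 128-64 encoder, 32-dimensional latent, and a
mirrored decoder; the ELBO is reconstruction MSE plus a weighted KL term
(KL weight 0 recovers a plain autoencoder).  The posterior mean is the
embedding.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import fit_loop, init_params
from ._tensor import Tensor, relu

__all__ = ["DeepVAE"]


class DeepVAE(BaseEstimator, TransformerMixin):
    def __init__(self, hidden: tuple = (128, 64), d_latent: int = 32,
                 kl_weight: float = 1.0, lr: float = 1e-3, batch_size: int = 32,
                 val_fraction: float = 0.2, max_epochs: int = 100,
                 plateau_factor: float = 0.5, plateau_patience: int = 6,
                 early_stop_patience: int = 20, random_state: int | None = None):
        self.hidden = hidden
        self.d_latent = d_latent
        self.kl_weight = kl_weight
        self.lr = lr
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.max_epochs = max_epochs
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.early_stop_patience = early_stop_patience
        self.random_state = random_state

    def _init(self, f: int, rng: np.random.Generator) -> dict[str, Tensor]:
        dims = [f, *self.hidden]
        p: dict[str, Tensor] = {}
        for i in range(len(dims) - 1):
            p[f"enc_w{i}"] = init_params(rng, (dims[i], dims[i + 1]),
                                         scale=dims[i] ** -0.5)
            p[f"enc_b{i}"] = Tensor(np.zeros(dims[i + 1], dtype=np.float32),
                                    requires_grad=True)
        h = dims[-1]
        p["mu_w"] = init_params(rng, (h, self.d_latent), scale=h ** -0.5)
        p["mu_b"] = Tensor(np.zeros(self.d_latent, dtype=np.float32), requires_grad=True)
        p["lv_w"] = init_params(rng, (h, self.d_latent), scale=h ** -0.5)
        p["lv_b"] = Tensor(np.zeros(self.d_latent, dtype=np.float32), requires_grad=True)
        ddims = [self.d_latent, *reversed(self.hidden), f]
        for i in range(len(ddims) - 1):
            p[f"dec_w{i}"] = init_params(rng, (ddims[i], ddims[i + 1]),
                                         scale=ddims[i] ** -0.5)
            p[f"dec_b{i}"] = Tensor(np.zeros(ddims[i + 1], dtype=np.float32),
                                    requires_grad=True)
        return p

    def _encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        p = self.params_
        hcur = x
        for i in range(len(self.hidden)):
            hcur = relu(hcur @ p[f"enc_w{i}"] + p[f"enc_b{i}"])
        return (hcur @ p["mu_w"] + p["mu_b"], hcur @ p["lv_w"] + p["lv_b"])

    def _decode(self, z: Tensor) -> Tensor:
        p = self.params_
        hcur = z
        n_dec = len(self.hidden) + 1
        for i in range(n_dec):
            hcur = hcur @ p[f"dec_w{i}"] + p[f"dec_b{i}"]
            if i < n_dec - 1:
                hcur = relu(hcur)
        return hcur

    def _loss(self, x: np.ndarray, training: bool) -> Tensor:
        xt = Tensor(x)
        mu, logvar = self._encode(xt)
        if training:
            eps = Tensor(self._noise_rng.standard_normal(mu.shape).astype(np.float32))
            z = mu + (logvar * 0.5).exp() * eps
        else:
            z = mu
        recon = self._decode(z)
        diff = recon - xt
        mse = (diff * diff).mean()
        # KL(q||N(0,1)) per sample, scaled by feature count to match MSE units
        kl = ((mu * mu + logvar.exp() - logvar - 1.0) * 0.5).sum(axis=1).mean()
        self.last_kl_ = float(kl.data)
        return mse + (self.kl_weight / x.shape[1]) * kl

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=np.float32)
        if np.isnan(x).any():
            raise ValueError("matrix contains missing values; impute first")
        n, f = x.shape
        rng = np.random.default_rng(self.random_state)
        self._noise_rng = np.random.default_rng(rng.integers(2 ** 31))
        perm = rng.permutation(n)
        n_val = max(int(round(self.val_fraction * n)), 1)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        self.params_ = self._init(f, rng)
        self.n_features_in_ = f
        self.history_ = fit_loop(
            self._loss, self.params_, x[tr_idx], x[val_idx],
            lr=self.lr, batch_size=self.batch_size, max_epochs=self.max_epochs,
            plateau_factor=self.plateau_factor,
            plateau_patience=self.plateau_patience,
            early_stop_patience=self.early_stop_patience, rng=rng)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        x = np.asarray(X, dtype=np.float32)
        mu, _ = self._encode(Tensor(x))
        return mu.data
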