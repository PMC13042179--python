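"""Feature-tokenizer transformer autoencoder for tabular physiomarkers.

Every scalar feature is mapped by a learnable per-feature affine into a
token vector; a learnable CLS token is prepended and learnable
feature-identity (positional) embeddings added.  The token sequence
passes through stacked post-norm transformer encoder blocks (multi-head
self-attention -> residual + layer norm -> feed-forward -> residual +
layer norm, with dropout), the CLS output is projected linearly to the
latent space, and a lightweight feed-forward decoder reconstructs all
features from the latent vector.  Mean-squared reconstruction error
drives fully self-supervised training with Adam, plateau learning-rate
decay and early stopping.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import (affine, dropout, fit_loop, init_params, layer_norm,
                  multi_head_attention)
from ._tensor import Tensor, concat, relu

__all__ = ["FTTransformerAutoencoder"]


class FTTransformerAutoencoder(BaseEstimator, TransformerMixin):
    """Self-supervised 32-dimensional embedding of a standardized matrix.

    Parameters mirror the reference configuration: 128-dimensional token
    space split over 4 attention heads (32 per head), 3 encoder blocks,
    256-unit ReLU feed-forward, dropout 0.1, Adam at 2e-3 with
    plateau halving (patience 6) and early stopping (patience 20),
    batch size 32.  ``transform`` returns the (n, d_latent) embedding
    with dropout disabled, so duplicate rows map to identical codes.

    ``max_train_rows`` caps the number of rows used for optimisation
    (encoding still covers every row) to bound runtime on large inputs.
    """

    def __init__(self, d_token: int = 128, n_blocks: int = 3, n_heads: int = 4,
                 d_head: int = 32, ffn_hidden: int = 256, dropout: float = 0.1,
                 d_latent: int = 32, lr: float = 2e-3, plateau_factor: float = 0.5,
                 plateau_patience: int = 6, early_stop_patience: int = 20,
                 batch_size: int = 32, val_fraction: float = 0.2,
                 max_epochs: int = 200, max_train_rows: int | None = None,
                 random_state: int | None = None):
        self.d_token = d_token
        self.n_blocks = n_blocks
        self.n_heads = n_heads
        self.d_head = d_head
        self.ffn_hidden = ffn_hidden
        self.dropout = dropout
        self.d_latent = d_latent
        self.lr = lr
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.early_stop_patience = early_stop_patience
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.max_epochs = max_epochs
        self.max_train_rows = max_train_rows
        self.random_state = random_state

    # -- model ---------------------------------------------------------
    def _init(self, n_features: int, rng: np.random.Generator) -> dict[str, Tensor]:
        d, h = self.d_token, self.ffn_hidden
        p: dict[str, Tensor] = {
            "tok_w": init_params(rng, (n_features, d)),
            "tok_b": init_params(rng, (n_features, d)),
            "cls": init_params(rng, (1, 1, d)),
            "pos": init_params(rng, (n_features + 1, d)),
            "lat_w": init_params(rng, (d, self.d_latent), scale=d ** -0.5),
            "lat_b": Tensor(np.zeros(self.d_latent, dtype=np.float32),
                            requires_grad=True),
            "dec_w1": init_params(rng, (self.d_latent, 128),
                                  scale=self.d_latent ** -0.5),
            "dec_b1": Tensor(np.zeros(128, dtype=np.float32), requires_grad=True),
            "dec_w2": init_params(rng, (128, n_features), scale=128 ** -0.5),
            "dec_b2": Tensor(np.zeros(n_features, dtype=np.float32),
                             requires_grad=True),
        }
        for i in range(self.n_blocks):
            for w in ("wq", "wk", "wv", "wo"):
                p[f"b{i}_{w}"] = init_params(rng, (d, d), scale=d ** -0.5)
            p[f"b{i}_ln1_g"] = Tensor(np.ones(d, dtype=np.float32), requires_grad=True)
            p[f"b{i}_ln1_b"] = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)
            p[f"b{i}_ffn_w1"] = init_params(rng, (d, h), scale=d ** -0.5)
            p[f"b{i}_ffn_b1"] = Tensor(np.zeros(h, dtype=np.float32), requires_grad=True)
            p[f"b{i}_ffn_w2"] = init_params(rng, (h, d), scale=h ** -0.5)
            p[f"b{i}_ffn_b2"] = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)
            p[f"b{i}_ln2_g"] = Tensor(np.ones(d, dtype=np.float32), requires_grad=True)
            p[f"b{i}_ln2_b"] = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)
        return p

    def _encode_tokens(self, x: np.ndarray, training: bool,
                       rng: np.random.Generator) -> Tensor:
        p = self.params_
        b, f = x.shape
        d = self.d_token
        xt = Tensor(x[:, :, None])
        tokens = xt * p["tok_w"] + p["tok_b"]            # (B, F, d)
        cls = p["cls"].broadcast_to((b, 1, d))
        seq = concat([cls, tokens], axis=1) + p["pos"]   # (B, F+1, d)
        for i in range(self.n_blocks):
            ctx = multi_head_attention(seq, p[f"b{i}_wq"], p[f"b{i}_wk"],
                                       p[f"b{i}_wv"], p[f"b{i}_wo"],
                                       self.n_heads, self.dropout, rng, training)
            ctx = dropout(ctx, self.dropout, rng, training)
            seq = layer_norm(seq + ctx, p[f"b{i}_ln1_g"], p[f"b{i}_ln1_b"])
            ff = affine(relu(affine(seq, p[f"b{i}_ffn_w1"], p[f"b{i}_ffn_b1"])),
                        p[f"b{i}_ffn_w2"], p[f"b{i}_ffn_b2"])
            ff = dropout(ff, self.dropout, rng, training)
            seq = layer_norm(seq + ff, p[f"b{i}_ln2_g"], p[f"b{i}_ln2_b"])
        return affine(seq[:, 0, :], p["lat_w"], p["lat_b"])  # (B, d_latent)

    def _forward_loss(self, x: np.ndarray, training: bool,
                      rng: np.random.Generator) -> Tensor:
        p = self.params_
        z = self._encode_tokens(x, training, rng)
        recon = affine(relu(affine(z, p["dec_w1"], p["dec_b1"])),
                       p["dec_w2"], p["dec_b2"])
        diff = recon - Tensor(x)
        return (diff * diff).mean()

    # -- estimator API -------------------------------------------------
    def fit(self, X, y=None):
        x = np.asarray(X, dtype=np.float32)
        if x.ndim != 2:
            raise ValueError("expected a 2-d matrix")
        if np.isnan(x).any():
            raise ValueError("matrix contains missing values; impute first")
        n, f = x.shape
        if self.d_token != self.n_heads * self.d_head:
            raise ValueError("d_token must equal n_heads * d_head")
        if self.d_latent >= f:
            raise ValueError("d_latent must be smaller than the input dimension")
        if n < 2 * self.batch_size:
            raise ValueError("need at least 2*batch_size rows")
        rng = np.random.default_rng(self.random_state)
        self._drop_rng = np.random.default_rng(rng.integers(2 ** 31))
        perm = rng.permutation(n)
        n_val = max(int(round(self.val_fraction * n)), 1)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if self.max_train_rows is not None and len(tr_idx) > self.max_train_rows:
            tr_idx = tr_idx[: self.max_train_rows]
        self.params_ = self._init(f, rng)
        self.n_features_in_ = f
        self.history_ = fit_loop(
            lambda b, training: self._forward_loss(b, training, self._drop_rng),
            self.params_, x[tr_idx], x[val_idx],
            lr=self.lr, batch_size=self.batch_size, max_epochs=self.max_epochs,
            plateau_factor=self.plateau_factor,
            plateau_patience=self.plateau_patience,
            early_stop_patience=self.early_stop_patience, rng=rng)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        x = np.asarray(X, dtype=np.float32)
        if x.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        out = []
        for s in range(0, len(x), 64):  # small chunks stay cache-resident
            out.append(self._encode_tokens(x[s:s + 64], False, self._drop_rng).data)
        return np.concatenate(out, axis=0)

    def reconstruct(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        p = self.params_
        z = Tensor(self.transform(X))
        return affine(relu(affine(z, p["dec_w1"], p["dec_b1"])),
                      p["dec_w2"], p["dec_b2"]).data
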