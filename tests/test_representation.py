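"""Autodiff engine and tabular representation learners."""

import numpy as np
import pytest

from physiophen.representation import (DeepVAE, FTTransformerAutoencoder,
                                       IdentityEmbedding, PCAEmbedding)
from physiophen.representation._nn import affine, layer_norm, multi_head_attention
from physiophen.representation._tensor import Tensor, concat, relu, softmax_lastdim


def _num_grad(fn, arrays, idx, eps=1e-6):
    num = np.zeros_like(arrays[idx])
    for pos in np.ndindex(arrays[idx].shape):
        plus = [a.copy() for a in arrays]
        minus = [a.copy() for a in arrays]
        plus[idx][pos] += eps
        minus[idx][pos] -= eps
        num[pos] = (fn(plus) - fn(minus)) / (2 * eps)
    return num


class TestAutodiff:
    def test_composite_expression_gradients(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(3, 4))
        w = rng.normal(size=(4, 4))

        def build(arrs):
            x = Tensor(arrs[0], requires_grad=True)
            m = Tensor(arrs[1], requires_grad=True)
            out = (relu(softmax_lastdim(x @ m) @ m.transpose(1, 0)) * x).mean()
            return out, (x, m)

        out, ts = build([a, w])
        out.backward()
        for i, t in enumerate(ts):
            num = _num_grad(lambda arrs: float(build(arrs)[0].data), [a, w], i)
            assert np.abs(num - t.grad).max() < 1e-7

    def test_fused_attention_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 4, 6))
        ws = [0.4 * rng.normal(size=(6, 6)) for _ in range(4)]

        def build(arrs):
            xt = Tensor(arrs[0], requires_grad=True)
            wts = [Tensor(w, requires_grad=True) for w in arrs[1:]]
            out = multi_head_attention(xt, *wts, n_heads=2, drop_rate=0.0,
                                       rng=rng, training=False)
            return (out ** 2.0).mean(), [xt, *wts]

        out, ts = build([x, *ws])
        out.backward()
        for i, t in enumerate(ts):
            num = _num_grad(lambda arrs: float(build(arrs)[0].data), [x, *ws], i)
            assert np.abs(num - t.grad).max() < 1e-7

    def test_layer_norm_and_affine_gradients(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 5))
        g = 1.0 + 0.1 * rng.normal(size=5)
        b = 0.1 * rng.normal(size=5)
        w = rng.normal(size=(5, 4))
        bb = rng.normal(size=4)

        def build(arrs):
            xt, gt, bt, wt, bbt = (Tensor(a, requires_grad=True) for a in arrs)
            out = (affine(layer_norm(xt, gt, bt), wt, bbt) ** 2.0).mean()
            return out, (xt, gt, bt, wt, bbt)

        arrs = [x, g, b, w, bb]
        out, ts = build(arrs)
        out.backward()
        for i, t in enumerate(ts):
            num = _num_grad(lambda a_: float(build(a_)[0].data), arrs, i)
            assert np.abs(num - t.grad).max() < 1e-7

    def test_concat_and_slice_gradients(self):
        a = Tensor(np.ones((2, 2)), requires_grad=True)
        b = Tensor(np.ones((2, 3)), requires_grad=True)
        out = concat([a, b], axis=1)[:, 1:4].sum()
        out.backward()
        assert np.array_equal(a.grad, [[0, 1], [0, 1]])
        assert np.array_equal(b.grad, [[1, 1, 0], [1, 1, 0]])


@pytest.fixture(scope="module")
def rank2_matrix():
    rng = np.random.default_rng(10)
    x = rng.normal(size=(200, 2)) @ rng.normal(size=(2, 50))
    x += 0.01 * rng.normal(size=x.shape)
    return (x - x.mean(0)) / x.std(0)


@pytest.fixture(scope="module")
def fitted_ftt(rank2_matrix):
    return FTTransformerAutoencoder(max_epochs=8, random_state=0).fit(rank2_matrix)


class TestFTTransformer:
    def test_token_sequence_and_latent_shapes(self, fitted_ftt):
        p = fitted_ftt.params_
        assert p["pos"].shape == (51, 128)       # n_features + CLS token
        assert p["cls"].shape == (1, 1, 128)
        assert p["lat_w"].shape == (128, 32)

    def test_embedding_width_32(self, fitted_ftt, rank2_matrix):
        z = fitted_ftt.transform(rank2_matrix)
        assert z.shape == (200, 32)
        assert np.isfinite(z).all()

    def test_row_permutation_equivariance(self, fitted_ftt, rank2_matrix):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(rank2_matrix))
        z = fitted_ftt.transform(rank2_matrix)
        zp = fitted_ftt.transform(rank2_matrix[perm])
        assert np.allclose(zp, z[perm], atol=1e-5)

    def test_duplicate_rows_identical_codes(self, fitted_ftt, rank2_matrix):
        dup = np.vstack([rank2_matrix[:1], rank2_matrix[:1]])
        z = fitted_ftt.transform(dup)
        assert np.array_equal(z[0], z[1])  # dropout disabled at inference

    def test_validation_loss_drops_on_rank_deficient_data(self, fitted_ftt):
        h = fitted_ftt.history_
        assert h["best_val"] < 0.25 * h["val"][0]

    def test_lr_schedule_and_early_stopping(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(100, 10)).astype(np.float32)
        enc = FTTransformerAutoencoder(d_token=16, n_heads=2, d_head=8,
                                       ffn_hidden=32, d_latent=4, batch_size=16,
                                       max_epochs=60, plateau_patience=2,
                                       early_stop_patience=6, random_state=0)
        enc.fit(x)
        h = enc.history_
        lr = np.asarray(h["lr"])
        assert (np.diff(lr) <= 1e-12).all()          # non-increasing
        drops = lr[1:][np.diff(lr) < 0] / lr[:-1][np.diff(lr) < 0]
        assert np.allclose(drops, 0.5)                # exact halving
        n_epochs = len(h["val"]) - 1
        assert n_epochs <= h["best_epoch"] + enc.early_stop_patience

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(80, 12)).astype(np.float32)
        kw = dict(d_token=16, n_heads=2, d_head=8, ffn_hidden=32, d_latent=4,
                  batch_size=16, max_epochs=5, random_state=9)
        h1 = FTTransformerAutoencoder(**kw).fit(x).history_
        h2 = FTTransformerAutoencoder(**kw).fit(x).history_
        assert abs(h1["best_val"] - h2["best_val"]) < 1e-6

    def test_input_validation(self):
        x = np.random.default_rng(0).normal(size=(100, 10))
        with pytest.raises(ValueError):
            FTTransformerAutoencoder(d_token=100, n_heads=4, d_head=32).fit(x)
        xm = x.copy()
        xm[0, 0] = np.nan
        with pytest.raises(ValueError):
            FTTransformerAutoencoder(d_latent=4, d_token=16, n_heads=2,
                                     d_head=8).fit(xm)
        with pytest.raises(ValueError):
            FTTransformerAutoencoder(d_latent=4, d_token=16, n_heads=2,
                                     d_head=8, batch_size=64).fit(x)


class TestBaselines:
    def test_pca_exact_on_planar_data(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 2)) @ rng.normal(size=(2, 6)) + 3.0
        emb = PCAEmbedding(d_latent=2).fit(x)
        assert emb.reconstruction_error_ == pytest.approx(0.0, abs=1e-12)

    def test_pca_scores_uncorrelated(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(300, 8))
        z = PCAEmbedding(d_latent=5).fit(x).transform(x)
        c = np.corrcoef(z.T)
        np.fill_diagonal(c, 0.0)
        assert np.abs(c).max() < 1e-6

    def test_pca_explained_variance_monotone(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(200, 10)) * np.arange(1, 11)
        evr = PCAEmbedding(d_latent=8).fit(x).explained_variance_ratio_
        assert (np.diff(evr) <= 1e-12).all()

    def test_identity_passthrough(self):
        x = np.random.default_rng(3).normal(size=(20, 5))
        z = IdentityEmbedding().fit(x).transform(x)
        assert np.array_equal(z, x)


class TestDVAE:
    def test_embedding_shape_and_kl_positive(self):
        rng = np.random.default_rng(0)
        x = (rng.normal(size=(150, 3)) @ rng.normal(size=(3, 40))).astype(np.float32)
        vae = DeepVAE(d_latent=32, max_epochs=5, random_state=0)
        vae.fit(x)
        assert vae.transform(x).shape == (150, 32)
        assert vae.last_kl_ >= 0.0

    def test_zero_kl_recovers_autoencoder(self):
        """KL weight -> 0 matches the plain-autoencoder objective within 10%."""
        rng = np.random.default_rng(1)
        x = (rng.normal(size=(150, 3)) @ rng.normal(size=(3, 30))).astype(np.float32)
        x = (x - x.mean(0)) / x.std(0)
        kw = dict(d_latent=8, hidden=(32, 16), max_epochs=25, random_state=0)
        ae = DeepVAE(kl_weight=0.0, **kw).fit(x)
        near_ae = DeepVAE(kl_weight=1e-6, **kw).fit(x)
        assert near_ae.history_["best_val"] <= 1.10 * ae.history_["best_val"] + 1e-6
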