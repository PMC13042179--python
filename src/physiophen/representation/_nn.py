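"""Layers and optimisation shared by the tabular encoders."""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor

__all__ = ["init_params", "layer_norm", "dropout", "affine",
           "multi_head_attention", "Adam", "fit_loop"]


def affine(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fused ``x @ w + b`` (single autodiff node)."""
    out = x.data @ w.data + b.data

    def backward(g):
        dx = g @ w.data.T
        gm = g.reshape(-1, g.shape[-1])
        dw = x.data.reshape(-1, x.data.shape[-1]).T @ gm
        return dx, dw, gm.sum(axis=0)
    return Tensor._make(out, (x, w, b), backward)


def multi_head_attention(x: Tensor, wq: Tensor, wk: Tensor, wv: Tensor,
                         wo: Tensor, n_heads: int, drop_rate: float,
                         rng: np.random.Generator, training: bool) -> Tensor:
    """Fused multi-head self-attention block (pre-residual part).

    Computes ``softmax(QK'/sqrt(dh)) V`` per head with optional dropout
    on the attention probabilities, merges heads and applies the output
    projection.  One autodiff node with a hand-written backward pass,
    which keeps the graph small enough for CPU training.
    """
    b, t, d = x.data.shape
    dh = d // n_heads
    scale = float(dh) ** -0.5  # python float: keeps float32 graphs float32

    def heads(m):  # (B,T,d) -> (B,H,T,dh)
        return m.reshape(b, t, n_heads, dh).transpose(0, 2, 1, 3)

    q = heads(x.data @ wq.data)
    k = heads(x.data @ wk.data)
    v = heads(x.data @ wv.data)
    s = q @ k.swapaxes(-1, -2) * scale
    s -= s.max(axis=-1, keepdims=True)
    p = np.exp(s)
    p /= p.sum(axis=-1, keepdims=True)
    if training and drop_rate > 0:
        mask = (rng.random(p.shape) >= drop_rate).astype(p.dtype) / (1.0 - drop_rate)
        pd = p * mask
    else:
        mask = None
        pd = p
    ctx = pd @ v                                   # (B,H,T,dh)
    merged = ctx.transpose(0, 2, 1, 3).reshape(b, t, d)
    out = merged @ wo.data

    def backward(g):
        gm = g.reshape(-1, d)
        dwo = merged.reshape(-1, d).T @ gm
        dmerged = g @ wo.data.T
        dctx = heads(dmerged)
        dpd = dctx @ v.swapaxes(-1, -2)
        dv = pd.swapaxes(-1, -2) @ dctx
        dp = dpd * mask if mask is not None else dpd
        ds = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
        ds *= scale
        dq = ds @ k
        dk = ds.swapaxes(-1, -2) @ q

        def merge(m):  # (B,H,T,dh) -> (B*T, d)
            return m.transpose(0, 2, 1, 3).reshape(b * t, d)

        xf = x.data.reshape(-1, d)
        dx = (merge(dq) @ wq.data.T + merge(dk) @ wk.data.T
              + merge(dv) @ wv.data.T).reshape(b, t, d)
        return (dx, xf.T @ merge(dq), xf.T @ merge(dk), xf.T @ merge(dv), dwo)
    return Tensor._make(out, (x, wq, wk, wv, wo), backward)


def init_params(rng: np.random.Generator, shape, scale: float = 0.02,
                dtype=np.float32) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape).astype(dtype),
                  requires_grad=True)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused last-axis layer normalisation (single autodiff node)."""
    d = x.data
    mu = d.mean(axis=-1, keepdims=True)
    xc = d - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data

    def backward(g):
        gg = g * gamma.data
        m1 = gg.mean(axis=-1, keepdims=True)
        m2 = (gg * xhat).mean(axis=-1, keepdims=True)
        dx = (gg - m1 - xhat * m2) * inv
        axes = tuple(range(g.ndim - 1))
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        return dx, dgamma, dbeta
    return Tensor._make(out, (x, gamma, beta), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    return x * Tensor(mask)


class Adam:
    """Adaptive-moment optimiser over a dict of named parameters."""

    def __init__(self, params: dict[str, Tensor], lr: float = 2e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def fit_loop(loss_fn, params: dict[str, Tensor], x_train: np.ndarray,
             x_val: np.ndarray, *, lr: float, batch_size: int, max_epochs: int,
             plateau_factor: float, plateau_patience: int,
             early_stop_patience: int, rng: np.random.Generator,
             min_rel_improve: float = 1e-4) -> dict:
    """Mini-batch training with plateau LR decay and early stopping.

    The learning rate halves (times ``plateau_factor``) after
    ``plateau_patience`` consecutive epochs without relative validation
    improvement; training stops ``early_stop_patience`` epochs after the
    best validation loss, and the best-epoch weights are restored.
    Epoch 0 of the history is the untrained validation loss.
    """
    opt = Adam(params, lr=lr)
    history = {"train": [], "val": [], "lr": []}
    val0 = float(loss_fn(x_val, training=False).data)
    history["val"].append(val0)
    history["train"].append(float(loss_fn(x_train, training=False).data))
    history["lr"].append(opt.lr)
    best = val0
    best_state = {k: p.data.copy() for k, p in params.items()}
    best_epoch = 0
    since_best = 0
    since_plateau = 0
    n = len(x_train)
    for epoch in range(1, max_epochs + 1):
        perm = rng.permutation(n)
        losses = []
        for s in range(0, n, batch_size):
            idx = perm[s:s + batch_size]
            if len(idx) < 2:
                continue
            loss = loss_fn(x_train[idx], training=True)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val = float(loss_fn(x_val, training=False).data)
        history["train"].append(float(np.mean(losses)))
        history["val"].append(val)
        history["lr"].append(opt.lr)
        if val < best * (1.0 - min_rel_improve):
            best = val
            best_epoch = epoch
            best_state = {k: p.data.copy() for k, p in params.items()}
            since_best = 0
            since_plateau = 0
        else:
            since_best += 1
            since_plateau += 1
            if since_plateau > plateau_patience:
                opt.lr *= plateau_factor
                since_plateau = 0
            if since_best >= early_stop_patience:
                break
    for k, p in params.items():
        p.data = best_state[k]
    history["best_epoch"] = best_epoch
    history["best_val"] = best
    return history
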