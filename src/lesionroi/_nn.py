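"""Minimal CNN building blocks on numpy arrays.

Implements exactly what the compact slice classifier needs: 3x3 same-pad
convolutions, ReLU, 2x2 max pooling, global average pooling, dropout, a
small dense head, softmax cross-entropy, and an AdamW optimizer — each
with an explicit backward pass. Keeping the backward pass in-package is
also what exposes the feature-map gradients that Grad-CAM consumes.

Array layout is (N, C, H, W) throughout; arithmetic is float32.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

__all__ = [
    "he_init",
    "conv3x3_forward",
    "conv3x3_backward",
    "maxpool2_forward",
    "maxpool2_backward",
    "softmax",
    "cross_entropy",
    "AdamW",
    "CompactCNN",
]


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padding 3x3 convolution via im2col + one GEMM.

    x (N,C,H,W), w (O,C,3,3), b (O,). Returns (y, cols); ``cols`` is the
    (N*H*W, C*9) patch matrix, reused by the backward pass.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    n, c, h, wd = x.shape
    o = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * wd, c * 9)
    y = cols @ w.reshape(o, c * 9).T + b
    return y.reshape(n, h, wd, o).transpose(0, 3, 1, 2), cols


def conv3x3_backward(
    dy: np.ndarray, cols: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a same-padding 3x3 convolution. Returns (dx, dw, db)."""
    n, o, h, wd = dy.shape
    c = w.shape[1]
    dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * h * wd, o)
    dw = (dy_flat.T @ cols).reshape(o, c, 3, 3)
    db = dy_flat.sum(axis=0)
    # dx is itself a same-padding convolution of dy with the spatially
    # rotated, channel-transposed kernel
    w_rot = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dx, _ = conv3x3_forward(dy, w_rot, np.zeros(c, dtype=DTYPE))
    return dx, dw, db


def maxpool2_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling (stride 2). Returns pooled output and argmax indices."""
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, idx


def maxpool2_backward(dy: np.ndarray, idx: np.ndarray, in_shape: tuple[int, ...]) -> np.ndarray:
    n, c, h, w = in_shape
    dxr = np.zeros((n, c, h // 2, w // 2, 4))
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


def batchnorm_forward(
    x: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    train: bool,
    momentum: float = 0.9,
    eps: float = 1e-5,
) -> tuple[np.ndarray, dict | None]:
    """Per-channel batch normalization on (N,C,H,W); updates running stats in
    train mode and returns the cache needed for the backward pass."""
    if train:
        mu = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running_mean *= momentum
        running_mean += (1 - momentum) * mu
        running_var *= momentum
        running_var += (1 - momentum) * var
    else:
        mu, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu[None, :, None, None]) * invstd[None, :, None, None]
    y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    cache = {"xhat": xhat, "invstd": invstd, "gamma": gamma, "train": train}
    return y, cache


def batchnorm_backward(dy: np.ndarray, cache: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xhat, invstd, gamma = cache["xhat"], cache["invstd"], cache["gamma"]
    dgamma = (dy * xhat).sum(axis=(0, 2, 3))
    dbeta = dy.sum(axis=(0, 2, 3))
    dxhat = dy * gamma[None, :, None, None]
    if not cache["train"]:
        return dxhat * invstd[None, :, None, None], dgamma, dbeta
    n, c, h, w = dy.shape
    m = n * h * w
    s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
    s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
    dx = (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
    return dx, dgamma, dbeta


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


class AdamW:
    """Adam with decoupled weight decay (decay applied to weights only)."""

    def __init__(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 1e-4):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and k.endswith("_w"):  # decay weights only, not biases/BN
                params[k] -= lr * self.weight_decay * params[k]


class CompactCNN:
    """Three conv blocks (conv3x3 -> batchnorm -> ReLU -> maxpool2), global
    average pooling, and a dense head with a 0.6/0.45/0.3 dropout ladder.

    The post-ReLU activation of the last convolution (before its pool) is
    the designated attribution layer, exposed via
    :meth:`feature_maps_and_gradients`.
    """

    FEATURE_LAYER = "conv3_relu"

    def __init__(
        self,
        input_size: int = 64,
        channels: tuple[int, int, int] = (8, 16, 32),
        hidden: int = 32,
        dropout: tuple[float, float, float] = (0.6, 0.45, 0.3),
        n_classes: int = 2,
        rng: np.random.Generator | None = None,
    ):
        if input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8 (three pooling stages)")
        rng = rng or np.random.default_rng(0)
        self.input_size = input_size
        self.channels = tuple(channels)
        self.hidden = hidden
        self.dropout = tuple(dropout)
        self.n_classes = n_classes
        c1, c2, c3 = channels
        self.params: dict[str, np.ndarray] = {
            "conv1_w": he_init(rng, (c1, 1, 3, 3), 9),
            "conv1_b": np.zeros(c1),
            "conv2_w": he_init(rng, (c2, c1, 3, 3), 9 * c1),
            "conv2_b": np.zeros(c2),
            "conv3_w": he_init(rng, (c3, c2, 3, 3), 9 * c2),
            "conv3_b": np.zeros(c3),
            "fc1_w": he_init(rng, (c3, hidden), c3),
            "fc1_b": np.zeros(hidden),
            "fc2_w": he_init(rng, (hidden, hidden), hidden),
            "fc2_b": np.zeros(hidden),
            "fc3_w": he_init(rng, (hidden, n_classes), hidden),
            "fc3_b": np.zeros(n_classes),
        }
        for li, ch in zip((1, 2, 3), channels):
            self.params[f"bn{li}_g"] = np.ones(ch)
            self.params[f"bn{li}_b"] = np.zeros(ch)
        # running statistics (not optimized, but part of the state)
        self.bn_stats: dict[str, np.ndarray] = {}
        for li, ch in zip((1, 2, 3), channels):
            self.bn_stats[f"bn{li}_mean"] = np.zeros(ch)
            self.bn_stats[f"bn{li}_var"] = np.ones(ch)

    # ---------------------------------------------------------------- forward
    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Return (logits, cache). ``x`` is (N, H, W) in [0, 1]."""
        p = self.params
        cache: dict = {}
        a = x[:, None, :, :].astype(np.float64)
        for li in (1, 2, 3):
            z, cols = conv3x3_forward(a, p[f"conv{li}_w"], p[f"conv{li}_b"])
            cache[f"cols{li}"] = cols
            z, bncache = batchnorm_forward(
                z,
                p[f"bn{li}_g"],
                p[f"bn{li}_b"],
                self.bn_stats[f"bn{li}_mean"],
                self.bn_stats[f"bn{li}_var"],
                train=train,
            )
            r = np.maximum(z, 0.0)
            cache[f"x{li}"] = a
            cache[f"bn{li}"] = bncache
            cache[f"relu{li}"] = r
            if li == 3:
                cache["features"] = r  # attribution layer
            a, idx = maxpool2_forward(r)
            cache[f"poolidx{li}"] = idx
        g = a.mean(axis=(2, 3))  # GAP -> (N, C3)
        cache["pool3_out_shape"] = a.shape
        cache["gap"] = g
        h = g
        for li, drop in zip((1, 2, 3), self.dropout):
            if train and drop > 0:
                keep = (rng.random(h.shape) >= drop) / (1.0 - drop)
            else:
                keep = None
            cache[f"dropmask{li}"] = keep
            hd = h * keep if keep is not None else h
            cache[f"fcin{li}"] = hd
            z = hd @ self.params[f"fc{li}_w"] + self.params[f"fc{li}_b"]
            if li < 3:
                cache[f"fcrelu{li}"] = z > 0
                h = np.maximum(z, 0.0)
            else:
                logits = z
        return logits, cache

    # --------------------------------------------------------------- backward
    def backward(
        self, dlogits: np.ndarray, cache: dict, want_feature_grad: bool = False
    ) -> tuple[dict[str, np.ndarray], np.ndarray | None]:
        """Backpropagate from d(logits); returns (param grads, d features)."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        d = dlogits
        for li in (3, 2, 1):
            hd = cache[f"fcin{li}"]
            grads[f"fc{li}_w"] = hd.T @ d
            grads[f"fc{li}_b"] = d.sum(axis=0)
            d = d @ p[f"fc{li}_w"].T
            keep = cache[f"dropmask{li}"]
            if keep is not None:
                d = d * keep
            if li > 1:
                d = d * cache[f"fcrelu{li - 1}"]
        # GAP backward
        n, c, hp, wp = cache["pool3_out_shape"]
        d = np.broadcast_to(d[:, :, None, None] / (hp * wp), (n, c, hp, wp)).copy()
        dfeat = None
        for li in (3, 2, 1):
            r = cache[f"relu{li}"]
            d = maxpool2_backward(d, cache[f"poolidx{li}"], r.shape)
            if li == 3 and want_feature_grad:
                dfeat = d.copy()
            d = d * (r > 0)
            d, dg, dbeta = batchnorm_backward(d, cache[f"bn{li}"])
            grads[f"bn{li}_g"] = dg
            grads[f"bn{li}_b"] = dbeta
            d, dw, db = conv3x3_backward(d, cache[f"cols{li}"], p[f"conv{li}_w"])
            grads[f"conv{li}_w"] = dw
            grads[f"conv{li}_b"] = db
        return grads, dfeat

    # ------------------------------------------------------------- utilities
    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> tuple[float, float, dict[str, np.ndarray]]:
        logits, cache = self.forward(x, train=True, rng=rng)
        probs = softmax(logits)
        loss = cross_entropy(probs, y)
        acc = float(np.mean(probs.argmax(axis=1) == y))
        dlogits = probs.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        dlogits /= len(y)
        grads, _ = self.backward(dlogits, cache)
        return loss, acc, grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            logits, _ = self.forward(x[i : i + batch_size], train=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    def feature_maps_and_gradients(
        self, image: np.ndarray, target_class: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Activations A and dScore/dA of the attribution layer for one image.

        The score is the pre-softmax logit of ``target_class``.
        """
        logits, cache = self.forward(image[None], train=False)
        dlogits = np.zeros_like(logits)
        dlogits[0, target_class] = 1.0
        _, dfeat = self.backward(dlogits, cache, want_feature_grad=True)
        # dfeat is the gradient after pool-backward, i.e. w.r.t. post-ReLU
        # conv3 activations (zero where the pooling window did not select)
        return cache["features"][0], dfeat[0]

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.copy() for k, v in self.params.items()}
        out.update({k: v.copy() for k, v in self.bn_stats.items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.array(state[k], dtype=np.float64)
        for k in self.bn_stats:
            self.bn_stats[k] = np.array(state[k], dtype=np.float64)
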