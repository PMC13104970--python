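"""Minimal fully convolutional network in numpy with explicit backpropagation.

The instance scorer only needs stride-1 3x3 convolutions, ReLUs and 1x1
convolutions with a per-location softmax head, on small fixed-size patches,
so the network and its gradients are implemented directly on numpy arrays
(im2col matrix products).  Everything runs in float32 on CPU and is
deterministic given the initialisation seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(H, W, C) -> (H*W, 9*C) columns for a 3x3 same-padding convolution."""
    h, w, c = x.shape
    p = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    cols = np.empty((h * w, 9 * c), dtype=x.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            cols[:, k * c : (k + 1) * c] = p[dy : dy + h, dx : dx + w, :].reshape(h * w, c)
            k += 1
    return cols


def _col2im3(dcols: np.ndarray, h: int, w: int, c: int) -> np.ndarray:
    """Adjoint of :func:`_im2col3`: scatter column gradients back to (H, W, C)."""
    dp = np.zeros((h + 2, w + 2, c), dtype=dcols.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            dp[dy : dy + h, dx : dx + w, :] += dcols[:, k * c : (k + 1) * c].reshape(h, w, c)
            k += 1
    return dp[1:-1, 1:-1, :]


@dataclass
class Conv3x3:
    """Stride-1, same-padding 3x3 convolution stored as a (9*Cin, Cout) matrix."""

    weight: np.ndarray
    bias: np.ndarray

    @classmethod
    def init(cls, c_in: int, c_out: int, rng: np.random.Generator) -> "Conv3x3":
        fan_in = 9 * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        return cls(w.astype(np.float32), np.zeros(c_out, dtype=np.float32))

    def forward(self, x: np.ndarray):
        cols = _im2col3(x)
        out = cols @ self.weight + self.bias
        return out.reshape(x.shape[0], x.shape[1], -1), cols

    def backward(self, dout: np.ndarray, cols: np.ndarray, x_shape):
        h, w, c = x_shape
        dflat = dout.reshape(-1, dout.shape[-1])
        dw = cols.T @ dflat
        db = dflat.sum(axis=0)
        dcols = dflat @ self.weight.T
        return _col2im3(dcols, h, w, c), dw, db


@dataclass
class Conv1x1:
    """Pointwise convolution: a per-location linear map (Cin, Cout)."""

    weight: np.ndarray
    bias: np.ndarray

    @classmethod
    def init(cls, c_in: int, c_out: int, rng: np.random.Generator) -> "Conv1x1":
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out))
        return cls(w.astype(np.float32), np.zeros(c_out, dtype=np.float32))

    def forward(self, x: np.ndarray):
        return x @ self.weight + self.bias, x

    def backward(self, dout: np.ndarray, x: np.ndarray):
        dflat = dout.reshape(-1, dout.shape[-1])
        xflat = x.reshape(-1, x.shape[-1])
        dw = xflat.T @ dflat
        db = dflat.sum(axis=0)
        dx = (dflat @ self.weight.T).reshape(x.shape)
        return dx, dw, db


def softmax_lastaxis(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class InstanceFCN:
    """Stack of 3x3 conv+ReLU layers, a 1x1 embedding layer and a 1x1 class head.

    ``forward`` keeps spatial resolution (h' = h) and returns per-location
    class probabilities; ``forward_cached`` additionally returns the
    intermediate activations needed for :meth:`backward`.  The penultimate
    (post-ReLU) 1x1 feature map is the crop-embedding layer.
    """

    def __init__(self, n_channels: int, n_classes: int, width: int = 32,
                 depth: int = 4, embed_dim: int = 64, seed: int = 0):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        rng = np.random.default_rng(seed)
        self.n_channels = n_channels
        self.n_classes = n_classes
        self.embed_dim = embed_dim
        self.convs = [Conv3x3.init(n_channels if i == 0 else width, width, rng)
                      for i in range(depth)]
        self.embed = Conv1x1.init(width, embed_dim, rng)
        self.head = Conv1x1.init(embed_dim, n_classes, rng)

    # --- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in [*self.convs, self.embed, self.head]:
            out.extend([layer.weight, layer.bias])
        return out

    def set_parameters(self, params: list[np.ndarray]) -> None:
        layers = [*self.convs, self.embed, self.head]
        for i, layer in enumerate(layers):
            layer.weight = params[2 * i].astype(np.float32)
            layer.bias = params[2 * i + 1].astype(np.float32)

    # --- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray):
        """Return (probs (h,h,K), features (h,h,d)) without caching."""
        probs, feat, _ = self._forward(np.asarray(x, dtype=np.float32))
        return probs, feat

    def forward_cached(self, x: np.ndarray):
        return self._forward(np.asarray(x, dtype=np.float32))

    def _forward(self, x: np.ndarray):
        caches = []
        a = x
        for conv in self.convs:
            z, cols = conv.forward(a)
            r = np.maximum(z, 0.0)
            caches.append((a.shape, cols, z))
            a = r
        e_pre, e_in = self.embed.forward(a)
        feat = np.maximum(e_pre, 0.0)
        logits, h_in = self.head.forward(feat)
        probs = softmax_lastaxis(logits)
        cache = {"conv": caches, "embed_in": e_in, "embed_pre": e_pre,
                 "feat": feat, "probs": probs}
        return probs, feat, cache

    def backward(self, cache: dict, dprobs: np.ndarray) -> list[np.ndarray]:
        """Gradients of a scalar loss w.r.t. all parameters, given dL/dprobs."""
        p = cache["probs"]
        # softmax Jacobian applied per location
        dlogits = p * (dprobs - (dprobs * p).sum(axis=-1, keepdims=True))
        grads: list[np.ndarray] = []
        dfeat, dw_h, db_h = self.head.backward(dlogits, cache["feat"])
        dfeat = dfeat * (cache["embed_pre"] > 0)
        dembed_in, dw_e, db_e = self.embed.backward(dfeat, cache["embed_in"])
        da = dembed_in
        conv_grads = []
        for conv, (x_shape, cols, z) in zip(reversed(self.convs),
                                            reversed(cache["conv"])):
            da = da * (z > 0)
            da, dw, db = conv.backward(da, cols, x_shape)
            conv_grads.append((dw, db))
        for dw, db in reversed(conv_grads):
            grads.extend([dw, db])
        grads.extend([dw_e, db_e, dw_h, db_h])
        return grads


class Adam:
    """Adam optimiser over a flat parameter list (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 lr_scales: list[float] | None = None):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.lr_scales = lr_scales if lr_scales is not None else [1.0] * len(params)
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v, scale in zip(self.params, grads, self.m, self.v, self.lr_scales):
            g = g.astype(p.dtype)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= scale * self.lr * mhat / (np.sqrt(vhat) + self.eps)
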