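"""A compact NumPy CNN engine.

Implements exactly the layer set the seizure-detection architecture needs:
2-D convolution (valid/same), batch normalization, ReLU, max pooling with
ceil-mode or same padding, average pooling, dropout, a dense layer, softmax
cross-entropy, the four-branch inception block, and SGD with momentum.

Tensors are NHWC float32. Convolutions use im2col + GEMM; the backward pass
accumulates col2im gradients with a small loop over kernel offsets. Everything
is seeded through :class:`numpy.random.Generator`, so builds and training runs
are bit-reproducible.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool",
    "AvgPool",
    "Dropout",
    "Flatten",
    "Dense",
    "Inception",
    "Sequential",
    "conv_bn_relu",
    "softmax",
    "softmax_cross_entropy",
    "SGDMomentum",
]


def _pair(v) -> tuple[int, int]:
    if isinstance(v, (tuple, list)):
        return int(v[0]), int(v[1])
    return int(v), int(v)


class Layer:
    """Base layer: forward/backward plus parameter access."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def sublayers(self) -> list["Layer"]:
        return []

    def all_layers(self) -> list["Layer"]:
        out = [self]
        for sub in self.sublayers():
            out.extend(sub.all_layers())
        return out


class Conv2D(Layer):
    """2-D convolution (cross-correlation), NHWC, no dilation.

    padding: "valid" (no padding) or "same" (stride-1 only; output spatial
    size equals input).

    Implemented as a loop over kernel offsets (one GEMM per tap); at the small
    channel counts this engine targets that avoids the kh*kw-fold im2col data
    blowup. 1x1 convolutions collapse to a single reshape + GEMM.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel,
        stride=(1, 1),
        padding: str = "valid",
        rng: np.random.Generator | None = None,
        bias: bool = False,
    ) -> None:
        super().__init__()
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride)
        self.in_ch, self.out_ch = in_ch, out_ch
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        if padding == "same" and (self.sh, self.sw) != (1, 1):
            raise ValueError("same padding supported for stride 1 only")
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        fan_in = self.kh * self.kw * in_ch
        self.w = rng.normal(
            0.0, math.sqrt(2.0 / fan_in), (self.kh, self.kw, in_ch, out_ch)
        ).astype(np.float32)
        self.gw = np.zeros_like(self.w)
        self.params = [self.w]
        self.grads = [self.gw]
        self.use_bias = bias
        if bias:
            self.b = np.zeros(out_ch, dtype=np.float32)
            self.gb = np.zeros_like(self.b)
            self.params.append(self.b)
            self.grads.append(self.gb)
        self._cache = None

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.padding == "valid":
            return x
        pt = (self.kh - 1) // 2
        pl = (self.kw - 1) // 2
        return np.pad(x, ((0, 0), (pt, self.kh - 1 - pt), (pl, self.kw - 1 - pl), (0, 0)))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xp = self._pad(np.ascontiguousarray(x, dtype=np.float32))
        n, hp, wp, c = xp.shape
        ho = (hp - self.kh) // self.sh + 1
        wo = (wp - self.kw) // self.sw + 1
        if (self.kh, self.kw, self.sh, self.sw) == (1, 1, 1, 1):
            y = xp.reshape(-1, c) @ self.w.reshape(c, self.out_ch)
            y = y.reshape(n, ho, wo, self.out_ch)
        else:
            y = np.zeros((n, ho, wo, self.out_ch), dtype=np.float32)
            for i in range(self.kh):
                for j in range(self.kw):
                    patch = xp[:, i : i + ho * self.sh : self.sh, j : j + wo * self.sw : self.sw]
                    y += patch @ self.w[i, j]
        if self.use_bias:
            y += self.b
        self._cache = (xp, (n, ho, wo))
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp, (n, ho, wo) = self._cache
        gy = np.ascontiguousarray(gy, dtype=np.float32)
        if (self.kh, self.kw, self.sh, self.sw) == (1, 1, 1, 1):
            g2 = gy.reshape(-1, self.out_ch)
            x2 = xp.reshape(-1, self.in_ch)
            self.gw[...] = (x2.T @ g2).reshape(self.gw.shape)
            gxp = (g2 @ self.w.reshape(self.in_ch, self.out_ch).T).reshape(xp.shape)
        else:
            gxp = np.zeros_like(xp)
            for i in range(self.kh):
                for j in range(self.kw):
                    hs = slice(i, i + ho * self.sh, self.sh)
                    ws = slice(j, j + wo * self.sw, self.sw)
                    self.gw[i, j] = np.tensordot(xp[:, hs, ws], gy, axes=([0, 1, 2], [0, 1, 2]))
                    gxp[:, hs, ws] += gy @ self.w[i, j].T
        if self.use_bias:
            self.gb[...] = gy.reshape(-1, self.out_ch).sum(axis=0)
        if self.padding == "same":
            pt = (self.kh - 1) // 2
            pl = (self.kw - 1) // 2
            h = xp.shape[1] - (self.kh - 1)
            w = xp.shape[2] - (self.kw - 1)
            gxp = gxp[:, pt : pt + h, pl : pl + w, :]
        return gxp


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.params = [self.gamma, self.beta]
        self.grads = [self.ggamma, self.gbeta]
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        shape = x.shape
        x2 = np.ascontiguousarray(x, dtype=np.float32).reshape(-1, shape[-1])
        if train:
            mean = x2.mean(axis=0)
            var = x2.var(axis=0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x2 - mean) * inv_std
        self._cache = (xhat, inv_std, shape) if train else None
        return (self.gamma * xhat + self.beta).reshape(shape)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        g2 = np.ascontiguousarray(gy, dtype=np.float32).reshape(-1, shape[-1])
        m = float(g2.shape[0])
        self.ggamma[...] = np.einsum("ij,ij->j", g2, xhat)
        self.gbeta[...] = g2.sum(axis=0)
        gxhat = g2 * self.gamma
        gx = (gxhat - gxhat.mean(axis=0) - xhat * (self.ggamma * self.gamma / m)) * inv_std
        return gx.reshape(shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0).astype(np.float32, copy=False)


class MaxPool(Layer):
    """Max pooling.

    mode "ceil": output = ceil((in - pool) / stride) + 1, padding the bottom /
    right edge with -inf as needed (so 112 -> 56 with a 3x3 stride-2 pool).
    mode "same": stride must be 1; symmetric padding keeps the spatial size
    (used inside inception blocks).
    """

    def __init__(self, pool, stride=None, mode: str = "ceil") -> None:
        super().__init__()
        self.ph, self.pw = _pair(pool)
        self.sh, self.sw = _pair(stride if stride is not None else pool)
        if mode not in ("ceil", "same"):
            raise ValueError(f"unknown pooling mode {mode!r}")
        if mode == "same" and (self.sh, self.sw) != (1, 1):
            raise ValueError("same pooling requires stride 1")
        self.mode = mode
        self._cache = None

    @staticmethod
    def ceil_out(size: int, pool: int, stride: int) -> int:
        if size < pool:
            raise ValueError(f"input extent {size} smaller than pool {pool}")
        return -((size - pool) // -stride) + 1  # ceil division

    def _geometry(self, h: int, w: int):
        if self.mode == "same":
            ho, wo = h, w
            pt = (self.ph - 1) // 2
            pl = (self.pw - 1) // 2
            pb = self.ph - 1 - pt
            pr = self.pw - 1 - pl
        else:
            ho = self.ceil_out(h, self.ph, self.sh)
            wo = self.ceil_out(w, self.pw, self.sw)
            pt = pl = 0
            pb = (ho - 1) * self.sh + self.ph - h
            pr = (wo - 1) * self.sw + self.pw - w
        return ho, wo, (pt, pb, pl, pr)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo, (pt, pb, pl, pr) = self._geometry(h, w)
        xp = x
        if pt or pb or pl or pr:
            xp = np.pad(
                x, ((0, 0), (pt, pb), (pl, pr), (0, 0)), constant_values=-np.float32(np.inf)
            )
        if (self.sh, self.sw) == (self.ph, self.pw):
            # non-overlapping pool: a reshape groups the windows without copies
            flat = np.ascontiguousarray(xp).reshape(n, ho, self.ph, wo, self.pw, c)
            flat = flat.transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, self.ph * self.pw)
        else:
            v = sliding_window_view(xp, (self.ph, self.pw), axis=(1, 2))[
                :, :: self.sh, :: self.sw
            ]
            flat = np.ascontiguousarray(v).reshape(n, ho, wo, c, self.ph * self.pw)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, (n, h, w, c), (ho, wo), (pt, pl), xp.shape)
        return y.astype(np.float32, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        arg, (n, h, w, c), (ho, wo), (pt, pl), xp_shape = self._cache
        gxp = np.zeros(xp_shape, dtype=np.float32)
        n_i = np.arange(n)[:, None, None, None]
        h_i = np.arange(ho)[None, :, None, None]
        w_i = np.arange(wo)[None, None, :, None]
        c_i = np.arange(c)[None, None, None, :]
        gi = h_i * self.sh + arg // self.pw
        gj = w_i * self.sw + arg % self.pw
        np.add.at(gxp, (n_i, gi, gj, c_i), gy.astype(np.float32, copy=False))
        return gxp[:, pt : pt + h, pl : pl + w, :]


class AvgPool(Layer):
    """Average pooling, valid padding (exact fit required)."""

    def __init__(self, pool, stride=None) -> None:
        super().__init__()
        self.ph, self.pw = _pair(pool)
        self.sh, self.sw = _pair(stride if stride is not None else pool)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if (h - self.ph) % self.sh or (w - self.pw) % self.sw:
            raise ValueError("average pooling requires an exact fit")
        v = sliding_window_view(x, (self.ph, self.pw), axis=(1, 2))[:, :: self.sh, :: self.sw]
        self._in_shape = x.shape
        return v.mean(axis=(-2, -1)).astype(np.float32, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        gx = np.zeros(self._in_shape, dtype=np.float32)
        scale = 1.0 / (self.ph * self.pw)
        ho, wo = gy.shape[1], gy.shape[2]
        for i in range(self.ph):
            for j in range(self.pw):
                gx[:, i : i + ho * self.sh : self.sh, j : j + wo * self.sw : self.sw, :] += (
                    gy * scale
                )
        return gx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator = np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy if self._mask is None else gy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, math.sqrt(2.0 / in_dim), (in_dim, out_dim)).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.params = [self.w, self.b]
        self.grads = [self.gw, self.gb]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.gw[...] = self._x.T @ gy
        self.gb[...] = gy.sum(axis=0)
        return (gy @ self.w.T).astype(np.float32, copy=False)


class Inception(Layer):
    """Four-branch inception block (channel-axis concatenation).

    Branches: 1x1 conv; 1x1 -> 3x3; 1x1 -> 5x5; 3x3 same max pool -> 1x1.
    Every convolution is followed by batch normalization and ReLU; spatial
    size is preserved (same padding), so the block holds 6 convolutions.
    """

    def __init__(
        self,
        in_ch: int,
        b1: int,
        b2: tuple[int, int],
        b3: tuple[int, int],
        b4: int,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.branches: list[list[Layer]] = [
            conv_bn_relu(in_ch, b1, (1, 1), padding="same", rng=rng),
            conv_bn_relu(in_ch, b2[0], (1, 1), padding="same", rng=rng)
            + conv_bn_relu(b2[0], b2[1], (3, 3), padding="same", rng=rng),
            conv_bn_relu(in_ch, b3[0], (1, 1), padding="same", rng=rng)
            + conv_bn_relu(b3[0], b3[1], (5, 5), padding="same", rng=rng),
            [MaxPool((3, 3), stride=(1, 1), mode="same")]
            + conv_bn_relu(in_ch, b4, (1, 1), padding="same", rng=rng),
        ]
        self.splits = [b1, b2[1], b3[1], b4]
        self.out_ch = sum(self.splits)

    def sublayers(self) -> list[Layer]:
        return [l for branch in self.branches for l in branch]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        outs = []
        for branch in self.branches:
            h = x
            for layer in branch:
                h = layer.forward(h, train)
            outs.append(h)
        return np.concatenate(outs, axis=-1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = None
        offset = 0
        for branch, width in zip(self.branches, self.splits):
            g = np.ascontiguousarray(gy[..., offset : offset + width])
            offset += width
            for layer in reversed(branch):
                g = layer.backward(g)
            gx = g if gx is None else gx + g
        return gx


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        super().__init__()
        self.layers = list(layers)

    def sublayers(self) -> list[Layer]:
        return self.layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


def conv_bn_relu(
    in_ch: int,
    out_ch: int,
    kernel,
    stride=(1, 1),
    padding: str = "valid",
    rng: np.random.Generator | None = None,
) -> list[Layer]:
    """Convolution -> batch normalization -> ReLU triple."""
    return [
        Conv2D(in_ch, out_ch, kernel, stride=stride, padding=padding, rng=rng, bias=False),
        BatchNorm(out_ch),
        ReLU(),
    ]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted mean cross-entropy; returns (loss, probabilities, grad wrt logits)."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    w = np.ones(n) if class_weights is None else class_weights[labels]
    wsum = w.sum()
    ll = -np.log(np.maximum(p[np.arange(n), labels], 1e-12))
    loss = float((w * ll).sum() / wsum)
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, p, grad.astype(np.float32)


class SGDMomentum:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, layers: Sequence[Layer], lr: float, momentum: float = 0.9) -> None:
        self.pairs: list[tuple[np.ndarray, np.ndarray]] = []
        for layer in layers:
            for root in [layer]:
                for sub in root.all_layers():
                    self.pairs.extend(zip(sub.params, sub.grads))
        self.velocity = [np.zeros_like(p) for p, _ in self.pairs]
        self.lr = lr
        self.momentum = momentum

    def step(self) -> None:
        for (p, g), v in zip(self.pairs, self.velocity):
            v *= self.momentum
            v += g
            p -= self.lr * v
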