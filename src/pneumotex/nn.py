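"""Minimal neural-network layer stack with reverse-mode gradients.

Layers operate on float32 numpy arrays in NCHW layout and implement an
explicit ``forward``/``backward`` pair; parameter gradients are accumulated
on :class:`Param` objects. Convolutions go through an im2col expansion so
the inner products run in BLAS. Gradient correctness of every layer and of
the texture-encoding head is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Linear",
    "L2Normalize",
    "TextureEncoding",
    "Adam",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    @property
    def shape(self):
        return self.value.shape


class Layer:
    """Base layer: subclasses define forward(x, train) and backward(dout)."""

    def params(self) -> list[tuple[str, Param]]:
        return []

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(xpad: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """Expand padded NCHW input into (C*k*k, B*oh*ow) patch columns.

    The channel-major layout lets the whole batch run as one GEMM.
    """
    b, c, _, _ = xpad.shape
    cols = np.empty((c, k, k, b, oh, ow), dtype=xpad.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, ki, kj] = xpad[:, :, ki : ki + stride * oh : stride,
                                   kj : kj + stride * ow : stride].transpose(1, 0, 2, 3)
    return cols.reshape(c * k * k, b * oh * ow)


def _col2im(dcols: np.ndarray, xpad_shape, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """Scatter-add patch-column gradients back onto the padded input."""
    b, c, hp, wp = xpad_shape
    dxpad = np.zeros(xpad_shape, dtype=dcols.dtype)
    dcols = dcols.reshape(c, k, k, b, oh, ow)
    for ki in range(k):
        for kj in range(k):
            dxpad[:, :, ki : ki + stride * oh : stride,
                  kj : kj + stride * ow : stride] += dcols[:, ki, kj].transpose(1, 0, 2, 3)
    return dxpad


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        # He-normal initialization, standard for ReLU networks
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_ch)) if bias else None
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache = None

    def params(self):
        out = [("weight", self.weight)]
        if self.bias is not None:
            out.append(("bias", self.bias))
        return out

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        k, s, p = self.kernel, self.stride, self.pad
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xpad, k, s, oh, ow)               # (ckk, b*oh*ow)
        wm = self.weight.value.reshape(self.out_ch, -1)
        out = wm @ cols                                   # one GEMM for the batch
        if self.bias is not None:
            out += self.bias.value[:, None]
        self._cache = (cols, xpad.shape, (b, c, h, w), oh, ow)
        return np.ascontiguousarray(
            out.reshape(self.out_ch, b, oh, ow).transpose(1, 0, 2, 3))

    def backward(self, dout):
        cols, xpad_shape, xshape, oh, ow = self._cache
        b = xshape[0]
        k, s, p = self.kernel, self.stride, self.pad
        dcat = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(self.out_ch, -1)
        self.weight.grad += (dcat @ cols.T).reshape(self.weight.shape)
        if self.bias is not None:
            self.bias.grad += dcat.sum(axis=1)
        wm = self.weight.value.reshape(self.out_ch, -1)
        dcols = wm.T @ dcat
        dxpad = _col2im(dcols, xpad_shape, k, s, oh, ow)
        if p:
            return dxpad[:, :, p:-p, p:-p]
        return dxpad


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def buffers(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout):
        xhat, inv, train, shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return dout * g * inv[None, :, None, None]
        n = shape[0] * shape[2] * shape[3]
        dxhat = dout * g
        # standard batchnorm backward through the batch statistics
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx * inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        stack = np.empty((b, c, k * k, oh, ow), dtype=x.dtype)
        t = 0
        for ki in range(k):
            for kj in range(k):
                stack[:, :, t] = xpad[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s]
                t += 1
        idx = stack.argmax(axis=2)
        out = np.take_along_axis(stack, idx[:, :, None], axis=2)[:, :, 0]
        self._cache = (idx, xpad.shape, (b, c, h, w), oh, ow)
        return out

    def backward(self, dout):
        idx, xpad_shape, xshape, oh, ow = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        dxpad = np.zeros(xpad_shape, dtype=dout.dtype)
        t = 0
        for ki in range(k):
            for kj in range(k):
                dxpad[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s] += dout * (idx == t)
                t += 1
        if p:
            return dxpad[:, :, p:-p, p:-p]
        return dxpad


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_dim)
        self.weight = Param(rng.uniform(-bound, bound, size=(out_dim, in_dim)))
        self.bias = Param(np.zeros(out_dim))
        self._x = None

    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout):
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value


class L2Normalize(Layer):
    """Row-wise L2 normalization of a (B, d) matrix."""

    def __init__(self, eps: float = 1e-12):
        self.eps = eps
        self._cache = None

    def forward(self, x, train=False):
        norm = np.sqrt((x * x).sum(axis=1, keepdims=True)) + self.eps
        y = x / norm
        self._cache = (y, norm)
        return y

    def backward(self, dout):
        y, norm = self._cache
        return (dout - y * (dout * y).sum(axis=1, keepdims=True)) / norm


class TextureEncoding(Layer):
    """Residual encoding against a learnable codebook with channel suppression.

    Input is a batch of descriptor sets (B, N, C); output is the batch of
    K x C encodings (B, K, C).  Residuals r_ij = x_i - d_j are softly
    assigned with weights softmax_j(-s_j ||r_ij||^2), aggregated per
    codeword, and the per-channel maximum of the encoding is damped by the
    suppression factor ``lam``.
    """

    def __init__(self, codewords: int, channels: int, lam: float = 1.0,
                 rng: np.random.Generator | None = None):
        if not 0.0 < lam <= 1.0:
            raise ValueError(f"suppression factor must be in (0, 1], got {lam}")
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(codewords)
        self.codewords = Param(rng.uniform(-bound, bound, size=(codewords, channels)))
        self.smoothing = Param(rng.uniform(0.0, 1.0, size=codewords))
        self.lam = float(lam)
        self.k, self.c = codewords, channels
        self._cache = None

    def params(self):
        return [("codewords", self.codewords), ("smoothing", self.smoothing)]

    def forward(self, x, train=False):
        if x.ndim != 3 or x.shape[2] != self.c:
            raise ValueError(f"expected descriptors of shape (B, N, {self.c}), got {x.shape}")
        d = self.codewords.value
        s = self.smoothing.value
        r = x[:, :, None, :] - d[None, None, :, :]          # (B, N, K, C)
        n = np.einsum("bnkc,bnkc->bnk", r, r)               # squared norms
        a = -s[None, None, :] * n
        a -= a.max(axis=2, keepdims=True)                    # log-sum-exp shift
        ex = np.exp(a)
        w = ex / ex.sum(axis=2, keepdims=True)               # (B, N, K)
        e = np.einsum("bnk,bnkc->bkc", w, r)                 # (B, K, C)
        # suppression: damp the (first) per-channel maximum by lam
        p = np.ones_like(e)
        idx = e.argmax(axis=1)                               # (B, C)
        np.put_along_axis(p, idx[:, None, :], self.lam, axis=1)
        self._cache = (r, n, w, p)
        return p * e

    def backward(self, dout):
        r, n, w, p = self._cache
        s = self.smoothing.value
        de = p * dout                                        # suppression mask is locally constant
        dw = np.einsum("bkc,bnkc->bnk", de, r)
        dr = w[:, :, :, None] * de[:, None, :, :]
        da = w * (dw - (dw * w).sum(axis=2, keepdims=True))  # softmax backward
        self.smoothing.grad += -(da * n).sum(axis=(0, 1))
        dn = -da * s[None, None, :]
        dr += 2.0 * r * dn[:, :, :, None]
        self.codewords.grad += -dr.sum(axis=(0, 1))
        return dr.sum(axis=2)


class Adam:
    """Adam optimizer over a list of Params."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
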