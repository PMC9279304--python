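"""Minimal 3D convolutional network engine on numpy.

Layers operate on single samples of shape ``(C, D, H, W)`` (batch size 1,
which is also the training batch size used by the pipeline).  Every layer
implements ``forward(x)`` and ``backward(grad_out)``; parameter gradients
accumulate into ``Param.grad`` and are consumed by :class:`Adam`.

Convolutions use im2col + BLAS matmul; the col2im scatter in the backward
pass is vectorized as a sum over the 27 kernel offsets.  float32 throughout.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, kernel ``k``, stride 1, 'same' zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        fan_in = in_channels * kernel**3
        # He initialization for ReLU networks
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, fan_in))
        self.w = Param(w)
        self.b = Param(np.zeros(out_channels))
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def parameters(self):
        return [self.w, self.b]

    @staticmethod
    def _offsets(k: int):
        return [(dz, dy, dx) for dz in range(k) for dy in range(k) for dx in range(k)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        assert c == self.cin, (c, self.cin)
        k, p = self.k, self.k // 2
        n = d * h * w
        if k == 1:
            cols = x.reshape(c, n).astype(np.float32, copy=False)
        else:
            xp = np.pad(x.astype(np.float32, copy=False),
                        ((0, 0), (p, p), (p, p), (p, p)))
            # column matrix ordered (channel, kernel offset) to match w layout
            cols3 = np.empty((c, k**3, n), dtype=np.float32)
            for o, (dz, dy, dx) in enumerate(self._offsets(k)):
                cols3[:, o, :] = xp[:, dz:dz + d, dy:dy + h, dx:dx + w].reshape(c, n)
            cols = cols3.reshape(c * k**3, n)
        out = self.w.value @ cols + self.b.value[:, None]
        self._cols, self._shape = cols, (c, d, h, w)
        return out.reshape(self.cout, d, h, w)

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        c, d, h, w = self._shape
        k, p = self.k, self.k // 2
        n = d * h * w
        g = grad.reshape(self.cout, n).astype(np.float32, copy=False)
        self.w.grad += g @ self._cols.T
        self.b.grad += g.sum(axis=1)
        if not need_input_grad:
            self._cols = None
            return None
        dcols = (self.w.value.T @ g).reshape(c, k**3, n)
        if k == 1:
            dx_ = dcols.reshape(c, d, h, w)
        else:
            dxp = np.zeros((c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=np.float32)
            for o, (dz, dy, dx) in enumerate(self._offsets(k)):
                dxp[:, dz:dz + d, dy:dy + h, dx:dx + w] += dcols[:, o, :].reshape(
                    c, d, h, w)
            dx_ = dxp[:, p:p + d, p:p + h, p:p + w]
        self._cols = None
        return np.ascontiguousarray(dx_)


class InstanceNorm3d(Layer):
    """Per-channel normalization over the spatial axes, with affine scale/shift."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mu) * inv
        self._cache = (xhat, inv, x.shape)
        out = self.gamma.value[:, None] * xhat + self.beta.value[:, None]
        return out.reshape(x.shape).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        c = shape[0]
        g = grad.reshape(c, -1).astype(np.float32)
        self.gamma.grad += (g * xhat).sum(axis=1)
        self.beta.grad += g.sum(axis=1)
        n = g.shape[1]
        gg = self.gamma.value[:, None] * g
        dx = inv / n * (n * gg - gg.sum(axis=1, keepdims=True)
                        - xhat * (gg * xhat).sum(axis=1, keepdims=True))
        return dx.reshape(shape).astype(np.float32)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2x2x2 max pooling; spatial dims must be even.  Ties go to the first
    voxel of the block (fixed order, so backward is deterministic)."""

    def forward(self, x):
        c, d, h, w = x.shape
        assert d % 2 == 0 and h % 2 == 0 and w % 2 == 0, x.shape
        blocks = np.ascontiguousarray(
            x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).transpose(
                0, 1, 3, 5, 2, 4, 6)).reshape(-1, 8)
        idx = blocks.argmax(axis=1)
        out = blocks[np.arange(blocks.shape[0]), idx]
        self._idx, self._shape = idx, x.shape
        return out.reshape(c, d // 2, h // 2, w // 2).astype(np.float32)

    def backward(self, grad):
        c, d, h, w = self._shape
        g = np.zeros((self._idx.size, 8), dtype=np.float32)
        g[np.arange(self._idx.size), self._idx] = grad.ravel()
        return np.ascontiguousarray(
            g.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2).transpose(
                0, 1, 4, 2, 5, 3, 6)).reshape(c, d, h, w)


class ConvTranspose2x(Layer):
    """2x2x2 transposed convolution with stride 2 (the U-Net up-convolution).

    Each input voxel expands into a 2x2x2 output block; offset ``o`` of the
    block is produced by its own (cout, cin) weight matrix.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.cin, self.cout = in_channels, out_channels
        w = rng.normal(0.0, np.sqrt(2.0 / in_channels), (8, out_channels, in_channels))
        self.w = Param(w)
        self.b = Param(np.zeros(out_channels))

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x):
        c, d, h, w = x.shape
        flat = x.reshape(c, -1).astype(np.float32, copy=False)
        out = np.empty((self.cout, 2 * d, 2 * h, 2 * w), dtype=np.float32)
        for o in range(8):
            oz, oy, ox = o >> 2 & 1, o >> 1 & 1, o & 1
            out[:, oz::2, oy::2, ox::2] = (
                self.w.value[o] @ flat + self.b.value[:, None]).reshape(
                self.cout, d, h, w)
        self._flat, self._shape = flat, (c, d, h, w)
        return out

    def backward(self, grad):
        c, d, h, w = self._shape
        dx = np.zeros((c, d * h * w), dtype=np.float32)
        for o in range(8):
            oz, oy, ox = o >> 2 & 1, o >> 1 & 1, o & 1
            go = np.ascontiguousarray(
                grad[:, oz::2, oy::2, ox::2]).reshape(self.cout, -1)
            self.w.grad[o] += go @ self._flat.T
            self.b.grad += go.sum(axis=1)
            dx += self.w.value[o].T @ go
        self._flat = None
        return dx.reshape(c, d, h, w)


class ConvBlock(Layer):
    """Conv -> InstanceNorm -> ReLU, twice."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.layers = [
            Conv3d(cin, cout, 3, rng), InstanceNorm3d(cout), ReLU(),
            Conv3d(cout, cout, 3, rng), InstanceNorm3d(cout), ReLU(),
        ]

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad, need_input_grad: bool = True):
        for l in self.layers[:0:-1]:
            grad = l.backward(grad)
        return self.layers[0].backward(grad, need_input_grad=need_input_grad)


class Softmax:
    """Numerically stable softmax over the class axis (axis 0)."""

    @staticmethod
    def forward(scores: np.ndarray) -> np.ndarray:
        dtype = scores.dtype if np.issubdtype(scores.dtype, np.floating) else np.float32
        s = scores - scores.max(axis=0, keepdims=True)
        e = np.exp(s, dtype=np.float64)
        return (e / e.sum(axis=0, keepdims=True)).astype(dtype)

    @staticmethod
    def backward(probs: np.ndarray, grad_probs: np.ndarray) -> np.ndarray:
        dot = (probs * grad_probs).sum(axis=0, keepdims=True)
        return (probs * (grad_probs - dot)).astype(np.float32)


class Adam:
    """Adam optimizer with externally supplied per-step learning rate."""

    def __init__(self, params: list[Param], betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
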