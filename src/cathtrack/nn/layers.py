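"""Layer primitives with analytic forward/backward passes.

All tensors are channels-last ``(N, H, W, C)`` arrays: with this layout the
im2col gather and scatter reduce to contiguous strided copies and the
convolution itself to a single BLAS matrix product, which is what keeps
CPU-only training practical.  Each layer caches what its backward pass needs
during ``forward(..., training=True)``; ``backward`` consumes the cache and
accumulates parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    """Base class: parameter/buffer discovery is by attribute recursion."""

    def params(self) -> list[Param]:
        out = []
        for attr in vars(self).values():
            if isinstance(attr, Param):
                out.append(attr)
            elif isinstance(attr, Module):
                out.extend(attr.params())
            elif isinstance(attr, (list, tuple)):
                for a in attr:
                    if isinstance(a, Module):
                        out.extend(a.params())
        return out

    def buffers(self) -> list[np.ndarray]:
        out = []
        for attr in vars(self).values():
            if isinstance(attr, Module):
                out.extend(attr.buffers())
            elif isinstance(attr, (list, tuple)):
                for a in attr:
                    if isinstance(a, Module):
                        out.extend(a.buffers())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Conv2d(Module):
    """2D convolution (cross-correlation), 'same' padding for odd kernels.

    The weight is stored as a ``(k*k*in_ch, out_ch)`` matrix so the forward
    pass is ``im2col(x) @ W``.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng()
        k = kernel
        # He initialisation for ReLU networks
        std = np.sqrt(2.0 / (in_ch * k * k))
        self.W = Param(rng.normal(0.0, std, (k * k * in_ch, out_ch)).astype(dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype)) if bias else None
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.kernel = k
        self.stride = stride
        self.pad = k // 2
        self._cache = None

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        k, s, c = self.kernel, self.stride, self.in_ch
        n = xp.shape[0]
        if k == 1 and s == 1:
            return xp
        cols = np.empty((n, ho, wo, k * k * c), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                patch = xp[:, i:i + s * ho:s, j:j + s * wo:s, :]
                cols[..., (i * k + j) * c:(i * k + j + 1) * c] = patch
        return cols

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        n, hp, wp, _ = xp.shape
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        cols = self._im2col(xp, ho, wo)
        y = cols.reshape(-1, self.W.value.shape[0]) @ self.W.value
        y = y.reshape(n, ho, wo, self.out_ch)
        if self.b is not None:
            y += self.b.value
        if training:
            self._cache = (cols, xp.shape, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xpshape, xshape = self._cache
        k, s, p, c = self.kernel, self.stride, self.pad, self.in_ch
        n, ho, wo, _ = dy.shape
        dy2 = dy.reshape(-1, self.out_ch)
        self.W.grad += cols.reshape(-1, self.W.value.shape[0]).T @ dy2
        if self.b is not None:
            self.b.grad += dy2.sum(axis=0)
        dcols = (dy2 @ self.W.value.T).reshape(n, ho, wo, k * k * c)
        if k == 1 and s == 1:
            dxp = dcols
        else:
            dxp = np.zeros(xpshape, dtype=dy.dtype)
            for i in range(k):
                for j in range(k):
                    dxp[:, i:i + s * ho:s, j:j + s * wo:s, :] += \
                        dcols[..., (i * k + j) * c:(i * k + j + 1) * c]
        if p:
            dxp = dxp[:, p:p + xshape[1], p:p + xshape[2], :]
        return dxp


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(ch, dtype=dtype))
        self.beta = Param(np.zeros(ch, dtype=dtype))
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean) * invstd
        if training:
            self._cache = (xhat, invstd)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        # standard batch-norm gradient through the batch statistics
        return (invstd / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Upsample2x(Module):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Adam:
    """Adaptive-moment-estimation optimiser over a parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
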