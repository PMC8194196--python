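"""Minimal numpy neural-network core.

Implements the handful of layers the framework needs (2-D convolution via
im2col, pooling, batch normalisation, linear head) with explicit manual
backpropagation and an Adam optimiser.  Layers operate on ``[N, C, H, W]``
batches.  Every layer caches what its backward pass needs during ``forward``,
so a ``forward``/``backward`` pair must be called in sequence for a given
step (the usual training-loop discipline).

All parameter initialisation is driven by an explicit ``numpy.random.Generator``
so that whole networks are reproducible from a single integer seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as _fft

DEFAULT_DTYPE = np.float32


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    training: bool = True

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for v in vars(self).values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for v in vars(self).values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- flat state for checkpointing ------------------------------------
    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)} parameters")
        for p, v in zip(params, state):
            if p.value.shape != v.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {v.shape}")
            p.value[...] = v


def _reflect_fold(d: np.ndarray, p: int, axis: int) -> np.ndarray:
    """Adjoint of ``np.pad(mode='reflect')`` along one axis: fold the
    gradient of the padded positions back onto their source elements and
    strip the padding."""
    if p == 0:
        return d
    d = np.moveaxis(d, axis, 0)
    out = d[p:-p].copy()
    out[1:p + 1] += d[:p][::-1]
    out[-p - 1:-1] += d[-p:][::-1]
    return np.moveaxis(out, 0, axis)


class Conv2d(Module):
    """2-D convolution (cross-correlation), stride >= 1, symmetric padding.

    Default padding ``(k - 1) // 2`` preserves the spatial size at stride 1
    for odd kernels.  ``pad_mode='reflect'`` mirrors the border instead of
    zero-filling, which removes the absolute-position signature that zero
    borders give edge receptive fields.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=DEFAULT_DTYPE,
                 pad_mode: str = "zeros"):
        if kernel_size < 1 or stride < 1:
            raise ValueError("kernel_size and stride must be >= 1")
        if pad_mode not in ("zeros", "reflect"):
            raise ValueError(f"unknown pad_mode '{pad_mode}'")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.pad = (kernel_size - 1) // 2 if padding is None else padding
        self.pad_mode = pad_mode
        self._reflect = False
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Param(_fan_in_uniform(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in, dtype))
        self.bias = Param(_fan_in_uniform(rng, (out_channels,), fan_in, dtype)) if bias else None
        self._cache = None

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k, s, p = self.k, self.stride, self.pad
        if h + 2 * p < k or w + 2 * p < k:
            raise ValueError("input smaller than kernel")
        self._reflect = self.pad_mode == "reflect" and p > 0
        if self._reflect:
            # pre-pad by reflection and run the padding-free path; position is
            # then invisible to the filter (no zero border signature)
            xr = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="reflect")
            self.pad = 0
            try:
                out = self._fft_forward(xr) if (s == 1 and k >= 5) else self._plain_forward(xr)
            finally:
                self.pad = p
            self._orig_hw = (h, w)
            return out
        if s == 1 and k >= 5:
            return self._fft_forward(x)
        return self._plain_forward(x)

    def _plain_forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, c * k * k)
        wmat = self.weight.value.reshape(self.out_channels, -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.value
        self._cache = ("im2col", cols, x.shape, (ho, wo))
        return np.ascontiguousarray(out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2))

    # -- FFT path for large stride-1 kernels (attention-scale convolutions):
    # im2col materialises H*W*(C*k*k) columns, which is memory-bound for
    # k in {5,7,9}; the convolution theorem does the same contraction in
    # O(HW log HW) with small constants.
    def _fft_forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        hp, wp = h + 2 * p, w + 2 * p
        ho, wo = hp - k + 1, wp - k + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        fx = _fft.rfft2(xp, s=(hp, wp))
        fk = _fft.rfft2(self.weight.value[:, :, ::-1, ::-1], s=(hp, wp))
        out = _fft.irfft2(np.einsum("ncyx,ocyx->noyx", fx, fk), s=(hp, wp))
        out = out[:, :, k - 1:k - 1 + ho, k - 1:k - 1 + wo].astype(x.dtype)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None]
        self._cache = ("fft", fx, x.shape, (ho, wo))
        return np.ascontiguousarray(out)

    def _fft_backward(self, dy: np.ndarray, need_input_grad: bool) -> np.ndarray | None:
        _, fx, xshape, (ho, wo) = self._cache
        n, c, h, w = xshape
        k, p = self.k, self.pad
        hp, wp = h + 2 * p, w + 2 * p
        fdy = _fft.rfft2(dy, s=(hp, wp))
        dw = _fft.irfft2(np.einsum("ncyx,noyx->ocyx", fx, np.conj(fdy)), s=(hp, wp))
        self.weight.grad += dw[:, :, :k, :k].astype(self.weight.value.dtype)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        if not need_input_grad:
            return None
        fw = _fft.rfft2(self.weight.value, s=(hp, wp))
        dxp = _fft.irfft2(np.einsum("noyx,ocyx->ncyx", fdy, fw), s=(hp, wp))
        dx = dxp[:, :, p:p + h, p:p + w] if p else dxp[:, :, :h, :w]
        return np.ascontiguousarray(dx.astype(dy.dtype))

    def backward(self, dy: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        if self._reflect:
            p = self.pad
            self.pad = 0
            try:
                dxp = (self._fft_backward(dy, need_input_grad)
                       if self._cache[0] == "fft" else self._plain_backward(dy, need_input_grad))
            finally:
                self.pad = p
            if not need_input_grad:
                return None
            return _reflect_fold(_reflect_fold(dxp, p, 2), p, 3)
        if self._cache[0] == "fft":
            return self._fft_backward(dy, need_input_grad)
        return self._plain_backward(dy, need_input_grad)

    def _plain_backward(self, dy: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        _, cols, xshape, (ho, wo) = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * ho * wo, self.out_channels)
        self.weight.grad += (dy2.T @ cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dy2.sum(axis=0)
        if not need_input_grad:
            return None
        if s == 1:
            # dx is a full correlation of dy with the spatially flipped kernel,
            # so reuse the im2col matmul path instead of a python offset loop
            q = k - 1 - p
            dyp = np.pad(dy, ((0, 0), (0, 0), (q, q), (q, q))) if q else dy
            win = sliding_window_view(dyp, (k, k), axis=(2, 3))
            gcols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, -1)
            wflip = self.weight.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(c, -1)
            return np.ascontiguousarray(
                (gcols @ wflip.T).reshape(n, h, w, c).transpose(0, 3, 1, 2))
        dcols = dy2 @ self.weight.value.reshape(self.out_channels, -1)
        d6 = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += d6[:, :, :, :, ki, kj]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=DEFAULT_DTYPE):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Param(_fan_in_uniform(rng, (out_features, in_features), in_features, dtype))
        self.bias = Param(_fan_in_uniform(rng, (out_features,), in_features, dtype))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = sigmoid(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=np.result_type(x, np.float32))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class AvgPool2d(Module):
    """Non-overlapping 2x2 average pooling (spatial sizes must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("AvgPool2d expects even spatial sizes")
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * 0.25


class MaxPool2d(Module):
    """Max pooling with kernel/stride/padding (used by the dense backbone stem)."""

    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        self.k, self.stride, self.pad = kernel_size, stride, padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, ho, wo, k * k)
        self._arg = flat.argmax(axis=-1)
        self._meta = (x.shape, xp.shape, ho, wo)
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (n, c, h, w), xpshape, ho, wo = self._meta
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros((n, c, xpshape[2] * xpshape[3]), dtype=dy.dtype)
        oy, ox = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        base_y = oy * s
        base_x = ox * s
        ky = self._arg // k
        kx = self._arg % k
        flat_idx = (base_y[None, None] + ky) * xpshape[3] + (base_x[None, None] + kx)
        np.add.at(dxp, (np.arange(n)[:, None, None, None], np.arange(c)[None, :, None, None], flat_idx), dy)
        dxp = dxp.reshape(n, c, xpshape[2], xpshape[3])
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1, dtype=DEFAULT_DTYPE):
        self.gamma = Param(np.ones(num_features, dtype=dtype))
        self.beta = Param(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return (self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        if self.training:
            t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = (inv[None, :, None, None] / m) * (m * dxhat - t1 - xhat * t2)
        else:
            dx = dxhat * inv[None, :, None, None]
        return dx.astype(dy.dtype)


class Upsample2x(Module):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with decoupled-style L2 (gradient-side weight decay, as in classic Adam)."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.value -= update.astype(p.value.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
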