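"""3D convolution, pooling and batch normalization for (N, C, D, H, W) arrays."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Parameter, _kaiming

__all__ = ["Conv3d", "MaxPool3d", "AvgPool3d", "BatchNorm3d"]

Triple = Tuple[int, int, int]


def _triple(v) -> Triple:
    if isinstance(v, int):
        return (v, v, v)
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected int or 3-tuple, got {v!r}")
    return t


def _out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def _windows(xp: np.ndarray, kernel: Triple, stride: Triple) -> np.ndarray:
    """(N, C, Do, Ho, Wo, kd, kh, kw) sliding windows of a padded input."""
    win = sliding_window_view(xp, kernel, axis=(2, 3, 4))
    return win[:, :, :: stride[0], :: stride[1], :: stride[2]]


class Conv3d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size,
        stride=1,
        padding=0,
        rng: Optional[np.random.Generator] = None,
        bias: bool = False,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        fan_in = in_channels * int(np.prod(self.kernel))
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = self.register(
            "weight",
            Parameter(_kaiming(rng, (out_channels, in_channels) + self.kernel, fan_in)),
        )
        self.bias = self.register("bias", Parameter(np.zeros(out_channels))) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.weight.data.dtype)
        n, c, d, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        pd, ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        win = _windows(xp, self.kernel, self.stride)
        do, ho, wo = win.shape[2:5]
        # (N*Do*Ho*Wo, C*kd*kh*kw) @ (C*k^3, Co)
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * do * ho * wo, -1)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.data
        out = out.reshape(n, do, ho, wo, self.out_channels).transpose(0, 4, 1, 2, 3)
        self._cache = (cols, x.shape, (do, ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xshape, (do, ho, wo) = self._cache
        n, c, d, h, w = xshape
        dtype = self.weight.data.dtype
        gmat = np.ascontiguousarray(
            grad.transpose(0, 2, 3, 4, 1).reshape(-1, self.out_channels), dtype=dtype
        )
        self.weight.grad += (gmat.T @ cols).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += gmat.sum(axis=0)
        pd, ph, pw = self.padding
        sd, sh, sw = self.stride
        dxp = np.zeros((n, c, d + 2 * pd, h + 2 * ph, w + 2 * pw), dtype=dtype)
        wk = self.weight.data.reshape(self.out_channels, c, -1)
        offset = 0
        for i in range(self.kernel[0]):
            for j in range(self.kernel[1]):
                for k in range(self.kernel[2]):
                    contrib = (gmat @ wk[:, :, offset]).reshape(n, do, ho, wo, c)
                    dxp[
                        :,
                        :,
                        i : i + sd * do : sd,
                        j : j + sh * ho : sh,
                        k : k + sw * wo : sw,
                    ] += contrib.transpose(0, 4, 1, 2, 3)
                    offset += 1
        return dxp[:, :, pd : pd + d, ph : ph + h, pw : pw + w]


class MaxPool3d(Module):
    def __init__(self, kernel_size, stride, padding=0):
        super().__init__()
        self.kernel = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        pd, ph, pw = self.padding
        xp = np.pad(
            x,
            ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)),
            constant_values=-np.inf,
        )
        win = _windows(xp, self.kernel, self.stride)
        do, ho, wo = win.shape[2:5]
        flat = win.reshape(n, c, do, ho, wo, -1)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, x.shape, (do, ho, wo))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        arg, xshape, (do, ho, wo) = self._cache
        n, c, d, h, w = xshape
        pd, ph, pw = self.padding
        sd, sh, sw = self.stride
        dp, hp, wp = d + 2 * pd, h + 2 * ph, w + 2 * pw
        ki, kj, kk = np.unravel_index(arg, self.kernel)
        zi = ki + sd * np.arange(do)[None, None, :, None, None]
        yi = kj + sh * np.arange(ho)[None, None, None, :, None]
        xi = kk + sw * np.arange(wo)[None, None, None, None, :]
        ni = np.arange(n)[:, None, None, None, None]
        ci = np.arange(c)[None, :, None, None, None]
        flat = (((ni * c + ci) * dp + zi) * hp + yi) * wp + xi
        acc = np.bincount(
            flat.ravel(), weights=grad.ravel(), minlength=n * c * dp * hp * wp
        )
        dxp = acc.reshape(n, c, dp, hp, wp).astype(grad.dtype)
        return dxp[:, :, pd : pd + d, ph : ph + h, pw : pw + w]


class AvgPool3d(Module):
    """Non-overlapping average pooling (kernel == stride)."""

    def __init__(self, kernel_size, stride=None):
        super().__init__()
        self.kernel = _triple(kernel_size)
        stride = self.kernel if stride is None else _triple(stride)
        if stride != self.kernel:
            raise ValueError("AvgPool3d supports kernel == stride only")
        self._xshape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        kd, kh, kw = self.kernel
        if d % kd or h % kh or w % kw:
            raise ValueError(f"input {x.shape} not divisible by kernel {self.kernel}")
        self._xshape = x.shape
        return x.reshape(n, c, d // kd, kd, h // kh, kh, w // kw, kw).mean(axis=(3, 5, 7))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kd, kh, kw = self.kernel
        scale = 1.0 / (kd * kh * kw)
        g = grad[:, :, :, None, :, None, :, None] * scale
        return np.broadcast_to(
            g,
            grad.shape[:2]
            + (grad.shape[2], kd, grad.shape[3], kh, grad.shape[4], kw),
        ).reshape(self._xshape)


class BatchNorm3d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.register("gamma", Parameter(np.ones(num_features)))
        self.beta = self.register("beta", Parameter(np.zeros(num_features)))
        dtype = self.gamma.data.dtype
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self._buffer_attrs = {"running_mean": "running_mean", "running_var": "running_var"}
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.gamma.data.dtype)
        axes = (0, 2, 3, 4)
        shape = (1, self.num_features, 1, 1, 1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, x.shape) if train else None
        return self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache is None:
            # eval-mode backward (frozen statistics)
            shape = (1, self.num_features, 1, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            return grad * (self.gamma.data * inv).reshape(shape)
        xhat, inv, xshape = self._cache
        axes = (0, 2, 3, 4)
        shape = (1, self.num_features, 1, 1, 1)
        m = xshape[0] * xshape[2] * xshape[3] * xshape[4]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gxhat = grad * self.gamma.data.reshape(shape)
        term = (
            gxhat
            - gxhat.mean(axis=axes).reshape(shape)
            - xhat * (gxhat * xhat).mean(axis=axes).reshape(shape)
        )
        return term * inv.reshape(shape)
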