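"""Minimal NumPy layer framework used by the convolutional feature extractor.

Layers operate on NCHW float arrays and implement both a forward pass and a
reverse-mode backward pass (caches are kept only when ``cache=True`` so that
pure feature extraction stays memory-lean).  Convolutions use im2col with
BLAS matmuls; batch normalisation keeps running statistics for evaluation
mode and supports a "calibrate" mode that pins the running statistics to the
statistics of the batch being passed through.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .._exceptions import ConfigurationError, ValidationError

DEFAULT_DTYPE = np.float32

Shape = tuple[int, int, int]  # (C, H, W)


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    """Base class: a differentiable operator with (possibly) parameters."""

    def forward(self, x: np.ndarray, mode: str = "eval", cache: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def shape_out(self, shape_in: Shape) -> Shape:
        return shape_in

    # --- traversal ------------------------------------------------------
    def _children(self) -> list[tuple[str, "Module"]]:
        return []

    def _local_params(self) -> list[tuple[str, Param]]:
        return []

    def _local_buffers(self) -> list[tuple[str, np.ndarray]]:
        return []

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Param]]:
        for name, p in self._local_params():
            yield prefix + name, p
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._local_buffers():
            yield prefix + name, b
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def parameters(self) -> list[Param]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


def _pad_amounts(size: int, k: int, stride: int, padding: str) -> tuple[int, int, int]:
    """Return (pad_before, pad_after, out_size) for one spatial axis."""
    if padding == "valid":
        out = (size - k) // stride + 1
        return 0, 0, out
    if padding == "same":
        out = -(-size // stride)  # ceil
        total = max(0, (out - 1) * stride + k - size)
        before = total // 2
        return before, total - before, out
    raise ValidationError(f"unknown padding {padding!r}")


class Conv2d(Module):
    """2-D convolution (cross-correlation) via im2col."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int] | int,
        stride: int = 1,
        padding: str = "same",
        bias: bool = False,
        rng: np.random.Generator | None = None,
        dtype=DEFAULT_DTYPE,
    ):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.c_in, self.c_out, self.kh, self.kw = c_in, c_out, kh, kw
        self.stride, self.padding = stride, padding
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / (c_in * kh * kw))
        self.weight = Param(rng.normal(0.0, std, (c_out, c_in, kh, kw)).astype(dtype))
        self.bias = Param(np.zeros(c_out, dtype=dtype)) if bias else None
        self._cache: tuple | None = None

    def _local_params(self):
        out = [("weight", self.weight)]
        if self.bias is not None:
            out.append(("bias", self.bias))
        return out

    def shape_out(self, shape_in: Shape) -> Shape:
        c, h, w = shape_in
        if c != self.c_in:
            raise ConfigurationError(f"expected {self.c_in} channels, got {c}")
        _, _, oh = _pad_amounts(h, self.kh, self.stride, self.padding)
        _, _, ow = _pad_amounts(w, self.kw, self.stride, self.padding)
        if oh < 1 or ow < 1:
            raise ConfigurationError(
                f"spatial size {h}x{w} too small for {self.kh}x{self.kw}/"
                f"{self.stride} {self.padding} convolution"
            )
        return (self.c_out, oh, ow)

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, Shape]:
        n, c, h, w = x.shape
        pb_h, pa_h, oh = _pad_amounts(h, self.kh, self.stride, self.padding)
        pb_w, pa_w, ow = _pad_amounts(w, self.kw, self.stride, self.padding)
        if oh < 1 or ow < 1:
            raise ValidationError(f"input {h}x{w} too small for convolution")
        if pb_h or pa_h or pb_w or pa_w:
            x = np.pad(x, ((0, 0), (0, 0), (pb_h, pa_h), (pb_w, pa_w)))
        view = sliding_window_view(x, (self.kh, self.kw), axis=(2, 3))
        view = view[:, :, :: self.stride, :: self.stride]  # (N,C,OH,OW,kh,kw)
        col = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, -1)
        return np.ascontiguousarray(col), (x.shape, oh, ow)

    def forward(self, x: np.ndarray, mode: str = "eval", cache: bool = False) -> np.ndarray:
        n = x.shape[0]
        col, (padded_shape, oh, ow) = self._im2col(x)
        w_mat = self.weight.value.reshape(self.c_out, -1)
        out = col @ w_mat.T
        if self.bias is not None:
            out += self.bias.value
        out = out.reshape(n, oh, ow, self.c_out).transpose(0, 3, 1, 2)
        if cache:
            self._cache = (col, padded_shape, x.shape, oh, ow)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        col, padded_shape, in_shape, oh, ow = self._cache
        n = dout.shape[0]
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.c_out)
        self.weight.grad += (dflat.T @ col).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dflat.sum(axis=0)
        dcol = dflat @ self.weight.value.reshape(self.c_out, -1)
        dcol = dcol.reshape(n, oh, ow, self.c_in, self.kh, self.kw)
        dx_pad = np.zeros(padded_shape, dtype=dout.dtype)
        s = self.stride
        for i in range(self.kh):
            for j in range(self.kw):
                dx_pad[:, :, i : i + oh * s : s, j : j + ow * s : s] += (
                    dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        _, _, h, w = in_shape
        pb_h, _, _ = _pad_amounts(h, self.kh, self.stride, self.padding)
        pb_w, _, _ = _pad_amounts(w, self.kw, self.stride, self.padding)
        self._cache = None
        return dx_pad[:, :, pb_h : pb_h + h, pb_w : pb_w + w]


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.1, dtype=DEFAULT_DTYPE):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache: tuple | None = None

    def _local_params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def _local_buffers(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]

    def forward(self, x: np.ndarray, mode: str = "eval", cache: bool = False) -> np.ndarray:
        if mode in ("train", "calibrate"):
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if mode == "calibrate":
                self.running_mean[...] = mean
                self.running_var[...] = var
            else:
                m = self.momentum
                self.running_mean[...] = (1 - m) * self.running_mean + m * mean
                self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        if cache:
            self._cache = (xhat, inv_std, mode)
        return out.astype(x.dtype, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, mode = self._cache
        axes = (0, 2, 3)
        dgamma = (dout * xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        if mode == "eval":
            dx = dout * g
        else:
            m = dout.shape[0] * dout.shape[2] * dout.shape[3]
            dx = g * (
                dout
                - dbeta[None, :, None, None] / m
                - xhat * dgamma[None, :, None, None] / m
            )
        self._cache = None
        return dx.astype(dout.dtype, copy=False)


class ReLU(Module):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, mode: str = "eval", cache: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if cache:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: str = "valid"):
        self.k, self.stride, self.padding = kernel, stride, padding
        self._cache: tuple | None = None

    def shape_out(self, shape_in: Shape) -> Shape:
        c, h, w = shape_in
        _, _, oh = _pad_amounts(h, self.k, self.stride, self.padding)
        _, _, ow = _pad_amounts(w, self.k, self.stride, self.padding)
        if oh < 1 or ow < 1:
            raise ConfigurationError(f"spatial size {h}x{w} too small for pooling")
        return (c, oh, ow)

    def forward(self, x: np.ndarray, mode: str = "eval", cache: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        view = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        view = view[:, :, :: self.stride, :: self.stride]
        oh, ow = view.shape[2], view.shape[3]
        flat = view.reshape(n, c, oh, ow, self.k * self.k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if cache:
            self._cache = (arg, x.shape, oh, ow)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, in_shape, oh, ow = self._cache
        n, c, h, w = in_shape
        dx = np.zeros(in_shape, dtype=dout.dtype)
        ki, kj = np.divmod(arg, self.k)
        rows = self.stride * np.arange(oh)[None, None, :, None] + ki
        cols = self.stride * np.arange(ow)[None, None, None, :] + kj
        ns = np.arange(n)[:, None, None, None]
        cs = np.arange(c)[None, :, None, None]
        np.add.at(dx, (ns, cs, rows, cols), dout)
        self._cache = None
        return dx


class GlobalAvgPool(Module):
    """NCHW -> NC global average pooling."""

    def __init__(self):
        self._hw: tuple[int, int] | None = None

    def shape_out(self, shape_in: Shape) -> Shape:
        c, _, _ = shape_in
        return (c, 1, 1)

    def forward(self, x: np.ndarray, mode: str = "eval", cache: bool = False) -> np.ndarray:
        if cache:
            self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._hw
        self._hw = None
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w), dout.shape + (h, w)
        ).astype(dout.dtype, copy=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 dtype=DEFAULT_DTYPE):
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / n_in)
        self.weight = Param(rng.normal(0.0, std, (n_out, n_in)).astype(dtype))
        self.bias = Param(np.zeros(n_out, dtype=dtype))
        self._x: np.ndarray | None = None

    def _local_params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x: np.ndarray, mode: str = "eval", cache: bool = False) -> np.ndarray:
        if cache:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        dx = dout @ self.weight.value
        self._x = None
        return dx


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules_list = list(modules)

    def _children(self):
        return [(str(i), m) for i, m in enumerate(self.modules_list)]

    def shape_out(self, shape_in: Shape) -> Shape:
        shape = shape_in
        for m in self.modules_list:
            shape = m.shape_out(shape)
        return shape

    def forward(self, x: np.ndarray, mode: str = "eval", cache: bool = False) -> np.ndarray:
        for m in self.modules_list:
            x = m.forward(x, mode=mode, cache=cache)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules_list):
            dout = m.backward(dout)
        return dout


class ConcatBranches(Module):
    """Run branches on the same input and concatenate along channels."""

    def __init__(self, *branches: Module):
        self.branches = list(branches)
        self._splits: list[int] | None = None

    def _children(self):
        return [(f"branch{i}", b) for i, b in enumerate(self.branches)]

    def shape_out(self, shape_in: Shape) -> Shape:
        shapes = [b.shape_out(shape_in) for b in self.branches]
        hw = {(h, w) for _, h, w in shapes}
        if len(hw) != 1:
            raise ConfigurationError(f"branch spatial sizes differ: {shapes}")
        (h, w), = hw
        return (sum(c for c, _, _ in shapes), h, w)

    def forward(self, x: np.ndarray, mode: str = "eval", cache: bool = False) -> np.ndarray:
        outs = [b.forward(x, mode=mode, cache=cache) for b in self.branches]
        if cache:
            self._splits = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = None
        offset = 0
        for b, c in zip(self.branches, self._splits):
            piece = b.backward(dout[:, offset : offset + c])
            dx = piece if dx is None else dx + piece
            offset += c
        self._splits = None
        return dx


class ResidualBlock(Module):
    """``relu(x + scale * inner(x))`` — the Inception-ResNet residual unit."""

    def __init__(self, inner: Module, scale: float):
        self.inner = inner
        self.scale = scale
        self._mask: np.ndarray | None = None

    def _children(self):
        return [("inner", self.inner)]

    def shape_out(self, shape_in: Shape) -> Shape:
        inner_shape = self.inner.shape_out(shape_in)
        if inner_shape != shape_in:
            raise ConfigurationError(
                f"residual branch output {inner_shape} != input {shape_in}"
            )
        return shape_in

    def forward(self, x: np.ndarray, mode: str = "eval", cache: bool = False) -> np.ndarray:
        y = x + self.scale * self.inner.forward(x, mode=mode, cache=cache)
        if cache:
            self._mask = y > 0
        return np.maximum(y, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dy = dout * self._mask
        self._mask = None
        return dy + self.inner.backward(self.scale * dy)


# ---------------------------------------------------------------------------
# training utilities
# ---------------------------------------------------------------------------


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient wrt the logits."""
    shifted = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    probs = exp / exp.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-30).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype)


class SGD:
    """Plain stochastic gradient descent."""

    def __init__(self, params: list[Param], lr: float = 0.001):
        self.params, self.lr = params, lr

    def step(self) -> None:
        for p in self.params:
            p.value -= (self.lr * p.grad).astype(p.value.dtype)


class RMSProp:
    """Root-mean-square propagation."""

    def __init__(self, params: list[Param], lr: float = 0.001, rho: float = 0.9,
                 eps: float = 1e-8):
        self.params, self.lr, self.rho, self.eps = params, lr, rho, eps
        self._ms = [np.zeros_like(p.value, dtype=np.float64) for p in params]

    def step(self) -> None:
        for p, ms in zip(self.params, self._ms):
            g = p.grad.astype(np.float64)
            ms *= self.rho
            ms += (1.0 - self.rho) * g * g
            p.value -= (self.lr * g / (np.sqrt(ms) + self.eps)).astype(p.value.dtype)
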