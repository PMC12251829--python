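"""Minimal NumPy layer library with explicit forward/backward passes.

Internal activation layout is channels-last ``(batch, time, channels)`` in
float32; the public N×C×L window tensors are transposed at the model
boundary. Every layer caches what its backward pass needs during
``forward(train=True)`` and accumulates parameter gradients into
``self.grads`` during ``backward``. ``backward(dy, guided=True)`` switches
activations to guided-backpropagation gating (gradients pass only where both
the pre-activation and the incoming gradient are positive), which is what
Guided Grad-CAM needs; parameter gradients are not meaningful in that mode.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

F32 = np.float32


def trunc_normal(shape, rng: np.random.Generator, std: float = 0.02) -> np.ndarray:
    """Truncated-normal init (resampled beyond 2 std), matching ConvNeXt practice."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=bad.sum())
        bad = np.abs(x) > 2 * std
    return x.astype(F32)


class Module:
    """Base layer: parameter dict, gradient dict, forward/backward contract."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray, guided: bool = False) -> np.ndarray:
        raise NotImplementedError

    def modules(self):
        yield self

    def zero_grad(self) -> None:
        for m in self.modules():
            for k, v in m.params.items():
                m.grads[k] = np.zeros_like(v)

    def n_params(self) -> int:
        return sum(v.size for m in self.modules() for v in m.params.values())

    def flops(self, t: int | None) -> tuple[int, int | None]:
        """(multiply-accumulates, output temporal length) for input length ``t``."""
        return 0, t

    def state_entries(self):
        """(key, array) pairs for checkpointing, including non-trainable buffers."""
        for i, m in enumerate(self.modules()):
            for k, v in m.params.items():
                yield f"{i}.{k}", v
            for k, v in getattr(m, "buffers", {}).items():
                yield f"{i}.buf.{k}", v

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self.modules()):
            for k in m.params:
                m.params[k] = state[f"{i}.{k}"].astype(F32).copy()
            for k in getattr(m, "buffers", {}):
                m.buffers[k] = state[f"{i}.buf.{k}"].copy()


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy, guided=False):
        for layer in reversed(self.layers):
            dy = layer.backward(dy, guided=guided)
        return dy

    def modules(self):
        for layer in self.layers:
            yield from layer.modules()

    def flops(self, t):
        total = 0
        for layer in self.layers:
            macs, t = layer.flops(t)
            total += macs
        return total, t


class Residual(Module):
    """y = x + inner(x); the inner path must preserve shape."""

    def __init__(self, inner: Module) -> None:
        super().__init__()
        self.inner = inner

    def forward(self, x, train=False):
        return x + self.inner.forward(x, train=train)

    def backward(self, dy, guided=False):
        return dy + self.inner.backward(dy, guided=guided)

    def modules(self):
        yield from self.inner.modules()

    def flops(self, t):
        macs, t_out = self.inner.flops(t)
        if t_out != t:
            raise ValueError("residual branch changed temporal length")
        return macs, t


class PatchConv(Module):
    """Non-overlapping strided 1-D convolution (kernel == stride).

    Used for the stem (k=4, s=4) and the downsamplers (k=2, s=2); lengths not
    divisible by the stride are truncated (floor division, no padding).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.params = {"w": trunc_normal((kernel * in_ch, out_ch), rng),
                       "b": np.zeros(out_ch, dtype=F32)}

    def forward(self, x, train=False):
        B, T, C = x.shape
        k = self.kernel
        S = T // k
        xr = x[:, : S * k].reshape(B, S, k * C)
        y = xr.reshape(-1, k * C) @ self.params["w"] + self.params["b"]
        if train:
            self.cache = (xr, (B, T, C))
        return y.reshape(B, S, self.out_ch)

    def backward(self, dy, guided=False):
        xr, (B, T, C) = self.cache
        k = self.kernel
        S = xr.shape[1]
        dym = dy.reshape(-1, self.out_ch)
        xm = xr.reshape(-1, k * C)
        self.grads["w"] += xm.T @ dym
        self.grads["b"] += dym.sum(0)
        dx = np.zeros((B, T, C), dtype=dy.dtype)
        dx[:, : S * k] = (dym @ self.params["w"].T).reshape(B, S * k, C)
        return dx

    def flops(self, t):
        s = t // self.kernel
        return s * self.out_ch * self.in_ch * self.kernel, s


class DepthwiseConv(Module):
    """Per-channel 1-D convolution, stride 1, same (zero) padding."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        assert kernel % 2 == 1
        self.channels, self.kernel = channels, kernel
        self.params = {"w": trunc_normal((channels, kernel), rng),
                       "b": np.zeros(channels, dtype=F32)}

    def forward(self, x, train=False):
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        v = sliding_window_view(xp, self.kernel, axis=1)  # (B, T, C, k)
        y = np.einsum("btcj,cj->btc", v, self.params["w"], optimize=True)
        y += self.params["b"]
        if train:
            self.cache = v
        return y.astype(x.dtype, copy=False)

    def backward(self, dy, guided=False):
        v = self.cache
        p = self.kernel // 2
        self.grads["w"] += np.einsum("btc,btcj->cj", dy, v, optimize=True)
        self.grads["b"] += dy.sum((0, 1))
        dyp = np.pad(dy, ((0, 0), (p, p), (0, 0)))
        dv = sliding_window_view(dyp, self.kernel, axis=1)
        return np.einsum("btcj,cj->btc", dv, self.params["w"][:, ::-1],
                         optimize=True).astype(dy.dtype, copy=False)

    def flops(self, t):
        return t * self.channels * self.kernel, t


class StridedConv(Module):
    """General strided 1-D convolution with TensorFlow-style 'same' padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.params = {"w": trunc_normal((kernel * in_ch, out_ch), rng),
                       "b": np.zeros(out_ch, dtype=F32)}

    def _pads(self, t: int) -> tuple[int, int, int]:
        out = -(-t // self.stride)  # ceil
        pad = max((out - 1) * self.stride + self.kernel - t, 0)
        return out, pad // 2, pad - pad // 2

    def forward(self, x, train=False):
        B, T, C = x.shape
        out, pl, pr = self._pads(T)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        v = sliding_window_view(xp, self.kernel, axis=1)[:, ::self.stride]
        vm = v.transpose(0, 1, 3, 2).reshape(B * out, self.kernel * C)
        y = vm @ self.params["w"] + self.params["b"]
        if train:
            self.cache = (vm, (B, T, C, out, pl))
        return y.reshape(B, out, self.out_ch)

    def backward(self, dy, guided=False):
        vm, (B, T, C, out, pl) = self.cache
        dym = dy.reshape(B * out, self.out_ch)
        self.grads["w"] += vm.T @ dym
        self.grads["b"] += dym.sum(0)
        dv = (dym @ self.params["w"].T).reshape(B, out, self.kernel, C)
        _, pl2, pr2 = self._pads(T)
        dxp = np.zeros((B, T + pl2 + pr2, C), dtype=dy.dtype)
        for j in range(self.kernel):
            dxp[:, j: j + self.stride * out: self.stride] += dv[:, :, j]
        return dxp[:, pl2: pl2 + T]

    def flops(self, t):
        out, _, _ = self._pads(t)
        return out * self.out_ch * self.in_ch * self.kernel, out


class Linear(Module):
    """Affine map over the trailing (channel) axis; also the pointwise conv."""

    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_f, self.out_f = in_f, out_f
        self.params = {"w": trunc_normal((in_f, out_f), rng),
                       "b": np.zeros(out_f, dtype=F32)}

    def forward(self, x, train=False):
        y = x.reshape(-1, self.in_f) @ self.params["w"] + self.params["b"]
        if train:
            self.cache = x
        return y.reshape(*x.shape[:-1], self.out_f)

    def backward(self, dy, guided=False):
        x = self.cache
        xm = x.reshape(-1, self.in_f)
        dym = dy.reshape(-1, self.out_f)
        self.grads["w"] += xm.T @ dym
        self.grads["b"] += dym.sum(0)
        return (dym @ self.params["w"].T).reshape(x.shape)

    def flops(self, t):
        mult = t if t is not None else 1
        return mult * self.in_f * self.out_f, t


class LayerNorm(Module):
    """Normalization over the channel axis at every time step (eps 1e-6)."""

    def __init__(self, channels: int, eps: float = 1e-6) -> None:
        super().__init__()
        self.eps = eps
        self.params = {"g": np.ones(channels, dtype=F32),
                       "b": np.zeros(channels, dtype=F32)}

    def forward(self, x, train=False):
        mu = x.mean(-1, keepdims=True)
        var = x.var(-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self.cache = (xhat, inv)
        return (xhat * self.params["g"] + self.params["b"]).astype(x.dtype, copy=False)

    def backward(self, dy, guided=False):
        xhat, inv = self.cache
        axes = tuple(range(dy.ndim - 1))
        self.grads["g"] += (dy * xhat).sum(axes)
        self.grads["b"] += dy.sum(axes)
        dxhat = dy * self.params["g"]
        m1 = dxhat.mean(-1, keepdims=True)
        m2 = (dxhat * xhat).mean(-1, keepdims=True)
        return ((dxhat - m1 - xhat * m2) * inv).astype(dy.dtype, copy=False)


class GELU(Module):
    """Exact Gaussian-error GELU; guided mode gates like a deconv ReLU."""

    _INV_SQRT2 = 1.0 / math.sqrt(2.0)
    _INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)

    def forward(self, x, train=False):
        if train:
            self.cache = x
        return (0.5 * x * (1.0 + erf(x * self._INV_SQRT2))).astype(x.dtype, copy=False)

    def backward(self, dy, guided=False):
        x = self.cache
        if guided:
            return (dy * (dy > 0) * (x > 0)).astype(dy.dtype, copy=False)
        phi = np.exp(-0.5 * x * x) * self._INV_SQRT2PI
        Phi = 0.5 * (1.0 + erf(x * self._INV_SQRT2))
        return (dy * (Phi + x * phi)).astype(dy.dtype, copy=False)


class ReLU(Module):
    def forward(self, x, train=False):
        if train:
            self.cache = x
        return np.maximum(x, 0)

    def backward(self, dy, guided=False):
        x = self.cache
        if guided:
            return (dy * (dy > 0) * (x > 0)).astype(dy.dtype, copy=False)
        return dy * (x > 0)


class GRN(Module):
    """Global response normalization over the temporal axis.

    Per channel c the global response is the L2 norm over time,
    ``G_c = ||x[:, :, c]||_2``; responses are normalized by their cross-channel
    mean, ``N_c = G_c / (mean_c G + eps)``, and the output is
    ``gamma * (x * N) + beta + x`` with learned per-channel gamma, beta
    initialized to zero — so at initialization the layer is the identity.
    """

    def __init__(self, channels: int, eps: float = 1e-6) -> None:
        super().__init__()
        self.eps = eps
        self.params = {"g": np.zeros(channels, dtype=F32),
                       "b": np.zeros(channels, dtype=F32)}

    def forward(self, x, train=False):
        G = np.sqrt((x * x).sum(axis=1))            # (B, C)
        M = G.mean(axis=-1, keepdims=True) + self.eps
        N = G / M                                   # (B, C)
        if train:
            self.cache = (x, G, M, N)
        return (self.params["g"] * (x * N[:, None, :])
                + self.params["b"] + x).astype(x.dtype, copy=False)

    def backward(self, dy, guided=False):
        x, G, M, N = self.cache
        g = self.params["g"]
        xn = x * N[:, None, :]
        self.grads["g"] += (dy * xn).sum((0, 1))
        self.grads["b"] += dy.sum((0, 1))
        # dL/dN per (batch, channel), then chain through N = G / mean_c(G)
        s = (dy * x).sum(axis=1) * g                # (B, C)
        C = G.shape[-1]
        dG = s / M - (s * G).sum(-1, keepdims=True) / (C * M * M)
        Gsafe = np.where(G > 0, G, 1.0)
        dx_g = np.where(G[:, None, :] > 0, x / Gsafe[:, None, :], 0.0) * dG[:, None, :]
        return (dy * (g * N[:, None, :] + 1.0) + dx_g).astype(dy.dtype, copy=False)


class BatchNorm(Module):
    """Batch normalization over batch and time per channel (eps 1e-5).

    Running statistics are exponential moving averages with Adam-style bias
    correction, so inference statistics are unbiased even after only a
    handful of training steps (plain EMAs stay anchored to their
    initialization for ~1/momentum steps, which distorts short desk-scale
    training runs).
    """

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"g": np.ones(channels, dtype=F32),
                       "b": np.zeros(channels, dtype=F32)}
        self.buffers = {"mean": np.zeros(channels, dtype=F32),
                        "var": np.zeros(channels, dtype=F32),
                        "steps": np.zeros(1, dtype=np.float64)}

    def forward(self, x, train=False):
        if train:
            mu = x.mean((0, 1))
            var = x.var((0, 1))
            self.buffers["mean"] = ((1 - self.momentum) * self.buffers["mean"]
                                    + self.momentum * mu).astype(F32)
            self.buffers["var"] = ((1 - self.momentum) * self.buffers["var"]
                                   + self.momentum * var).astype(F32)
            self.buffers["steps"] += 1.0
        else:
            t = float(self.buffers["steps"][0])
            if t == 0:
                mu = np.zeros_like(self.buffers["mean"])
                var = np.ones_like(self.buffers["var"])
            else:
                debias = 1.0 - (1.0 - self.momentum) ** t
                mu = self.buffers["mean"] / debias
                var = self.buffers["var"] / debias
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self.cache = (xhat, inv, x.shape[0] * x.shape[1])
        return (xhat * self.params["g"] + self.params["b"]).astype(x.dtype, copy=False)

    def backward(self, dy, guided=False):
        xhat, inv, n = self.cache
        self.grads["g"] += (dy * xhat).sum((0, 1))
        self.grads["b"] += dy.sum((0, 1))
        dxhat = dy * self.params["g"]
        m1 = dxhat.mean((0, 1))
        m2 = (dxhat * xhat).mean((0, 1))
        return ((dxhat - m1 - xhat * m2) * inv).astype(dy.dtype, copy=False)


class Dropout(Module):
    def __init__(self, p: float, seed: int = 0) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout p must lie in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self.cache = None
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        self.cache = mask
        return (x * mask).astype(x.dtype, copy=False)

    def backward(self, dy, guided=False):
        if self.cache is None:
            return dy
        return (dy * self.cache).astype(dy.dtype, copy=False)


class GlobalAvgPool(Module):
    """(B, T, C) -> (B, C) mean over time."""

    def forward(self, x, train=False):
        if train:
            self.cache = x.shape
        return x.mean(axis=1)

    def backward(self, dy, guided=False):
        B, T, C = self.cache
        return np.broadcast_to(dy[:, None, :] / T, (B, T, C)).astype(dy.dtype)

    def flops(self, t):
        return 0, None


class GlobalAvgMaxPool(Module):
    """(B, T, C) -> (B, 2C): concatenated temporal mean and max."""

    def forward(self, x, train=False):
        idx = x.argmax(axis=1)
        if train:
            self.cache = (x.shape, idx)
        return np.concatenate([x.mean(axis=1),
                               np.take_along_axis(x, idx[:, None, :], 1)[:, 0]],
                              axis=-1)

    def backward(self, dy, guided=False):
        (B, T, C), idx = self.cache
        davg, dmax = dy[:, :C], dy[:, C:]
        dx = np.broadcast_to(davg[:, None, :] / T, (B, T, C)).astype(dy.dtype).copy()
        np.put_along_axis(dx, idx[:, None, :],
                          np.take_along_axis(dx, idx[:, None, :], 1) + dmax[:, None, :], 1)
        return dx

    def flops(self, t):
        return 0, None
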