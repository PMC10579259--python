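"""Feed-forward layer primitives with analytic backward passes.

Data layout is channels-last: ``(batch, time, channel, feature)``.
Convolutions are two-dimensional over the (time, channel) grid with a
3x2 kernel by default, "same" zero padding and stride 1, so spatial
dimensions are conserved.  Pooling uses ceil-mode (boundary-preserving)
windows so that a 23-wide channel axis survives four pooling stages
(23 -> 12 -> 6 -> 3 -> 1); upsampling is nearest-neighbour repetition,
the exact inverse of that arithmetic.

Each layer exposes ``params`` / ``grads`` dictionaries consumed by the
optimizers and caches whatever the backward pass needs.

Implementation note: the stage-1 feature maps of a 4-s segment batch
are ~100 MB, so the hot path is memory traffic, not flops.  Layers
therefore keep persistent, shape-keyed workspace buffers and write into
them with ``out=`` instead of allocating fresh temporaries; the
convolution lowers to a single im2col GEMM.  Buffers are reused across
batches, never across concurrent calls of the same layer.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from seizurecae.nn._kernels import (affine1, affine_combine, col2im,
                                    colsum_and_sq, conv_single_backward,
                                    dual_colsum, im2col, pool2_bwd,
                                    pool2_fwd, relu_fwd_inplace)

__all__ = [
    "Layer", "Conv2D", "MaxPool2D", "Upsample2D", "BatchNorm", "Dense",
    "Flatten", "ReLU", "Sigmoid", "SqueezeAxis", "CropTo", "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int,
                   fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameter container plus forward/backward contract."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._ws: dict = {}

    def _buf(self, key, shape, dtype) -> np.ndarray:
        """Persistent workspace buffer for this (key, shape, dtype)."""
        full = (key, tuple(shape), np.dtype(dtype))
        buf = self._ws.get(full)
        if buf is None:
            buf = np.empty(shape, dtype=dtype)
            self._ws[full] = buf
        return buf

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_parameters(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class Conv2D(Layer):
    """2-D convolution (cross-correlation), same padding, stride 1."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int] = (3, 2),
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        kh, kw = kernel
        self.kernel = (kh, kw)
        self.in_channels = in_channels
        self.out_channels = out_channels
        rng = rng or np.random.default_rng()
        fan_in = kh * kw * in_channels
        fan_out = kh * kw * out_channels
        self.params["W"] = glorot_uniform(
            rng, (kh, kw, in_channels, out_channels), fan_in, fan_out)
        self.params["b"] = np.zeros(out_channels)

    def _pad_widths(self):
        kh, kw = self.kernel
        pt, pl = (kh - 1) // 2, (kw - 1) // 2
        return (pt, kh - 1 - pt), (pl, kw - 1 - pl)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        kh, kw = self.kernel
        n, h, w, cin = x.shape
        if cin != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input features, got {cin}")
        (pt, pb), (pl, pr) = self._pad_widths()
        hp, wp = h + pt + pb, w + pl + pr
        if hp < kh or wp < kw:
            raise ValueError("kernel larger than padded input")
        W = self.params["W"].astype(x.dtype, copy=False)
        xp = self._buf("xp", (n, hp, wp, cin), x.dtype)
        if pt or pb or pl or pr:
            xp[:, :pt] = 0
            xp[:, pt + h:] = 0
            xp[:, :, :pl] = 0
            xp[:, :, pl + w:] = 0
        xp[:, pt:pt + h, pl:pl + w, :] = x
        y = self._buf("y", (n, h, w, self.out_channels), x.dtype)
        if self.out_channels <= 4:
            # few output maps: shifted tensordots beat building the
            # (kh*kw*cin)-wide im2col matrix
            y[:] = self.params["b"].astype(x.dtype, copy=False)
            for di in range(kh):
                for dj in range(kw):
                    y += np.tensordot(xp[:, di:di + h, dj:dj + w, :],
                                      W[di, dj], axes=([3], [0]))
            self._cache = (None, x.shape)
            return y
        xcol = self._buf("xcol", (n * h * w, kh * kw * cin), x.dtype)
        xv = xcol.reshape(n, h, w, kh, kw, cin)
        if not im2col(xp, xv, h, w):
            for di in range(kh):
                for dj in range(kw):
                    xv[:, :, :, di, dj, :] = xp[:, di:di + h, dj:dj + w, :]
        np.matmul(xcol, W.reshape(-1, self.out_channels),
                  out=y.reshape(n * h * w, self.out_channels))
        y += self.params["b"].astype(x.dtype, copy=False)
        self._cache = (xcol, x.shape)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel
        xcol, (n, h, w, cin) = self._cache
        (pt, pb), (pl, pr) = self._pad_widths()
        cout = self.out_channels
        W = self.params["W"]
        dxp = self._buf("dxp", (n, h + pt + pb, w + pl + pr, cin),
                        dout.dtype)
        if xcol is None and cout == 1:
            # 1-filter conv: direct transposed-correlation kernels; the
            # padded input is still warm in its buffer
            xp = self._buf("xp", dxp.shape, dout.dtype)
            g = np.ascontiguousarray(dout[..., 0])
            dW2 = np.empty((kh, kw, cin), dtype=dout.dtype)
            W2 = np.ascontiguousarray(W[..., 0]).astype(dout.dtype,
                                                        copy=False)
            if conv_single_backward(xp, g, W2, dxp, dW2, h, w):
                self.grads["W"] = dW2[..., None]
                self.grads["b"] = np.array([g.sum()], dtype=dout.dtype)
                self._cache = None
                return dxp[:, pt:pt + h, pl:pl + w, :]
        if xcol is None:
            # small-cout forward skipped im2col; rebuild it from the
            # padded input still warm in its buffer
            xp = self._buf("xp", dxp.shape, dout.dtype)
            xcol = self._buf("xcol", (n * h * w, kh * kw * cin), dout.dtype)
            xv = xcol.reshape(n, h, w, kh, kw, cin)
            if not im2col(xp, xv, h, w):
                for di in range(kh):
                    for dj in range(kw):
                        xv[:, :, :, di, dj, :] = xp[:, di:di + h, dj:dj + w, :]
        d2 = np.ascontiguousarray(dout).reshape(n * h * w, cout)
        dW = self._buf("dW", (kh * kw * cin, cout), d2.dtype)
        np.matmul(xcol.T, d2, out=dW)
        self.grads["W"] = dW.reshape(W.shape)
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        dxcol = self._buf("dxcol", xcol.shape, d2.dtype)
        np.matmul(d2, W.reshape(-1, cout).T.astype(d2.dtype, copy=False),
                  out=dxcol)
        dv = dxcol.reshape(n, h, w, kh, kw, cin)
        if not col2im(dv, dxp, h, w):
            dxp[:] = 0
            for di in range(kh):
                for dj in range(kw):
                    dxp[:, di:di + h, dj:dj + w, :] += dv[:, :, :, di, dj, :]
        self._cache = None
        return dxp[:, pt:pt + h, pl:pl + w, :]


def _pool1d_forward(layer: Layer, tag: str, x: np.ndarray, axis: int,
                    factor: int):
    """Ceil-mode 1-D max pooling along ``axis``; returns (out, cache)."""
    size = x.shape[axis]
    main = size // factor
    tail = size - main * factor
    out_shape = list(x.shape)
    out_shape[axis] = main + (1 if tail else 0)
    out = layer._buf((tag, "out"), out_shape, x.dtype)

    def take(arr, start, stop, step=1):
        sl = [slice(None)] * arr.ndim
        sl[axis] = slice(start, stop, step)
        return arr[tuple(sl)]

    if factor == 2:
        if x.flags.c_contiguous:
            A = int(np.prod(x.shape[:axis], dtype=np.int64))
            C = int(np.prod(x.shape[axis + 1:], dtype=np.int64))
            mask = layer._buf((tag, "mask3"), (A, main, C), bool)
            if pool2_fwd(x.reshape(A, size, C),
                         out.reshape(A, out_shape[axis], C), mask, tail):
                return out, (("two3d", mask, tail, None), x.shape)
        a0 = take(x, 0, 2 * main, 2)
        a1 = take(x, 1, 2 * main, 2)
        mask = layer._buf((tag, "mask"), a0.shape, bool)
        np.greater(a1, a0, out=mask)
        np.maximum(a0, a1, out=take(out, 0, main))
        cache = ("two", mask)
    else:
        # small shapes only (channel-axis factor 3); generic argmax path
        windows = np.stack([take(x, k, main * factor, factor)
                            for k in range(factor)], axis=-1)
        idx = windows.argmax(axis=-1)
        np.copyto(take(out, 0, main),
                  np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0])
        cache = ("argmax", idx)
    if tail:
        tail_src = take(x, main * factor, size)
        tail_dst = take(out, main, main + 1)
        if tail == 1:
            tail_dst[...] = tail_src
            tcache = None
        else:
            tidx = tail_src.argmax(axis=axis, keepdims=True)
            np.copyto(tail_dst, np.take_along_axis(tail_src, tidx, axis=axis))
            tcache = tidx
        cache = cache + (tail, tcache)
    else:
        cache = cache + (0, None)
    return out, (cache, x.shape)


def _pool1d_backward(layer: Layer, tag: str, dout: np.ndarray, axis: int,
                     factor: int, cache_entry):
    (kind, meta, tail, tcache), xshape = cache_entry
    size = xshape[axis]
    main = size // factor
    dx = layer._buf((tag, "dx"), xshape, dout.dtype)
    if kind == "two3d":
        A, mainc, C = meta.shape
        pool2_bwd(np.ascontiguousarray(dout).reshape(A, -1, C), meta,
                  dx.reshape(A, size, C), tail)
        return dx
    # every input position is assigned below (factor-2 writes both
    # strided halves; the argmax path scatters full windows), so no
    # upfront zero fill is needed except the multi-element tail span

    def take(arr, start, stop, step=1):
        sl = [slice(None)] * arr.ndim
        sl[axis] = slice(start, stop, step)
        return arr[tuple(sl)]

    dmain = take(dout, 0, main)
    if kind == "two":
        mask = meta
        d1 = layer._buf((tag, "d1"), dmain.shape, dout.dtype)
        np.multiply(dmain, mask, out=d1)
        take(dx, 1, 2 * main, 2)[...] = d1
        np.subtract(dmain, d1, out=d1)
        take(dx, 0, 2 * main, 2)[...] = d1
    else:
        idx = meta
        # scatter via expanded window view (small shapes only)
        dwin = np.zeros(dmain.shape + (factor,), dtype=dout.dtype)
        np.put_along_axis(dwin, idx[..., None], dmain[..., None], axis=-1)
        for k in range(factor):
            take(dx, k, main * factor, factor)[...] = dwin[..., k]
    if tail:
        dtail = take(dout, main, main + 1)
        if tail == 1:
            take(dx, main * factor, size)[...] = dtail
        else:
            span = take(dx, main * factor, size)
            span[...] = 0
            np.put_along_axis(span, tcache, dtail, axis=axis)
    return dx


class MaxPool2D(Layer):
    """Ceil-mode max pooling: output dims = ceil(input / window).

    Decomposed into two 1-D poolings (channel axis, then time axis);
    ties within a window route the gradient to a single element.
    """

    def __init__(self, window: tuple[int, int]) -> None:
        super().__init__()
        self.window = window

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        ph, pw = self.window
        mid, cache_w = _pool1d_forward(self, "w", x, axis=2, factor=pw)
        out, cache_h = _pool1d_forward(self, "h", mid, axis=1, factor=ph)
        self._cache = (cache_w, cache_h)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        ph, pw = self.window
        cache_w, cache_h = self._cache
        dmid = _pool1d_backward(self, "h", dout, axis=1, factor=ph,
                                cache_entry=cache_h)
        dx = _pool1d_backward(self, "w", dmid, axis=2, factor=pw,
                              cache_entry=cache_w)
        self._cache = None
        return dx


class Upsample2D(Layer):
    """Nearest-neighbour repetition by an integer factor per axis."""

    def __init__(self, factor: tuple[int, int]) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        fh, fw = self.factor
        n, h, w, c = x.shape
        self._shape = x.shape
        out = self._buf("out", (n, h * fh, w * fw, c), x.dtype)
        out.reshape(n, h, fh, w, fw, c)[...] = \
            x[:, :, None, :, None, :]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        fh, fw = self.factor
        n, h, w, c = self._shape
        dx = self._buf("dx", (n, h, w, c), dout.dtype)
        np.sum(dout.reshape(n, h, fh, w, fw, c), axis=(2, 4), out=dx)
        return dx


class BatchNorm(Layer):
    """Per-feature batch normalization with learned affine transform.

    Train mode normalizes by mini-batch statistics over all but the
    feature (last) axis, then applies gamma/beta; inference mode uses
    exponentially-averaged running statistics (eps 1e-3, retention
    momentum 0.9).  The running statistics are seeded from the first
    training batch rather than from (0, 1): an exponential average
    started at the conventional placeholder values is still dominated
    by them after a few dozen batches, which distorts inference-mode
    activations badly in short training runs.
    """

    def __init__(self, n_features: int, eps: float = 1e-3,
                 momentum: float = 0.9) -> None:
        super().__init__()
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(n_features)
        self.params["beta"] = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.n_updates = 0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c = x.shape[-1]
        x2 = x.reshape(-1, c)
        m = x2.shape[0]
        gamma = self.params["gamma"]
        beta = self.params["beta"]
        y = self._buf("y", x.shape, x.dtype)
        if not train:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            a = (gamma * inv).astype(x.dtype, copy=False)
            b = (beta - gamma * self.running_mean * inv).astype(
                x.dtype, copy=False)
            np.multiply(x, a, out=y)
            y += b
            return y
        if x.shape[0] < 2:
            raise ValueError("batch normalization needs batch size >= 2 "
                             "in train mode")
        # fused single-read reductions; no standardized copy is
        # materialized — backward recomputes xhat terms from the (still
        # live) input.  The input array must not be mutated between
        # forward and backward; the provided stacks guarantee this.
        s, ss = colsum_and_sq(x2)
        mean = s / m
        var = np.maximum(ss / m - mean ** 2, 0.0)
        if self.n_updates == 0:
            self.running_mean = mean.copy()
            self.running_var = var.copy()
        else:
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        self.n_updates += 1
        inv = 1.0 / np.sqrt(var + self.eps)
        a = (gamma * inv).astype(x.dtype, copy=False)
        b = (beta - gamma * mean * inv).astype(x.dtype, copy=False)
        affine1(x2, a, b, y.reshape(-1, c))
        self._cache = (x, mean, inv, m)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, mean, inv, m = self._cache
        c = dout.shape[-1]
        d2 = np.ascontiguousarray(dout).reshape(-1, c)
        x2 = np.ascontiguousarray(x).reshape(-1, c)
        dbeta, dx_sum = dual_colsum(d2, x2)
        dgamma = (dx_sum - mean * dbeta) * inv
        self.grads["gamma"] = dgamma
        self.grads["beta"] = dbeta
        gamma = self.params["gamma"]
        coeff = gamma * inv / m
        # dx = coeff * (m*dout - dbeta - xhat*dgamma)
        #    = A*dout + B*x + C with per-feature coefficients
        A = (coeff * m).astype(dout.dtype, copy=False)
        B = (-coeff * inv * dgamma).astype(dout.dtype, copy=False)
        C = (coeff * (mean * inv * dgamma - dbeta)).astype(dout.dtype,
                                                           copy=False)
        dx = self._buf("dx", x.shape, dout.dtype)
        affine_combine(d2, x2, A, B, C, dx.reshape(-1, c))
        self._cache = None
        return dx


class Dense(Layer):
    """Fully connected layer ``y = x W + b``."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = glorot_uniform(
            rng, (in_features, out_features), in_features, out_features)
        self.params["b"] = np.zeros(out_features)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].astype(x.dtype, copy=False) \
            + self.params["b"].astype(x.dtype, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["W"].T.astype(dout.dtype, copy=False)
        self._x = None
        return dx


class ReLU(Layer):
    """Elementwise max{0, x}; optionally rewrites its input in place
    (safe when the producing layer does not cache its output)."""

    def __init__(self, inplace: bool = False) -> None:
        super().__init__()
        self.inplace = inplace

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = self._buf("mask", x.shape, bool)
        self._mask = mask
        if self.inplace and x.flags.c_contiguous and \
                relu_fwd_inplace(x.reshape(-1), mask.reshape(-1)):
            return x
        np.greater(x, 0, out=mask)
        if self.inplace:
            np.maximum(x, 0, out=x)
            return x
        y = self._buf("y", x.shape, x.dtype)
        np.maximum(x, 0, out=y)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.inplace and dout.flags.writeable:
            np.multiply(dout, self._mask, out=dout)
            dx = dout
        else:
            dx = self._buf("dx", dout.shape, dout.dtype)
            np.multiply(dout, self._mask, out=dx)
        self._mask = None
        return dx


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = expit(x)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._y * (1 - self._y)
        self._y = None
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class SqueezeAxis(Layer):
    """Drop a singleton axis (used to turn the latent grid into a sequence)."""

    def __init__(self, axis: int) -> None:
        super().__init__()
        self.axis = axis

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[self.axis] != 1:
            raise ValueError(f"axis {self.axis} of shape {x.shape} is not 1")
        return np.squeeze(x, axis=self.axis)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.expand_dims(dout, axis=self.axis)


class CropTo(Layer):
    """Crop trailing rows/columns down to a target (time, channel) size."""

    def __init__(self, target_h: int, target_w: int) -> None:
        super().__init__()
        self.target = (target_h, target_w)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        th, tw = self.target
        if x.shape[1] < th or x.shape[2] < tw:
            raise ValueError(f"cannot crop {x.shape} to {self.target}")
        self._shape = x.shape
        return x[:, :th, :tw, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = self._buf("dx", self._shape, dout.dtype)
        dx[:] = 0
        th, tw = self.target
        dx[:, :th, :tw, :] = dout
        return dx
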