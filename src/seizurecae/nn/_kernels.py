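"""Fused elementwise, reduction and patch-layout kernels.

The stage-1 feature maps of a 4-s segment batch are ~100 MB, so every
avoided pass over them matters on a single core.  These numba kernels
fuse the batch-norm reductions and affine transforms, the window-2 max
pooling, the ReLU clamp, and the im2col/col2im patch shuffles of the
convolution; plain NumPy fallbacks keep every operation functional if
numba is unavailable.  Loops are ordered so large operands stream
sequentially while the accumulation window stays cache-resident.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in prod
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = ["HAVE_NUMBA", "colsum_and_sq", "dual_colsum", "affine_combine",
           "affine1", "pool2_fwd", "pool2_bwd", "relu_fwd_inplace",
           "col2im", "im2col", "conv_single_backward"]


@njit(cache=True, fastmath=True)
def _colsum_and_sq(x2):
    m, c = x2.shape
    s = np.zeros(c, dtype=np.float64)
    ss = np.zeros(c, dtype=np.float64)
    for i in range(m):
        for j in range(c):
            v = x2[i, j]
            s[j] += v
            ss[j] += v * v
    return s, ss


@njit(cache=True, fastmath=True)
def _dual_colsum(a2, b2):
    m, c = a2.shape
    s = np.zeros(c, dtype=np.float64)
    sp = np.zeros(c, dtype=np.float64)
    for i in range(m):
        for j in range(c):
            s[j] += a2[i, j]
            sp[j] += a2[i, j] * b2[i, j]
    return s, sp


@njit(cache=True, fastmath=True)
def _affine1(x2, a, b, out2):
    m, c = x2.shape
    for i in range(m):
        for j in range(c):
            out2[i, j] = a[j] * x2[i, j] + b[j]


@njit(cache=True, fastmath=True)
def _affine_combine(d2, x2, a, b, c0, out2):
    m, c = d2.shape
    for i in range(m):
        for j in range(c):
            out2[i, j] = a[j] * d2[i, j] + b[j] * x2[i, j] + c0[j]


@njit(cache=True, fastmath=True)
def _pool2_fwd(x3, out3, mask3, tail):
    A, S, C = x3.shape
    main = S // 2
    for a in range(A):
        for j in range(main):
            for k in range(C):
                v0 = x3[a, 2 * j, k]
                v1 = x3[a, 2 * j + 1, k]
                m = v1 > v0
                mask3[a, j, k] = m
                out3[a, j, k] = v1 if m else v0
        if tail:
            for k in range(C):
                out3[a, main, k] = x3[a, S - 1, k]


@njit(cache=True, fastmath=True)
def _pool2_bwd(dout3, mask3, dx3, tail):
    A, S, C = dx3.shape
    main = S // 2
    for a in range(A):
        for j in range(main):
            for k in range(C):
                d = dout3[a, j, k]
                if mask3[a, j, k]:
                    dx3[a, 2 * j, k] = 0.0
                    dx3[a, 2 * j + 1, k] = d
                else:
                    dx3[a, 2 * j, k] = d
                    dx3[a, 2 * j + 1, k] = 0.0
        if tail:
            for k in range(C):
                dx3[a, S - 1, k] = dout3[a, main, k]


@njit(cache=True, fastmath=True)
def _relu_fwd_inplace(xf, maskf):
    for i in range(xf.size):
        v = xf[i]
        m = v > 0
        maskf[i] = m
        if not m:
            xf[i] = 0


def pool2_fwd(x3, out3, mask3, tail: int) -> bool:
    """Fused window-2 max pool along the middle axis; False = no kernel."""
    if not HAVE_NUMBA:
        return False
    _pool2_fwd(x3, out3, mask3, tail)
    return True


def pool2_bwd(dout3, mask3, dx3, tail: int) -> bool:
    if not HAVE_NUMBA:
        return False
    _pool2_bwd(dout3, mask3, dx3, tail)
    return True


def relu_fwd_inplace(xf, maskf) -> bool:
    """Clamp negatives in place and record the positive mask."""
    if not HAVE_NUMBA:
        return False
    _relu_fwd_inplace(xf, maskf)
    return True


@njit(cache=True, fastmath=True)
def _im2col(xp, xv, h, w):
    # xp: (n, hp, wp, cin) padded input; xv: (n, h, w, kh, kw, cin)
    n_, hp, wp, cin = xp.shape
    kh, kw = xv.shape[3], xv.shape[4]
    for n in range(n_):
        for i in range(h):
            for j in range(w):
                for di in range(kh):
                    for dj in range(kw):
                        for c in range(cin):
                            xv[n, i, j, di, dj, c] = xp[n, i + di, j + dj, c]


def im2col(xp, xv, h: int, w: int) -> bool:
    """Extract sliding kernel patches into the im2col layout."""
    if not HAVE_NUMBA:
        return False
    _im2col(xp, xv, h, w)
    return True


@njit(cache=True, fastmath=True)
def _col2im(dv, dxp, h, w):
    # dv: (n, h, w, kh, kw, cin) gradient patches; dxp: (n, hp, wp, cin).
    # Scatter order: dv is streamed sequentially and the accumulation
    # window in dxp (kh rows) stays cache-resident.
    n_, hp, wp, cin = dxp.shape
    kh, kw = dv.shape[3], dv.shape[4]
    dxp[:] = 0.0
    for n in range(n_):
        for i in range(h):
            for j in range(w):
                for di in range(kh):
                    for dj in range(kw):
                        for c in range(cin):
                            dxp[n, i + di, j + dj, c] += dv[n, i, j, di,
                                                            dj, c]


@njit(cache=True, fastmath=True)
def _convT_single(g, W2, dxp, h, w):
    # input gradient of a 1-filter conv: g (n, h, w), W2 (kh, kw, cin)
    n_, hp, wp, cin = dxp.shape
    kh, kw = W2.shape[0], W2.shape[1]
    dxp[:] = 0.0
    for n in range(n_):
        for i in range(h):
            for j in range(w):
                gv = g[n, i, j]
                for di in range(kh):
                    for dj in range(kw):
                        for c in range(cin):
                            dxp[n, i + di, j + dj, c] += gv * W2[di, dj, c]


@njit(cache=True, fastmath=True)
def _convW_single(xp, g, dW2):
    # weight gradient of a 1-filter conv; dW2 (kh, kw, cin) zeroed here
    n_, h, w = g.shape
    kh, kw, cin = dW2.shape
    dW2[:] = 0.0
    for n in range(n_):
        for i in range(h):
            for j in range(w):
                gv = g[n, i, j]
                if gv != 0.0:
                    for di in range(kh):
                        for dj in range(kw):
                            for c in range(cin):
                                dW2[di, dj, c] += xp[n, i + di, j + dj, c] * gv


def col2im(dv, dxp, h: int, w: int) -> bool:
    """Fold im2col patch gradients back onto the padded input grid."""
    if not HAVE_NUMBA:
        return False
    _col2im(dv, dxp, h, w)
    return True


def conv_single_backward(xp, g, W2, dxp, dW2, h: int, w: int) -> bool:
    """Input and weight gradients of a single-filter convolution."""
    if not HAVE_NUMBA:
        return False
    _convT_single(g, W2, dxp, h, w)
    _convW_single(xp, g, dW2)
    return True


def colsum_and_sq(x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column sum and sum of squares in one pass (float64 accum)."""
    if HAVE_NUMBA:
        return _colsum_and_sq(x2)
    return (x2.sum(axis=0, dtype=np.float64),
            np.einsum("ic,ic->c", x2.astype(np.float64), x2))


def dual_colsum(a2: np.ndarray, b2: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-column sum(a) and sum(a*b) in one pass (float64 accum)."""
    if HAVE_NUMBA:
        return _dual_colsum(a2, b2)
    a64 = a2.astype(np.float64)
    return a64.sum(axis=0), np.einsum("ic,ic->c", a64, b2)


def affine1(x2: np.ndarray, a: np.ndarray, b: np.ndarray,
            out2: np.ndarray) -> None:
    """``out = a*x + b`` columnwise, written into ``out2``."""
    if HAVE_NUMBA:
        _affine1(x2, a, b, out2)
        return
    np.multiply(x2, a, out=out2)
    out2 += b


def affine_combine(d2: np.ndarray, x2: np.ndarray, a: np.ndarray,
                   b: np.ndarray, c0: np.ndarray,
                   out2: np.ndarray) -> None:
    """``out = a*d + b*x + c0`` columnwise, written into ``out2``."""
    if HAVE_NUMBA:
        _affine_combine(d2, x2, a, b, c0, out2)
        return
    np.multiply(d2, a, out=out2)
    out2 += b * x2
    out2 += c0
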