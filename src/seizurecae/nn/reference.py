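"""Brute-force reference implementations of every layer primitive.

These are deliberately slow, loop-based formulations kept independent
of the production layers in :mod:`seizurecae.nn.layers` and
:mod:`seizurecae.nn.recurrent`; the test suite checks that the two
agree to 1e-6 relative error on random small inputs.  Do not use them
for anything but verification.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "conv2d_reference", "max_pool_reference", "upsample_reference",
    "batch_norm_reference", "lstm_sequence_reference", "bilstm_reference",
]


def conv2d_reference(x: np.ndarray, W: np.ndarray,
                     b: np.ndarray) -> np.ndarray:
    """Same-padding, stride-1 sliding-window correlation, one loop per axis."""
    n, h, w, cin = x.shape
    kh, kw, _, cout = W.shape
    pt = (kh - 1) // 2
    pl = (kw - 1) // 2
    out = np.zeros((n, h, w, cout))
    for s in range(n):
        for i in range(h):
            for jj in range(w):
                for o in range(cout):
                    acc = 0.0
                    for di in range(kh):
                        for dj in range(kw):
                            ii = i + di - pt
                            ji = jj + dj - pl
                            if 0 <= ii < h and 0 <= ji < w:
                                for c in range(cin):
                                    acc += x[s, ii, ji, c] * W[di, dj, c, o]
                    out[s, i, jj, o] = acc + b[o]
    return out


def max_pool_reference(x: np.ndarray,
                       window: tuple[int, int]) -> np.ndarray:
    """Ceil-mode max pooling by explicit window enumeration."""
    n, h, w, c = x.shape
    ph, pw = window
    ho, wo = math.ceil(h / ph), math.ceil(w / pw)
    out = np.empty((n, ho, wo, c), dtype=x.dtype)
    for s in range(n):
        for i in range(ho):
            for j in range(wo):
                block = x[s, i * ph:(i + 1) * ph, j * pw:(j + 1) * pw, :]
                out[s, i, j, :] = block.max(axis=(0, 1))
    return out


def upsample_reference(x: np.ndarray,
                       factor: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour repetition via index arithmetic."""
    n, h, w, c = x.shape
    fh, fw = factor
    out = np.empty((n, h * fh, w * fw, c), dtype=x.dtype)
    for i in range(h * fh):
        for j in range(w * fw):
            out[:, i, j, :] = x[:, i // fh, j // fw, :]
    return out


def batch_norm_reference(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                         eps: float) -> np.ndarray:
    """Train-mode batch normalization, one feature at a time."""
    flat = x.reshape(-1, x.shape[-1])
    out = np.empty_like(flat, dtype=float)
    for f in range(flat.shape[1]):
        col = flat[:, f]
        mu = col.mean()
        var = ((col - mu) ** 2).mean()
        out[:, f] = gamma[f] * (col - mu) / math.sqrt(var + eps) + beta[f]
    return out.reshape(x.shape)


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return np.where(v >= 0, 1.0 / (1.0 + np.exp(-np.abs(v))),
                    np.exp(-np.abs(v)) / (1.0 + np.exp(-np.abs(v))))


def lstm_sequence_reference(params, seq: np.ndarray,
                            reverse: bool = False) -> np.ndarray:
    """Run the gated recurrence over ``(time, features)`` step by step.

    ``params`` is an :class:`~seizurecae.nn.recurrent.LSTMCellParams`;
    each gate is evaluated from its own explicit formula rather than the
    fused matmul of the production layer.  Returns per-step hidden
    states ``(time, units)`` in original time order.
    """
    T = seq.shape[0]
    u = params.units
    h = np.zeros(u)
    c = np.zeros(u)
    hs = np.empty((T, u))
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        z = np.concatenate([h, seq[t]])
        j = _sigmoid(z @ params.X_j + params.a_j)
        k = _sigmoid(z @ params.X_k + params.a_k)
        l = _sigmoid(z @ params.X_l + params.a_l)
        cand = np.tanh(z @ params.X_b + params.a_b)
        c = j * c + k * cand
        h = l * np.tanh(c)
        hs[t] = h
    return hs


def bilstm_reference(fwd_params, bwd_params, seq: np.ndarray) -> np.ndarray:
    """Concatenate both directions per step and average over time."""
    hf = lstm_sequence_reference(fwd_params, seq)
    hb = lstm_sequence_reference(bwd_params, seq, reverse=True)
    return np.concatenate([hf, hb], axis=1).mean(axis=0)
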