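"""LSTM recurrence and the bidirectional sequence classifier layer.

The memory cell follows the standard gated recurrence: forget gate
``j``, input gate ``k``, output gate ``l`` and candidate state all act
on the concatenation ``[h_prev, y_t]``; the cell state is
``b_t = j * b_prev + k * candidate`` and the hidden output
``h_t = l * tanh(b_t)``.  The bidirectional layer runs two independent
50-unit cells over the latent sequence in opposite directions,
concatenates their per-step outputs (100 features) and averages over
time; that average is what the classifier head sees.

:func:`lstm_step` exposes a single, framework-free step of the
recurrence; the :class:`LSTM` training layer fuses the four gate
matmuls for speed but is numerically identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from seizurecae.nn.layers import Layer, glorot_uniform

__all__ = ["LSTMCellParams", "lstm_step", "LSTM", "BiLSTM"]


@dataclass(frozen=True)
class LSTMCellParams:
    """Per-gate weights acting on ``[h_prev, y]`` plus bias vectors.

    Each weight has shape ``(hidden + input, units)`` (row-vector
    convention) and each bias shape ``(units,)``.  ``X_j/a_j`` is the
    forget gate, ``X_k/a_k`` the input gate, ``X_l/a_l`` the output
    gate, ``X_b/a_b`` the candidate state.
    """

    X_j: np.ndarray
    X_k: np.ndarray
    X_l: np.ndarray
    X_b: np.ndarray
    a_j: np.ndarray
    a_k: np.ndarray
    a_l: np.ndarray
    a_b: np.ndarray

    def __post_init__(self) -> None:
        shape = self.X_j.shape
        units = self.a_j.shape[0]
        for name in ("X_k", "X_l", "X_b"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape differs from X_j {shape}")
        for name in ("a_k", "a_l", "a_b"):
            if getattr(self, name).shape != (units,):
                raise ValueError(f"{name} must have shape ({units},)")
        if shape[1] != units:
            raise ValueError("weight column count must equal unit count")

    @property
    def units(self) -> int:
        return self.a_j.shape[0]

    @property
    def input_size(self) -> int:
        return self.X_j.shape[0] - self.units


def lstm_step(params: LSTMCellParams, y_i: np.ndarray, h_prev: np.ndarray,
              b_prev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One step of the LSTM recurrence; returns ``(h_i, b_i)``.

    Accepts a single example ``(features,)`` or a batch
    ``(batch, features)``; states have the matching shape with ``units``
    features.
    """
    z = np.concatenate([h_prev, y_i], axis=-1)
    if z.shape[-1] != params.X_j.shape[0]:
        raise ValueError(
            f"concatenated input width {z.shape[-1]} does not match "
            f"weights of width {params.X_j.shape[0]}")
    j = expit(z @ params.X_j + params.a_j)
    k = expit(z @ params.X_k + params.a_k)
    l = expit(z @ params.X_l + params.a_l)
    candidate = np.tanh(z @ params.X_b + params.a_b)
    b_i = j * b_prev + k * candidate
    h_i = l * np.tanh(b_i)
    return h_i, b_i


class LSTM(Layer):
    """One directional LSTM over a ``(batch, time, features)`` sequence.

    Gate weights are fused into a single ``(hidden + input, 4 * units)``
    matrix ordered [forget, input, output, candidate]; the forget-gate
    bias starts at 1 so early training does not erase the cell state.
    """

    def __init__(self, in_features: int, units: int,
                 rng: np.random.Generator | None = None,
                 reverse: bool = False) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.units = units
        self.in_features = in_features
        self.reverse = reverse
        blocks = [
            glorot_uniform(rng, (units + in_features, units),
                           units + in_features, units)
            for _ in range(4)
        ]
        self.params["W"] = np.concatenate(blocks, axis=1)
        bias = np.zeros(4 * units)
        bias[:units] = 1.0  # forget gate
        self.params["b"] = bias

    @property
    def cell_params(self) -> LSTMCellParams:
        u = self.units
        W, b = self.params["W"], self.params["b"]
        return LSTMCellParams(
            X_j=W[:, :u], X_k=W[:, u:2 * u], X_l=W[:, 2 * u:3 * u],
            X_b=W[:, 3 * u:], a_j=b[:u], a_k=b[u:2 * u],
            a_l=b[2 * u:3 * u], a_b=b[3 * u:],
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, T, f = x.shape
        if T == 0:
            raise ValueError("empty sequence")
        u = self.units
        W = self.params["W"].astype(x.dtype, copy=False)
        b = self.params["b"].astype(x.dtype, copy=False)
        order = range(T - 1, -1, -1) if self.reverse else range(T)
        h = np.zeros((n, u), dtype=x.dtype)
        c = np.zeros((n, u), dtype=x.dtype)
        hs = np.empty((n, T, u), dtype=x.dtype)
        cache = []
        for t in order:
            z = np.concatenate([h, x[:, t, :]], axis=1)
            gates = z @ W + b
            j = expit(gates[:, :u])
            k = expit(gates[:, u:2 * u])
            l = expit(gates[:, 2 * u:3 * u])
            g = np.tanh(gates[:, 3 * u:])
            c_prev = c
            c = j * c_prev + k * g
            tanh_c = np.tanh(c)
            h = l * tanh_c
            hs[:, t, :] = h
            cache.append((t, z, j, k, l, g, c_prev, tanh_c))
        self._cache = cache
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        cache = self._cache
        n, T, u = dhs.shape
        W = self.params["W"]
        dW = np.zeros_like(W)
        db = np.zeros_like(self.params["b"])
        dx = np.empty((n, T, self.in_features), dtype=dhs.dtype)
        dh_next = np.zeros((n, u), dtype=dhs.dtype)
        dc_next = np.zeros((n, u), dtype=dhs.dtype)
        Wt = W.T.astype(dhs.dtype, copy=False)
        for t, z, j, k, l, g, c_prev, tanh_c in reversed(cache):
            dh = dhs[:, t, :] + dh_next
            dc = dc_next + dh * l * (1 - tanh_c ** 2)
            dl = dh * tanh_c * l * (1 - l)
            dj = dc * c_prev * j * (1 - j)
            dk = dc * g * k * (1 - k)
            dg = dc * k * (1 - g ** 2)
            dgates = np.concatenate([dj, dk, dl, dg], axis=1)
            dW += z.T @ dgates
            db += dgates.sum(axis=0)
            dz = dgates @ Wt
            dh_next = dz[:, :u]
            dx[:, t, :] = dz[:, u:]
            dc_next = dc * j
        self.grads["W"] = dW
        self.grads["b"] = db
        self._cache = None
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM returning the time-average of per-step outputs.

    Forward and backward directions are independent cells of the same
    unit count; their per-step outputs are concatenated (forward half
    first) and averaged over time, yielding ``(batch, 2 * units)``.
    Optional input dropout (seeded) is applied in train mode only.
    """

    def __init__(self, in_features: int, units: int,
                 rng: np.random.Generator | None = None,
                 dropout: float = 0.0) -> None:
        super().__init__()
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        rng = rng or np.random.default_rng()
        self.forward_cell = LSTM(in_features, units, rng=rng)
        self.backward_cell = LSTM(in_features, units, rng=rng, reverse=True)
        self.units = units
        self.dropout = dropout
        self._drop_rng = np.random.default_rng(rng.integers(2 ** 31))

    @property
    def sublayers(self) -> tuple[Layer, ...]:
        return (self.forward_cell, self.backward_cell)

    @property
    def n_parameters(self) -> int:
        return sum(layer.n_parameters for layer in self.sublayers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 3:
            raise ValueError(f"expected (batch, time, features), got {x.shape}")
        if x.shape[1] == 0:
            raise ValueError("empty sequence")
        self._mask = None
        if train and self.dropout > 0.0:
            mask = (self._drop_rng.random(x.shape) >= self.dropout)
            mask = mask.astype(x.dtype) / (1.0 - self.dropout)
            x = x * mask
            self._mask = mask
        self._T = x.shape[1]
        hf = self.forward_cell.forward(x, train=train)
        hb = self.backward_cell.forward(x, train=train)
        return np.concatenate([hf.mean(axis=1), hb.mean(axis=1)], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        u, T = self.units, self._T
        dh = np.repeat(dout[:, None, :], T, axis=1) / T
        dx = self.forward_cell.backward(dh[:, :, :u])
        dx = dx + self.backward_cell.backward(dh[:, :, u:])
        if self._mask is not None:
            dx = dx * self._mask
            self._mask = None
        return dx
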