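"""Joint training objective: binary cross-entropy plus reconstruction MSE.

The total loss is the weighted sum ``TL = weight_cl * CL +
weight_rlc * RC_L`` with defaults 0.5 and 1.0: ``CL`` is the mean
binary cross-entropy of the predicted class probabilities and ``RC_L``
the mean (over segments) of the per-segment mean squared error between
the original and reconstructed value grids.  Probabilities are clamped
to ``[1e-7, 1 - 1e-7]`` inside the cross-entropy for log-domain safety;
the bias this introduces is negligible at any realistic batch size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossWeights", "PROB_CLAMP",
    "classification_loss", "classification_loss_grad",
    "reconstruction_loss", "reconstruction_loss_grad",
    "total_loss",
]

PROB_CLAMP = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Weights of the classification and reconstruction terms.

    Both default weights follow the modelled protocol (0.5 and 1.0).
    A weight may be set to exactly 0 to disable its term — used for
    controlled comparisons such as reducing a supervised autoencoder to
    its pure-classifier limit — but at least one term must remain.
    """

    weight_cl: float = 0.5
    weight_rlc: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_cl <= 1.0:
            raise ValueError("weight_cl must lie in [0, 1]")
        if not 0.0 <= self.weight_rlc <= 1.0:
            raise ValueError("weight_rlc must lie in [0, 1]")
        if self.weight_cl == 0.0 and self.weight_rlc == 0.0:
            raise ValueError("at least one loss weight must be positive")


def _clamped(predictions: np.ndarray) -> np.ndarray:
    p = np.asarray(predictions, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty prediction batch")
    return np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)


def classification_loss(predictions: np.ndarray,
                        labels: np.ndarray) -> float:
    """Mean binary cross-entropy of predicted probabilities (CL)."""
    p = _clamped(predictions)
    x = np.asarray(labels, dtype=np.float64)
    return float(-np.mean(x * np.log(p) + (1.0 - x) * np.log1p(-p)))


def classification_loss_grad(predictions: np.ndarray,
                             labels: np.ndarray) -> np.ndarray:
    """d CL / d prediction, elementwise over the batch."""
    p = _clamped(predictions)
    x = np.asarray(labels, dtype=np.float64)
    return ((p - x) / (p * (1.0 - p) * p.size)).astype(
        np.asarray(predictions).dtype, copy=False)


def reconstruction_loss(originals: np.ndarray,
                        reconstructions: np.ndarray) -> float:
    """Mean over segments of the per-segment mean squared error (RC_L)."""
    x = np.asarray(originals)
    xhat = np.asarray(reconstructions)
    if x.shape != xhat.shape:
        raise ValueError(
            f"shape mismatch: originals {x.shape}, "
            f"reconstructions {xhat.shape}")
    diff = (xhat.astype(np.float64) - x.astype(np.float64))
    per_segment = diff.reshape(diff.shape[0], -1)
    return float(np.mean(np.mean(per_segment ** 2, axis=1)))


def reconstruction_loss_grad(originals: np.ndarray,
                             reconstructions: np.ndarray) -> np.ndarray:
    """d RC_L / d reconstruction."""
    x = np.asarray(originals)
    xhat = np.asarray(reconstructions)
    if x.shape != xhat.shape:
        raise ValueError("shape mismatch")
    per_elem = x[0].size
    return (2.0 / (x.shape[0] * per_elem)) * (xhat - x)


def total_loss(cl: float, rc_l: float,
               weights: LossWeights = LossWeights()) -> float:
    """Weighted sum ``weight_cl * CL + weight_rlc * RC_L``."""
    if not (np.isfinite(cl) and np.isfinite(rc_l)):
        raise ValueError("loss terms must be finite")
    return weights.weight_cl * cl + weights.weight_rlc * rc_l
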