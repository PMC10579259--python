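"""Elementwise activation functions (overflow-safe)."""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["relu", "sigmoid"]


def relu(y):
    """Rectified linear unit: elementwise ``max{0, y}``."""
    return np.maximum(0, y)


def sigmoid(y):
    """Logistic function ``1 / (1 + exp(-y))``, safe for large ``|y|``."""
    return expit(y)
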