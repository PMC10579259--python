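"""First-order optimizers operating on layer parameter dictionaries."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Adam", "RMSprop", "Adadelta", "make_optimizer"]


class Optimizer:
    """Updates every ``layer.params`` entry in place from ``layer.grads``."""

    def __init__(self, learning_rate: float) -> None:
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.learning_rate = learning_rate
        self._state: dict[tuple[int, str], dict[str, np.ndarray]] = {}

    def step(self, layers) -> None:
        for layer in layers:
            for name, param in layer.params.items():
                grad = layer.grads.get(name)
                if grad is None:
                    continue
                key = (id(layer), name)
                state = self._state.setdefault(key, {})
                self._update(param, grad.astype(param.dtype, copy=False),
                             state)

    def _update(self, param, grad, state) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def _update(self, param, grad, state) -> None:
        param -= self.learning_rate * grad


class Adam(Optimizer):
    """Adam with the common framework defaults (beta 0.9/0.999, eps 1e-7)."""

    def __init__(self, learning_rate: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        super().__init__(learning_rate)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _update(self, param, grad, state) -> None:
        if not state:
            state["m"] = np.zeros_like(param)
            state["v"] = np.zeros_like(param)
            state["t"] = 0
        state["t"] += 1
        t = state["t"]
        m, v = state["m"], state["v"]
        m *= self.beta1
        m += (1 - self.beta1) * grad
        v *= self.beta2
        v += (1 - self.beta2) * grad ** 2
        mhat = m / (1 - self.beta1 ** t)
        vhat = v / (1 - self.beta2 ** t)
        param -= self.learning_rate * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, learning_rate: float = 1e-4, rho: float = 0.9,
                 eps: float = 1e-7) -> None:
        super().__init__(learning_rate)
        self.rho, self.eps = rho, eps

    def _update(self, param, grad, state) -> None:
        if not state:
            state["v"] = np.zeros_like(param)
        v = state["v"]
        v *= self.rho
        v += (1 - self.rho) * grad ** 2
        param -= self.learning_rate * grad / (np.sqrt(v) + self.eps)


class Adadelta(Optimizer):
    def __init__(self, learning_rate: float = 1.0, rho: float = 0.95,
                 eps: float = 1e-7) -> None:
        super().__init__(learning_rate)
        self.rho, self.eps = rho, eps

    def _update(self, param, grad, state) -> None:
        if not state:
            state["v"] = np.zeros_like(param)
            state["u"] = np.zeros_like(param)
        v, u = state["v"], state["u"]
        v *= self.rho
        v += (1 - self.rho) * grad ** 2
        delta = np.sqrt(u + self.eps) / np.sqrt(v + self.eps) * grad
        u *= self.rho
        u += (1 - self.rho) * delta ** 2
        param -= self.learning_rate * delta


_OPTIMIZERS = {"sgd": SGD, "adam": Adam, "rmsprop": RMSprop,
               "adadelta": Adadelta}


def make_optimizer(name: str, learning_rate: float) -> Optimizer:
    try:
        cls = _OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}"
        ) from None
    return cls(learning_rate=learning_rate)
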