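"""Optimizers for the numpy layer stack."""

from __future__ import annotations

import numpy as np

from .layers import Layer, iter_parameters

__all__ = ["RMSprop"]


class RMSprop:
    """RMSprop with a running second-moment average.

    update: ``v <- rho * v + (1 - rho) * g**2``;
    ``p <- p - lr * g / (sqrt(v) + eps)``.
    """

    def __init__(self, model: Layer, lr: float = 1e-4, rho: float = 0.9, eps: float = 1e-7):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.model = model
        self.lr, self.rho, self.eps = float(lr), float(rho), float(eps)
        self._state: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        for layer, name in iter_parameters(self.model):
            g = layer.grads[name]
            key = (id(layer), name)
            v = self._state.get(key)
            if v is None:
                v = np.zeros_like(g)
                self._state[key] = v
            v *= self.rho
            v += (1.0 - self.rho) * g * g
            layer.params[name] -= self.lr * g / (np.sqrt(v) + self.eps)
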