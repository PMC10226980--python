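"""Adam optimizer over a Network's trainable layers."""

from __future__ import annotations

import numpy as np

from .network import Network


class Adam:
    def __init__(
        self,
        network: Network,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.network = network
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for layer in self.network.parameter_layers():
            if not layer.trainable:
                continue
            for key, grad in layer.grads.items():
                slot = f"{layer.name}.{key}"
                m = self._m.setdefault(slot, np.zeros_like(grad))
                v = self._v.setdefault(slot, np.zeros_like(grad))
                m += (1.0 - self.beta1) * (grad - m)
                v += (1.0 - self.beta2) * (grad * grad - v)
                update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                layer.params[key] -= update.astype(layer.params[key].dtype)
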