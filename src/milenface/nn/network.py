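"""Sequential container with named layers and weight (de)serialization."""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer, ResidualBlock


class Network:
    """A plain sequential network.

    ``forward`` caches per-layer intermediates so that ``backward`` can
    propagate a gradient from the output back to the input; the returned
    input gradient is what FGSM perturbs, and per-layer captured gradients
    are what Grad-CAM weighs feature maps with.
    """

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers
        names = [l.name for l in layers if l.name]
        if len(names) != len(set(names)):
            raise ValueError("layer names must be unique")

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # -- introspection -----------------------------------------------------
    def get_layer(self, name: str) -> Layer:
        for layer in self.layers:
            if layer.name == name:
                return layer
            if isinstance(layer, ResidualBlock):
                for sub in layer.sublayers:
                    if sub.name == name:
                        return sub
        raise KeyError(f"no layer named {name!r}")

    def parameter_layers(self) -> list[Layer]:
        out: list[Layer] = []
        for layer in self.layers:
            if isinstance(layer, ResidualBlock):
                out.extend(layer.sublayers)
            elif layer.params:
                out.append(layer)
        return out

    def n_parameters(self, trainable_only: bool = False) -> int:
        return sum(
            l.n_parameters()
            for l in self.parameter_layers()
            if not trainable_only or l.trainable
        )

    # -- weights -----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for layer in self.parameter_layers():
            for key, val in layer.params.items():
                state[f"{layer.name}.{key}"] = val.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for layer in self.parameter_layers():
            for key in layer.params:
                layer.params[key] = state[f"{layer.name}.{key}"].copy()

    def save_weights(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))

    def clone_state(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.state_dict())
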