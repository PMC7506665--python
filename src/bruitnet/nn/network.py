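"""Sequential network container with weight (de)serialization and
partial backward passes (needed by Grad-CAM, which wants the gradient of a
class logit at an interior convolutional activation)."""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer

__all__ = ["Sequential"]


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(
        self, x: np.ndarray, train: bool = True, capture: int | None = None
    ) -> np.ndarray:
        """Run all layers; if ``capture`` is a layer index, stash that
        layer's output on ``self.captured``."""
        self.captured = None
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            if capture is not None and i == capture:
                self.captured = x
        return x

    def backward(self, dy: np.ndarray, stop_at: int = 0) -> np.ndarray:
        """Backpropagate ``dy`` from the output down to (and including)
        layer index ``stop_at``; returns the gradient w.r.t. that layer's
        *input* (or the network input when ``stop_at == 0``)."""
        for layer in reversed(self.layers[stop_at:]):
            dy = layer.backward(dy)
        return dy

    def backward_to_activation(self, dy: np.ndarray, layer_idx: int) -> np.ndarray:
        """Gradient of the objective w.r.t. the *output* of ``layer_idx``."""
        for layer in reversed(self.layers[layer_idx + 1 :]):
            dy = layer.backward(dy)
        return dy

    # -- parameter plumbing -------------------------------------------------

    def parameters(self):
        """Yield (unique_name, layer, param_name) triples."""
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"layer{i}.{name}", layer, name

    def n_parameters(self) -> int:
        return sum(layer.params[n].size for _, layer, n in self.parameters())

    def get_weights(self) -> dict[str, np.ndarray]:
        state = {
            key: layer.params[name].copy() for key, layer, name in self.parameters()
        }
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "running_mean"):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def set_weights(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.parameters():
            layer.params[name][...] = state[key]
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "running_mean"):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]

    def clone_weights(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.get_weights())
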