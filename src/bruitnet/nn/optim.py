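"""Adam optimizer and the class-weighted softmax cross-entropy loss."""

from __future__ import annotations

import numpy as np

from .network import Sequential

__all__ = ["Adam", "softmax", "weighted_cross_entropy"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, sample_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Weighted softmax cross-entropy.

    Loss = Σᵢ wᵢ · (−log pᵢ,yᵢ) / Σᵢ wᵢ, so unit weights give the plain mean
    cross-entropy exactly, and rescaling all weights by a common factor
    leaves both the loss and its gradient unchanged.

    Returns (loss, dlogits).
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    if sample_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weights, dtype=np.float64)
    wsum = w.sum()
    logp = np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    loss = float(-(w * logp).sum() / wsum)
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits.astype(np.float32)


class Adam:
    """Adaptive-moment gradient descent over a Sequential's parameters."""

    def __init__(
        self,
        net: Sequential,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {key: np.zeros_like(layer.params[name])
                  for key, layer, name in net.parameters()}
        self.v = {key: np.zeros_like(layer.params[name])
                  for key, layer, name in net.parameters()}

    def step(self) -> None:
        from .kernels import adam_update

        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for key, layer, name in self.net.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            p = layer.params[name]
            m = self.m[key]
            v = self.v[key]
            if p.dtype == np.float32 and p.flags.c_contiguous:
                g32 = np.ascontiguousarray(g, dtype=np.float32)
                adam_update(p.reshape(-1), g32.reshape(-1), m.reshape(-1),
                            v.reshape(-1), self.lr, b1, b2, self.eps, bias1, bias2)
            else:
                g = g.astype(p.dtype)
                m += (1 - b1) * (g - m)
                v += (1 - b2) * (g * g - v)
                p -= (self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)).astype(
                    p.dtype
                )
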