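"""Grad-CAM heatmaps on log-mel spectrograms.

Gradient-weighted class activation mapping localizes the time–frequency
regions driving a class decision: channel weights are the spatially
averaged gradients of the target-class logit at the last convolutional
activation, the weighted channel sum is rectified, bilinearly upsampled to
the input grid and max-normalized. For the CRNN kinds attribution uses the
convolutional trunk only (the recurrence and head are part of the
backpropagated objective but carry no spatial map of their own).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .features import LogMelSpectrogram, mel_peak_frequencies_hz
from .models import BruitClassifier, _as_batch
from .nn import Conv2d
from .synth import CLASSES

__all__ = ["GradCamMap", "grad_cam", "export_heatmap_png"]


@dataclass(frozen=True)
class GradCamMap:
    """Heat values on the input grid, ``values[frame, mel]`` in [0, 1]."""

    values: np.ndarray
    target_class: str
    model_kind: str

    def __post_init__(self) -> None:
        if self.values.min() < 0 or self.values.max() > 1.0 + 1e-6:
            raise ValueError("heat values must lie in [0, 1]")


def grad_cam(model: BruitClassifier, features, target_class: str | int) -> GradCamMap:
    """Compute the Grad-CAM heatmap of ``target_class`` for one beat.

    ``features`` is a LogMelSpectrogram (or a (frames, mels) array) whose
    mel axis matches the model. An all-zero map (a logit constant in the
    input) stays zero rather than being normalized.
    """
    if isinstance(target_class, str):
        if target_class not in CLASSES:
            raise ValueError(f"unknown class {target_class!r}")
        class_idx = CLASSES.index(target_class)
    else:
        class_idx = int(target_class)
        if not (0 <= class_idx < len(CLASSES)):
            raise ValueError(f"class index {class_idx} out of range")
        target_class = CLASSES[class_idx]
    if not any(isinstance(l, Conv2d) for l in model.net.layers):
        raise ValueError("model has no convolutional layer")

    x = _as_batch(model, features)
    if x.shape[0] != 1:
        raise ValueError("grad_cam expects a single beat")
    layer_idx = model.gradcam_target(x.shape[2])
    logits = model.net.forward(x, train=False, capture=layer_idx)
    activation = model.net.captured  # (1, H, W, C)
    dlogits = np.zeros_like(logits)
    dlogits[0, class_idx] = 1.0
    grad = model.net.backward_to_activation(dlogits, layer_idx)

    weights = grad.mean(axis=(1, 2))  # (1, C)
    cam = np.maximum((weights[:, None, None, :] * activation).sum(axis=3)[0], 0.0)
    n_mels, n_frames = x.shape[1], x.shape[2]
    if cam.shape != (n_mels, n_frames):
        zoom = (n_mels / cam.shape[0], n_frames / cam.shape[1])
        cam = np.maximum(ndimage.zoom(cam, zoom, order=1, grid_mode=True, mode="nearest"), 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return GradCamMap(values=cam.T.astype(np.float64), target_class=target_class,
                      model_kind=model.spec.kind)


def export_heatmap_png(
    cam: GradCamMap,
    features: LogMelSpectrogram,
    path: str | Path,
    fmax_hz: float = 2000.0,
) -> Path:
    """Overlay the heatmap on the log-mel spectrogram and write a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    freqs = mel_peak_frequencies_hz(features.values.shape[1], fmax_hz)
    fig, ax = plt.subplots(figsize=(6, 4))
    extent = (0, features.values.shape[0], float(freqs[0]), float(freqs[-1]))
    ax.imshow(features.values.T, origin="lower", aspect="auto", cmap="gray",
              extent=extent)
    ax.imshow(cam.values.T, origin="lower", aspect="auto", cmap="jet", alpha=0.4,
              extent=extent)
    ax.set_xlabel("time frame")
    ax.set_ylabel("mel filter peak frequency [Hz]")
    ax.set_title(f"Grad-CAM: {cam.target_class} ({cam.model_kind})")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
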