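"""Five-class bruit classifiers: VGG13 and CRNN (Bi-GRU / Bi-LSTM).

All three share a VGG13 convolutional trunk — five pairs of 3×3
convolutions (64, 64 → 128, 128 → 256, 256 → 512, 512 → 512, 512 channels),
each convolution followed by batch normalization and ReLU, with 2×2 max
pooling between pairs and after the last pair. Five pooling stages take a
400-frame input time axis to exactly 12 frames at the head; the CRNN kinds
run a 512-wide bidirectional recurrence over those frames before global
average pooling, the plain VGG13 pools the conv features directly. The
output is a softmax over the five sound classes.

Class imbalance (abnormal sounds are rare in auscultation corpora) is
handled by inverse-frequency class weights in the cross-entropy loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit

from .features import LogMelSpectrogram
from .nn import (
    Adam,
    BatchNorm2d,
    BiGRU,
    BiLSTM,
    Conv2d,
    Dense,
    GlobalAvgPool2d,
    MaxPool2d,
    ReLU,
    Sequential,
    TimeAvgPool,
    TimeUnfold,
    softmax,
    weighted_cross_entropy,
)
from .synth import CLASSES

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "TrainingSet",
    "LearningCurve",
    "BruitClassifier",
    "build_model",
    "compute_class_weights",
    "train",
    "predict",
    "predict_batch",
    "save_model",
    "load_model",
]

MODEL_KINDS = ("vgg13", "crnn_bigru", "crnn_bilstm")

#: channel plan of the conv trunk: (in, out) pairs, "P" = 2×2 max pool
_CONV_PLAN = (
    (1, 64), (64, 64), "P",
    (64, 128), (128, 128), "P",
    (128, 256), (256, 256), "P",
    (256, 512), (512, 512), "P",
    (512, 512), (512, 512), "P",
)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Which classifier to build and at what mel resolution."""

    kind: str
    n_mels: int = 64
    recurrent_width: int = 512
    n_classes: int = 5

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unsupported kind {self.kind!r}; one of {MODEL_KINDS}")
        if self.n_mels < 32:
            raise ValueError("n_mels must be >= 32 (five 2x2 pooling stages)")


def _vgg_trunk(rng: np.random.Generator) -> list:
    layers: list = []
    for item in _CONV_PLAN:
        if item == "P":
            layers.append(MaxPool2d())
        else:
            cin, cout = item
            layers += [Conv2d(cin, cout, rng), BatchNorm2d(cout), ReLU()]
    return layers


def _pooled(n: int, stages: int = 5) -> int:
    for _ in range(stages):
        n //= 2
    return n


class BruitClassifier:
    """A built (possibly trained) five-class model plus its architecture spec."""

    def __init__(self, spec: ArchitectureSpec, net: Sequential, trunk_len: int) -> None:
        self.spec = spec
        self.net = net
        self.trunk_len = trunk_len
        self.trained = False

    @property
    def gradcam_layer(self) -> int:
        """Index of the activation after the last convolution (its ReLU)."""
        return self.trunk_len - 2

    def gradcam_target(self, n_frames: int, min_time_cells: int = 8) -> int:
        """Attribution layer for an ``n_frames`` input: the deepest
        convolutional activation whose time axis still has at least
        ``min_time_cells`` cells.

        For reference-width (400-frame) inputs this is the activation after
        the last convolution — the standard Grad-CAM choice. For compact
        inputs the final block's receptive field covers the whole clip and
        its cells carry no positional information, so the target backs off
        to the deepest block that still resolves time.
        """
        width = n_frames
        candidates: list[tuple[int, int]] = []  # (layer index, time cells)
        for i, layer in enumerate(self.net.layers[: self.trunk_len]):
            if isinstance(layer, ReLU):
                candidates.append((i, width))
            elif isinstance(layer, MaxPool2d):
                width //= 2
        chosen = candidates[-1][0]
        for i, cells in candidates:
            if cells >= min_time_cells:
                chosen = i
        return chosen

    def has_recurrent_layers(self) -> bool:
        return any(isinstance(l, (BiGRU, BiLSTM)) for l in self.net.layers)

    def time_frames_at_head(self, n_frames: int = 400) -> int:
        """Time-axis length entering the recurrent layer (or the final
        feature pooling for the plain CNN) for an ``n_frames`` input."""
        x = np.zeros((1, self.spec.n_mels, n_frames, 1), dtype=np.float32)
        for layer in self.net.layers[: self.trunk_len]:
            x = layer.forward(x, train=False)
        return x.shape[2]


def build_model(spec: ArchitectureSpec, seed: int = 0) -> BruitClassifier:
    """Construct the requested architecture with seeded initialization."""
    rng = np.random.default_rng(seed)
    trunk = _vgg_trunk(rng)
    pooled_mels = _pooled(spec.n_mels)
    if spec.kind == "vgg13":
        layers = trunk + [GlobalAvgPool2d(), Dense(512, spec.n_classes, rng)]
    else:
        rec_cls = BiGRU if spec.kind == "crnn_bigru" else BiLSTM
        d_in = 512 * pooled_mels
        layers = trunk + [
            TimeUnfold(),
            rec_cls(d_in, spec.recurrent_width, rng),
            ReLU(),
            TimeAvgPool(),
            Dense(2 * spec.recurrent_width, spec.n_classes, rng),
        ]
    return BruitClassifier(spec, Sequential(layers), trunk_len=len(trunk))


def compute_class_weights(counts: dict[str, int]) -> dict[str, float]:
    """Inverse-frequency weights: ``w_c = N_total / (K * N_c)``.

    Balanced counts give all 1.0; a zero-count class is an error.
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    if any(c <= 0 for c in counts.values()):
        zero = [k for k, v in counts.items() if v <= 0]
        raise ValueError(f"classes with non-positive counts: {zero}")
    total = sum(counts.values())
    k = len(counts)
    return {cls: total / (k * n) for cls, n in counts.items()}


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    class_weights: dict[str, float] | None = None
    val_fraction: float = 0.2
    seed: int = 0


@dataclass(frozen=True)
class TrainingSet:
    """Featurized labeled beats: ``features`` is (N, n_mels, n_frames)."""

    features: np.ndarray
    labels: np.ndarray  # integer class indices into CLASSES
    patients: np.ndarray
    split: np.ndarray | None = None  # optional explicit "train"/"val" tags

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.patients) == n):
            raise ValueError("features, labels and patients must align")
        if self.split is not None and len(self.split) != n:
            raise ValueError("split must align with features")


@dataclass
class LearningCurve:
    """Per-epoch training history."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["epoch", "train_accuracy", "train_loss", "val_accuracy", "val_loss"]
        )
    )

    def append(self, epoch: int, ta: float, tl: float, va: float, vl: float) -> None:
        self.records.loc[len(self.records)] = [epoch, ta, tl, va, vl]


def _grouped_split(
    labels: np.ndarray, patients: np.ndarray, val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    splitter = GroupShuffleSplit(n_splits=1, test_size=val_fraction, random_state=seed)
    train_idx, val_idx = next(splitter.split(labels, labels, groups=patients))
    return train_idx, val_idx


def _eval_pass(
    net: Sequential, x: np.ndarray, y: np.ndarray, w: np.ndarray, batch: int = 32
) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, x.shape[0], batch):
        logits = net.forward(x[i : i + batch], train=False)
        loss, _ = weighted_cross_entropy(logits, y[i : i + batch], w[i : i + batch])
        losses.append(loss * (logits.shape[0]))
        correct += int((logits.argmax(axis=1) == y[i : i + batch]).sum())
    return correct / x.shape[0], float(np.sum(losses) / x.shape[0])


def train(
    model: BruitClassifier, corpus: TrainingSet, config: TrainingConfig
) -> tuple[BruitClassifier, LearningCurve]:
    """Class-weighted cross-entropy training with a patient-grouped
    train/validation split; the best-validation-accuracy weights are kept.

    A corpus whose explicit split places one patient in both halves is an
    error — patient leakage across splits would inflate validation scores.
    """
    y = np.asarray(corpus.labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training corpus must contain at least two classes")
    patients = np.asarray(corpus.patients)
    if corpus.split is not None:
        split = np.asarray(corpus.split)
        leaked = set(patients[split == "train"]) & set(patients[split == "val"])
        if leaked:
            raise ValueError(f"patients in both splits: {sorted(leaked)}")
        train_idx = np.flatnonzero(split == "train")
        val_idx = np.flatnonzero(split == "val")
    else:
        train_idx, val_idx = _grouped_split(y, patients, config.val_fraction, config.seed)

    if config.class_weights is None:
        counts = {CLASSES[c]: int(n) for c, n in zip(*np.unique(y[train_idx], return_counts=True))}
        weights = compute_class_weights(counts)
    else:
        weights = config.class_weights
    w_by_idx = np.array([weights.get(CLASSES[c], 1.0) for c in range(len(CLASSES))])
    x = _as_batch(model, corpus.features)
    w = w_by_idx[y]

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.net, lr=config.learning_rate)
    curve = LearningCurve()
    best_val, best_state = -1.0, None
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(train_idx)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, order.size, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.net.forward(x[idx], train=True)
            loss, dl = weighted_cross_entropy(logits, y[idx], w[idx])
            model.net.backward(dl)
            opt.step()
            ep_loss += loss * idx.size
            ep_correct += int((logits.argmax(axis=1) == y[idx]).sum())
        train_acc = ep_correct / order.size
        train_loss = ep_loss / order.size
        val_acc, val_loss = _eval_pass(model.net, x[val_idx], y[val_idx], w[val_idx])
        curve.append(epoch, train_acc, train_loss, val_acc, val_loss)
        if val_acc > best_val:
            best_val = val_acc
            best_state = model.net.clone_weights()
    if best_state is not None:
        model.net.set_weights(best_state)
    model.trained = True
    return model, curve


def _as_batch(model: BruitClassifier, features) -> np.ndarray:
    """Normalize features to the channels-last batch layout (N, mels, frames, 1)."""
    if isinstance(features, LogMelSpectrogram):
        arr = features.values.T[None, :, :, None]
    else:
        arr = np.asarray(features, dtype=np.float32)
        if arr.ndim == 2:  # (frames, mels)
            arr = arr.T[None, :, :, None]
        elif arr.ndim == 3:  # (N, mels, frames)
            arr = arr[:, :, :, None]
    if arr.shape[1] != model.spec.n_mels:
        raise ValueError(
            f"feature mel axis {arr.shape[1]} does not match model n_mels "
            f"{model.spec.n_mels}"
        )
    return arr.astype(np.float32)


def predict(model: BruitClassifier, features) -> np.ndarray:
    """Five-class probability vector (order: normal, hard, high,
    intermittent, whistle), summing to 1."""
    return predict_batch(model, features)[0]


def predict_batch(model: BruitClassifier, features, batch: int = 32) -> np.ndarray:
    x = _as_batch(model, features)
    out = []
    for i in range(0, x.shape[0], batch):
        logits = model.net.forward(x[i : i + batch], train=False)
        out.append(softmax(logits))
    return np.concatenate(out, axis=0)


def save_model(model: BruitClassifier, path: str | Path) -> Path:
    """Checkpoint: weights plus an embedded architecture manifest."""
    path = Path(path)
    manifest = json.dumps(
        {
            "kind": model.spec.kind,
            "n_mels": model.spec.n_mels,
            "recurrent_width": model.spec.recurrent_width,
            "n_classes": model.spec.n_classes,
            "classes": list(CLASSES),
            "trained": model.trained,
        }
    )
    np.savez_compressed(
        path, __manifest__=np.frombuffer(manifest.encode(), dtype=np.uint8),
        **model.net.get_weights(),
    )
    return path


def load_model(path: str | Path) -> BruitClassifier:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        state = {k: data[k] for k in data.files if k != "__manifest__"}
    spec = ArchitectureSpec(
        kind=manifest["kind"],
        n_mels=manifest["n_mels"],
        recurrent_width=manifest["recurrent_width"],
        n_classes=manifest["n_classes"],
    )
    model = build_model(spec)
    model.net.set_weights(state)
    model.trained = bool(manifest["trained"])
    return model
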