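"""Shared fixtures.

The two expensive session fixtures — a trained bruit-vs-environment gate
and a trained five-class CRNN — are built once and reused by every test
that needs a trained network, so the suite's cost is dominated by exactly
one gate run and one classifier run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from bruitnet import synth
from bruitnet.features import FeatureConfig, featurize_recording, mel_filterbank

warnings.filterwarnings("ignore", category=RuntimeWarning, module="bruitnet")

#: desk-scale study conditions: short (tachycardic-range) beats keep the
#: padded time axis at 48 frames so single-core training stays tractable
CORPUS_PARAMS = synth.CorpusParams(duration_range=(0.50, 0.52), n_patients=20,
                                   snr_db=15.0)
FEATURE_CONFIG = FeatureConfig(n_mels=64, target_frames=48)
SEED = 7


def featurize_beats(beats, config=FEATURE_CONFIG):
    fb = mel_filterbank(config.n_mels, config.fmax_hz, config.sample_rate_hz,
                        config.window_len)
    return np.stack(
        [featurize_recording(b.recording, config, fb).values.T for b in beats]
    ).astype(np.float32)


@dataclass
class TrainedCorpusModel:
    model: object
    features: np.ndarray  # (N, n_mels, n_frames)
    labels: np.ndarray
    patients: np.ndarray
    split: np.ndarray
    test_probs: np.ndarray
    config: FeatureConfig


@pytest.fixture(scope="session")
def trained_crnn() -> TrainedCorpusModel:
    """CRNN-BiGRU (64 mels) trained for 20 epochs on 100 synthetic beats
    per class; evaluation beats come from patients unseen in training."""
    from bruitnet import models

    beats, _ = synth.synth_corpus(
        {c: 100 for c in synth.CLASSES}, CORPUS_PARAMS, seed=SEED
    )
    x = featurize_beats(beats)
    y = np.array([synth.CLASSES.index(b.sound_class) for b in beats])
    pats = np.array([b.patient_id for b in beats])
    split = np.array([b.split for b in beats])
    tr = split == "train"
    model = models.build_model(
        models.ArchitectureSpec(kind="crnn_bigru", n_mels=64), seed=SEED
    )
    model, _ = models.train(
        model,
        models.TrainingSet(x[tr], y[tr], pats[tr]),
        models.TrainingConfig(epochs=20, batch_size=16, seed=SEED),
    )
    probs = models.predict_batch(model, x[~tr])
    return TrainedCorpusModel(model, x, y, pats, split, probs, FEATURE_CONFIG)


@pytest.fixture(scope="session")
def trained_vgg13() -> TrainedCorpusModel:
    """VGG13 (pure CNN) trained on a smaller corpus; used for the Grad-CAM
    localization property — gradient-based class activation maps carry
    positional credit through convolutional pooling, but not through the
    CRNNs' bidirectional recurrence."""
    from bruitnet import models

    beats, _ = synth.synth_corpus(
        {c: 30 for c in synth.CLASSES}, CORPUS_PARAMS, seed=SEED
    )
    x = featurize_beats(beats)
    y = np.array([synth.CLASSES.index(b.sound_class) for b in beats])
    pats = np.array([b.patient_id for b in beats])
    split = np.array([b.split for b in beats])
    tr = split == "train"
    model = models.build_model(
        models.ArchitectureSpec(kind="vgg13", n_mels=64), seed=SEED
    )
    model, _ = models.train(
        model,
        models.TrainingSet(x[tr], y[tr], pats[tr]),
        models.TrainingConfig(epochs=8, batch_size=16, seed=SEED),
    )
    probs = models.predict_batch(model, x[~tr])
    return TrainedCorpusModel(model, x, y, pats, split, probs, FEATURE_CONFIG)


@pytest.fixture(scope="session")
def trained_gate():
    """Bruit-vs-environment gate trained on 200 synthetic beats vs 200
    synthetic environment clips (32 mels, 192-frame axis covers 2 s beats)."""
    from bruitnet import segmentation

    beats, clips = synth.synth_gate_clips(200, 200, seed=SEED + 1)
    config = segmentation.GateTrainConfig(
        feature=FeatureConfig(n_mels=32, target_frames=192), epochs=4, seed=SEED
    )
    gate = segmentation.train_gate(beats[:160], clips[:160], config)
    # held-out clips for AUC checks
    return gate, beats[160:], clips[160:]
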