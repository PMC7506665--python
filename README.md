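# bruitnet

Deep-learning analysis of arteriovenous-fistula (AVF) bruit — the sound of
turbulent blood flow through the surgical artery–vein connection that gives
hemodialysis patients vascular access. Auscultation of the fistula is part
of every dialysis consultation, but its findings are subjective and hard to
compare across days and examiners. `bruitnet` turns a bedside recording
into an objective per-beat score: it extracts single heartbeats from a long
auscultation recording, converts each beat to a fixed-size log-mel
spectrogram, classifies it into one of five clinically meaningful sound
classes, and explains each decision with a Grad-CAM heatmap.

The five classes and what they signal about stenosis (vessel narrowing):

| class | acoustic signature | clinical reading |
|---|---|---|
| `normal` | broadband 2–750 Hz bruit with a systolic peak | baseline |
| `hard` | strongly exaggerated systolic peak, band up to 1500 Hz | elevated vascular resistance |
| `high` | energy concentrated in 250–750 Hz during systole | long narrow segment |
| `intermittent` | diastolic silence | severe obstruction |
| `whistle` | narrowband 800–1500 Hz tone | sharp diameter decrease |

## Pipeline

1. **Beat segmentation** (`bruitnet.segmentation`) — a short-time band-energy
   envelope over 2–750 Hz (the band characteristic of fistula bruit) is
   smoothed with a cubic spline; convex ranges (local minimum → maximum →
   local minimum) lasting 0.5–2 s are proposed as beats; a binary gate CNN
   accepts a candidate only when its probability of being fistula bruit
   strictly exceeds 50 %.
2. **Features** (`bruitnet.features`) — STFT at 192 kHz with a 4096-sample
   window and 2048 hop, mel filterbank (64–1024 filters) capped at 2000 Hz,
   log compression, per-clip standardization, and blank-padding of the time
   axis to a fixed frame count (reference 400).
3. **Classifiers** (`bruitnet.models`) — a VGG13 trunk (3×3 convolutions
   64·64–128·128–256·256–512·512–512·512, each with batch norm + ReLU, 2×2
   max-pooling) mapping 400 input frames to exactly 12, optionally followed
   by a 512-wide bidirectional GRU or LSTM, then global average pooling and
   a 5-class softmax. Training uses Adam on class-weighted cross-entropy
   (w_c = N/(K·N_c)) with a patient-grouped train/validation split. The
   networks run on a seeded NumPy/numba engine built into the package
   (`bruitnet.nn`), verified layer-by-layer against finite differences.
4. **Evaluation & ensembling** (`bruitnet.evaluation`) — one-vs-rest
   ROC/AUC per class, per-class best-model selection from an AUC table,
   a per-class logistic stacking ensemble, Table-style metric reports
   (accuracy, precision, recall, specificity, F1, AUC) and a longitudinal
   class-proportion trend.
5. **Interpretation** (`bruitnet.interpret`) — Grad-CAM heatmaps on the
   conv trunk, upsampled to the input spectrogram grid.

No patient audio is distributed with the package; `bruitnet.synth`
generates seedable synthetic bruit with the class signatures above plus
environmental sounds (mains hum, babble, clatter), so the full pipeline is
testable end to end.

## Worked example

```python
import numpy as np
from bruitnet import synth, models
from bruitnet.features import FeatureConfig, featurize_recording, mel_filterbank
from bruitnet.evaluation import macro_ovr_auc

params = synth.CorpusParams(duration_range=(0.50, 0.52), n_patients=20)
beats, manifest = synth.synth_corpus({c: 100 for c in synth.CLASSES}, params, seed=1)

config = FeatureConfig(n_mels=64, target_frames=48)
fb = mel_filterbank(config.n_mels, config.fmax_hz, config.sample_rate_hz, config.window_len)
x = np.stack([featurize_recording(b.recording, config, fb).values.T for b in beats])
y = np.array([synth.CLASSES.index(b.sound_class) for b in beats])
pats = np.array([b.patient_id for b in beats])
train = np.array([b.split for b in beats]) == "train"

model = models.build_model(models.ArchitectureSpec(kind="crnn_bigru", n_mels=64), seed=1)
model, curve = models.train(
    model,
    models.TrainingSet(x[train], y[train], pats[train]),
    models.TrainingConfig(epochs=20, batch_size=16, seed=1),
)
probs = models.predict_batch(model, x[~train])
print("held-out macro one-vs-rest AUC:", macro_ovr_auc(probs, y[~train]))
print("held-out accuracy:", (probs.argmax(1) == y[~train]).mean())
```

On this seeded synthetic corpus the run printed:

```
held-out macro one-vs-rest AUC: 1.0
held-out accuracy: 1.0
```

The synthetic classes are constructed to be separable, so a correct
implementation should saturate these scores; the numbers certify the
pipeline, not clinical performance (see `docs/methods.md`).

The same flow is available from the shell:

```bash
bruit simulate --out corpus --n-per-class 100 --seed 1 --duration-range 0.5 0.52
bruit train corpus --kind crnn_bigru --n-mels 64 --target-frames 48 \
      --epochs 20 --out model.npz --curve curve.csv
bruit evaluate model.npz corpus --out metrics.csv --target-frames 48
bruit explain model.npz corpus --out-dir cams --class high --target-frames 48
```

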