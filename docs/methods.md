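# Methods

## The problem and the model

An arteriovenous fistula (AVF) produces an audible bruit whose character
tracks the hemodynamic state of the access vessel. The package
operationalizes a three-stage analysis of auscultation recordings:
per-beat extraction, spectrogram classification into five sound classes
(normal, hard, high, intermittent, whistle), and gradient-based
explanation of each decision. This note records the modeling choices, the
parameters that matter, what the synthetic data does and does not emulate,
and the scale at which the automated checks run.

## Beat segmentation

The segmenter assumes a bruit whose energy is concentrated in 2–750 Hz and
whose per-beat envelope is unimodal (a systolic peak with a diastolic
decay).

* **Envelope.** Mean short-time FFT magnitude over bins in 2–750 Hz;
  frame 0.05 s, hop 0.01 s. The frame length bounds frequency resolution
  at 20 Hz, so the 2 Hz lower edge reduces to "exclude the DC bin" —
  which is also its physical meaning at these durations. Frame/hop are
  exposed; 0.05/0.01 s resolve 0.5 s beats with an order of magnitude of
  margin.
* **Smoothing.** A cubic smoothing spline evaluated at the frame times.
  The residual-sum target defaults to `n_frames × σ̂²`, with σ̂² a robust
  first-difference (Rice) estimate of the envelope's frame-to-frame noise.
  An envelope-variance-proportional target was rejected: over a minute of
  beats the envelope's variance is dominated by the beats themselves, and
  a target proportional to it flattens the signal rather than the noise.
  `smoothing=0` gives the interpolating spline.
* **Convex ranges.** Candidate beats are minimum-to-minimum spans around
  peaks with prominence ≥ 10 % of the global envelope maximum (suppressing
  micro-bumps); spans outside 0.5–2 s are discarded. The duration filter
  doubles as the non-auscultation rejector: handling noise, silence and
  probe movement all produce envelope features outside the physiologic
  beat-length band. Plateau ties resolve to the leftmost extremum (the
  peak finder's convention).
* **Gate.** A binary classifier (the same VGG13 trunk as the five-class
  models, 2-class head) scores each candidate's log-mel spectrogram as
  bruit vs environment; acceptance requires probability strictly greater
  than 0.5, so an exactly ambivalent candidate is rejected. The gate's
  negatives here are synthetic environment clips (hum, babble, clatter);
  a deployment against real ward noise would need to retrain it on a real
  environmental corpus.

## Features

STFT with a 4096-sample periodic Hann window and 2048 hop at 192 kHz
(frame count exactly `1 + floor((N − 4096)/2048)`, no centering or
padding); triangular mel filters (HTK scale, unit peak) spanning 0–2000 Hz;
`log(· + 1e−10)`; per-clip standardization over real frames; tail padding
with the post-standardization blank value 0 to a fixed frame count
(default 400). The 2000 Hz ceiling reflects that the bruit's spectral
content converges below ~1500 Hz, with margin for transient spikes.

Two numerical quirks are deliberate:

* With a 4096-point window at 192 kHz only 43 FFT bins lie at or below
  2000 Hz, so filter banks of 64 and up cannot all own a distinct bin.
  Filters narrower than one bin are realized by interpolating their peak
  onto the two bracketing bins, and construction emits a warning. The
  information content beyond ~43 filters is limited; the larger banks are
  supported because the resolution sweep is part of the design space.
* Standardization treats a spread below 1e−8 (log-scale units) as
  degenerate and only centers, so a silent clip maps to exactly zero
  rather than amplified rounding noise.

## Classifiers

All three kinds share a VGG13 trunk: five pairs of 3×3 convolutions
(64, 64 → 128, 128 → 256, 256 → 512, 512 → 512, 512), each convolution
followed by batch normalization and ReLU. 2×2 max pooling follows the
first four pairs; a fifth 2×2 pooling is appended after the last pair so
that a 400-frame input reaches exactly 12 time frames at the head — the
printed time-axis contract — under floor-division pooling
(400→200→100→50→25→12). The CRNN kinds unfold the trunk output into time
steps of flattened frequency×channel features and run a 512-wide
bidirectional GRU or LSTM before ReLU, time-average pooling and the
5-class softmax; the plain CNN applies global average pooling directly.

Training: Adam (lr 1e−3 default, β = 0.9/0.999), class-weighted softmax
cross-entropy normalized by the summed weights (so unit weights reduce
exactly to the unweighted mean and rescaling all weights is a no-op),
class weights `w_c = N/(K·N_c)` (inverse frequency; balanced counts give
1.0), batch 16, a patient-grouped validation split (20 %), best
validation-accuracy epoch retained. Patient leakage across splits is an
error, not a warning. Batch size, optimizer and learning rate are
config-exposed; none has a principled reference value.

The engine (`bruitnet.nn`) is a seeded NumPy implementation: channels-last
im2col convolution driven by BLAS GEMMs, with numba-fused kernels for the
patch gather/scatter, batch-norm arithmetic and the Adam update (the
memory-bound parts of single-core training). Every layer's backward pass
is verified against central finite differences in float64, where the
layers fall back to pure NumPy; the float32 fast path is cross-checked
against the float64 path. Max-pool gradients split ties evenly, which
keeps the operator finite-difference-exact. All computation is a pure
function of configuration and seed, so training runs are bit-reproducible
on a fixed BLAS.

## Evaluation and ensembling

Per-class scores are one-vs-rest projections of the softmax vector. ROC
curves sweep the unique scores (tied scores flip together) and AUC is the
trapezoidal area — equal, by construction, to the pairwise concordance
statistic, which the tests verify by exhaustive enumeration. Best-model
selection takes the per-class argmax of an AUC table with deterministic
tie-breaking (smaller filter count first, then CNN < GRU < LSTM). The
stacking ensemble fits, per class, a logistic regression on the base
models' one-vs-rest scores, using data disjoint from base-model training
(overlap is an error); the stacked vector is renormalized to sum to 1.
For per-class ROC analysis the raw (un-renormalized) meta scores are
available, since renormalization couples the classes. Metric reports
compute accuracy, precision, recall, specificity, F1 and AUC from the
one-vs-rest confusion at the argmax rule by default, with optional
per-class probability thresholds for low-false-positive operation on rare
classes. The longitudinal trend table reports per-date mean class
probability and argmax share, sorted chronologically.

## Grad-CAM

Attribution targets a convolutional activation in the trunk — for the CRNN
kinds the conv trunk only. Channel weights are the spatially averaged
gradients of the target class logit; the weighted channel sum is
rectified, bilinearly upsampled to the input grid and max-normalized, with
all-zero maps left at zero. Normalization makes maps invariant to positive
rescaling of the logits.

The target layer is resolution-aware: the deepest conv activation whose
time axis still has at least 8 cells. For reference-width (400-frame)
inputs that is the activation after the last convolution — the standard
Grad-CAM choice (25 time cells). For compact inputs the final block's
receptive field covers the whole clip, its cells carry no positional
information, and maps computed there place heat essentially at random (we
observed perfect-accuracy models whose last-conv maps localized correctly
under one training seed and not another); the back-off restores stable
localization.

Localization should be read from the pure-CNN kind: in controlled runs the
VGG13's "high"-class heat lands in the systolic 250–750 Hz region across
training seeds, while gradients routed through the CRNNs' bidirectional
recurrence mix time steps and do not place credit positionally. The CRNN
maps remain available but are qualitative.

## Synthetic data: what it emulates, and what it does not

`bruitnet.synth` renders each class from its qualitative acoustic
description: band-limited Gaussian turbulence amplitude-modulated by a
raised-cosine systole (fraction 0.35 of the beat, a typical physiological
value) and exponential diastolic decay. Class parameters: diastolic floor
0.30 of peak (normal/high/whistle), 0.06 (hard — chosen so the
peak-to-diastole ratio is at least 3× the normal class's, the contract the
class is defined by), 0.01 (intermittent); hard extends the noise band to
1500 Hz; high adds a dominant 250–750 Hz component gated to systole;
whistle adds a tone at 800–1500 Hz with a ±1 % wobble at 4 Hz. Band
limiting uses 4th-order Butterworth filtering, run forward-backward; edges
below 20 Hz are realized as lowpass plus mean removal because a Butterworth
bandpass with a few-Hz edge at a 192 kHz rate is numerically degenerate.
Environmental stand-ins: 50 Hz mains hum with harmonics, speech-band
amplitude-modulated babble, sparse clatter transients, silence. Corpora
assign beats to simulated patients (per-patient heart rate and gain), mix
white background noise at a configurable SNR (default 15 dB), and split
strictly by patient. The default class mix is the reference training-corpus
proportion 394:578:670:91:91.

What passing tests therefore show: the segmentation, feature, training,
ensembling and attribution machinery is correct, deterministic under seed,
and able to learn spectro-temporally defined classes from imbalanced,
patient-grouped data. What they do not show: performance on real bruit,
where class boundaries are gradual, labels are noisy, inter-patient
variability dwarfs the class signal, and environmental sound is far
richer. The synthetic classes are constructed to be separable, so
near-perfect held-out scores are the expected behavior of a correct
implementation, not a clinical claim.

## Problem sizes of the automated checks

The test suite and the acceptance script run the full pipeline at desk
scale, chosen once as the package's reference check conditions: corpora of
100 beats per class from 20 simulated patients with beat durations
0.50–0.52 s (a tachycardic but physiological heart-rate band) on a
48-frame padded time axis, 20 training epochs; the gate trains on 160
bruit + 160 environment clips with full-range 0.5–2 s durations on a
192-frame axis; segmentation runs on a one-minute 60 bpm recording at
10 dB SNR with three clatter bursts. The 400-frame reference axis remains
the default everywhere and the 400→12 contract is verified directly; the
compact training axis simply keeps a full training run in the
ten-minute range on one CPU. On these conditions the end-to-end run
reaches macro one-vs-rest AUC ≈ 1.0 on held-out patients (see the README's
worked example).

## Known limitations

* The recorded-to-400-frames padding convention means a ≤2 s beat occupies
  at most ~187 real frames; the remaining width is blank. The fixed width
  is honored as the input contract; no cropping or re-scaling is applied.
* The gate and classifier share a front end but are trained independently;
  no joint calibration is attempted.
* Multi-label sounds (e.g., simultaneous whistle and intermittent) are out
  of scope: the taxonomy is single-label by construction.
* Stenosis severity is not regressed; class probabilities are relative to
  the training distribution and are not a monotone severity scale.
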