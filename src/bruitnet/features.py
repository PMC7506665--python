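"""Fixed-size log-mel spectrogram features for single-beat bruit audio.

The classifiers consume a log-compressed mel spectrogram computed from
high-resolution (192 kHz) audio with a 4096-sample window and 2048-sample
hop, mel filters capped at 2000 Hz (bruit energy converges below ~1500 Hz;
the ceiling keeps a margin for transient spikes), per-clip standardization,
and blank-padding of the time axis to a fixed frame count so every beat —
long (slow heart rate) or short (fast) — presents the same input width.

With a 4096-point window at 192 kHz the linear-frequency resolution is
46.875 Hz, so only 43 FFT bins lie at or below the 2000 Hz ceiling. Filter
bank sizes beyond that (the 64–1024 sweep) cannot all own a distinct bin;
they are realized as interpolated triangles (each filter is guaranteed
nonzero weight on the bins bracketing its peak) and a warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .audio_io import AudioRecording

__all__ = [
    "FeatureConfig",
    "Spectrogram",
    "LogMelSpectrogram",
    "stft",
    "mel_filterbank",
    "log_mel",
    "pad_to_length",
    "featurize_recording",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Front-end parameters shared by the gate and the five-class models."""

    sample_rate_hz: int = 192_000
    window_len: int = 4096
    hop_len: int = 2048
    n_mels: int = 64
    fmax_hz: float = 2000.0
    target_frames: int = 400
    log_floor: float = 1e-10


@dataclass(frozen=True)
class Spectrogram:
    """Short-time magnitude spectrum: ``magnitudes[frame, bin]`` ≥ 0."""

    magnitudes: np.ndarray
    window_len: int
    hop_len: int
    sample_rate_hz: int

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def bin_hz(self) -> np.ndarray:
        """Center frequency of each FFT bin."""
        return np.fft.rfftfreq(self.window_len, d=1.0 / self.sample_rate_hz)


@dataclass(frozen=True)
class LogMelSpectrogram:
    """Log-compressed mel features, ``values[frame, mel]``.

    ``pad_mask[frame]`` is True on real frames and False on appended blanks.
    """

    values: np.ndarray
    n_mels: int
    fmax_hz: float
    pad_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pad_mask is None:
            object.__setattr__(
                self, "pad_mask", np.ones(self.values.shape[0], dtype=bool)
            )
        if self.values.shape[0] != self.pad_mask.shape[0]:
            raise ValueError("pad_mask length must match frame count")
        if self.values.shape[1] != self.n_mels:
            raise ValueError("values width must equal n_mels")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def n_stft_frames(n_samples: int, window_len: int = 4096, hop_len: int = 2048) -> int:
    """Number of full analysis frames: ``1 + floor((N - window) / hop)``."""
    if n_samples < window_len:
        raise ValueError(
            f"audio of {n_samples} samples is shorter than one window ({window_len})"
        )
    return 1 + (n_samples - window_len) // hop_len


def stft(
    recording: AudioRecording, window_len: int = 4096, hop_len: int = 2048
) -> Spectrogram:
    """Hann-windowed short-time magnitude spectrum (no centering, no padding).

    Frame count is exactly ``1 + floor((N - window_len) / hop_len)``.
    """
    x = np.asarray(recording.samples, dtype=np.float32)
    n_stft_frames(x.size, window_len, hop_len)  # raises on short audio
    frames = sliding_window_view(x, window_len)[::hop_len]
    # periodic Hann: exact nulls at integer bin offsets >= 2
    window = (0.5 - 0.5 * np.cos(2 * np.pi * np.arange(window_len) / window_len)).astype(
        np.float32
    )
    mags = np.abs(np.fft.rfft(frames * window, axis=1)).astype(np.float32)
    return Spectrogram(
        magnitudes=mags,
        window_len=window_len,
        hop_len=hop_len,
        sample_rate_hz=recording.sample_rate_hz,
    )


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int,
    fmax_hz: float = 2000.0,
    sample_rate_hz: int = 192_000,
    window_len: int = 4096,
) -> np.ndarray:
    """Triangular mel filters (HTK scale, unit peak) spanning [0, fmax_hz].

    Returns a ``(n_mels, window_len // 2 + 1)`` weight matrix. When
    ``n_mels`` exceeds the number of FFT bins at or below ``fmax_hz``,
    filters narrower than one bin are realized by linear interpolation of
    their peak onto the two bracketing bins, and a warning is issued.
    """
    if n_mels < 1:
        raise ValueError("n_mels must be >= 1")
    if fmax_hz > sample_rate_hz / 2:
        raise ValueError("fmax_hz exceeds the Nyquist frequency")
    bin_hz = np.fft.rfftfreq(window_len, d=1.0 / sample_rate_hz)
    n_bins = bin_hz.size
    in_band = int(np.sum(bin_hz <= fmax_hz))
    if n_mels > in_band:
        warnings.warn(
            f"{n_mels} mel filters over only {in_band} FFT bins <= {fmax_hz} Hz; "
            "filters narrower than one bin are interpolated",
            RuntimeWarning,
            stacklevel=2,
        )
    mel_pts = np.linspace(0.0, float(_hz_to_mel(fmax_hz)), n_mels + 2)
    hz_pts = np.asarray(_mel_to_hz(mel_pts))  # left edges, peaks, right edges

    weights = np.zeros((n_mels, n_bins), dtype=np.float64)
    bin_step = bin_hz[1] - bin_hz[0]
    for i in range(n_mels):
        left, center, right = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bin_hz - left) / max(center - left, 1e-12)
        down = (right - bin_hz) / max(right - center, 1e-12)
        tri = np.maximum(0.0, np.minimum(up, down))
        # interpolated peak: guarantee nonzero weight on the bins bracketing
        # the filter center even when the triangle is narrower than one bin
        j = int(np.clip(np.floor(center / bin_step), 0, n_bins - 2))
        frac = center / bin_step - j
        tri[j] = max(tri[j], 1.0 - frac)
        tri[j + 1] = max(tri[j + 1], frac)
        peak = tri.max()
        if peak > 0:
            tri /= peak
        weights[i] = tri
    return weights


def log_mel(
    spec: Spectrogram,
    filterbank: np.ndarray,
    log_floor: float = 1e-10,
    standardize: bool = True,
) -> LogMelSpectrogram:
    """Mel-pool the magnitude spectrum and log-compress.

    ``values = log(magnitudes @ filterbank.T + log_floor)``, then per-clip
    standardization (zero mean, unit variance over real frames) so the
    representation is invariant to global amplitude scaling.
    """
    if filterbank.shape[1] != spec.magnitudes.shape[1]:
        raise ValueError(
            f"filterbank expects {filterbank.shape[1]} bins, "
            f"spectrogram has {spec.magnitudes.shape[1]}"
        )
    mel = spec.magnitudes.astype(np.float64) @ filterbank.T
    values = np.log(mel + log_floor)
    if standardize:
        mu = values.mean()
        sd = values.std()
        # a constant clip (e.g. silence) has only rounding-level spread
        values = (values - mu) / sd if sd > 1e-8 else values - mu
    n_mels = filterbank.shape[0]
    fmax = float(np.fft.rfftfreq(spec.window_len, 1.0 / spec.sample_rate_hz)[
        filterbank[-1].nonzero()[0].max()
    ]) if filterbank[-1].any() else 0.0
    return LogMelSpectrogram(values=values.astype(np.float32), n_mels=n_mels, fmax_hz=fmax)


def pad_to_length(spec: LogMelSpectrogram, target_frames: int = 400) -> LogMelSpectrogram:
    """Append blank frames (value 0 post-standardization) up to ``target_frames``.

    Real frames are preserved bit-identically; appended frames have
    ``pad_mask`` False. Input longer than the target is an error.
    """
    n = spec.n_frames
    if n > target_frames:
        raise ValueError(
            f"spectrogram has {n} frames, more than target {target_frames}"
        )
    if n == target_frames:
        return spec
    pad = np.zeros((target_frames - n, spec.values.shape[1]), dtype=spec.values.dtype)
    values = np.concatenate([spec.values, pad], axis=0)
    mask = np.concatenate([spec.pad_mask, np.zeros(target_frames - n, dtype=bool)])
    return replace(spec, values=values, pad_mask=mask)


def mel_peak_frequencies_hz(
    n_mels: int, fmax_hz: float = 2000.0
) -> np.ndarray:
    """Peak (center) frequency of each mel filter; strictly increasing."""
    mel_pts = np.linspace(0.0, float(_hz_to_mel(fmax_hz)), n_mels + 2)
    return np.asarray(_mel_to_hz(mel_pts))[1:-1]


def featurize_recording(
    recording: AudioRecording, config: FeatureConfig, filterbank: np.ndarray | None = None
) -> LogMelSpectrogram:
    """Full front end: STFT → mel → log → standardize → pad to fixed width."""
    if filterbank is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            filterbank = mel_filterbank(
                config.n_mels, config.fmax_hz, config.sample_rate_hz, config.window_len
            )
    spec = stft(recording, config.window_len, config.hop_len)
    lm = log_mel(spec, filterbank, log_floor=config.log_floor)
    return pad_to_length(lm, config.target_frames)
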