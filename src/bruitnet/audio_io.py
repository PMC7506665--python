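"""Mono PCM WAV reading, writing and slicing.

This is the pipeline's only contact with the WAV container. Auscultation
recorders in this domain produce high-resolution PCM (the reference format
is 24-bit / 192 kHz), so 24-bit integer frames are supported in both
directions; 16-bit integer and 32-bit float round out the formats a bedside
recorder or an export tool may emit. Amplitudes are normalized to [-1, 1]
at read time so all downstream signal processing is bit-depth independent.
"""

from __future__ import annotations

import struct
import wave
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["AudioRecording", "read_wav", "write_wav", "slice_audio"]

#: reference acquisition format of the auscultation recorder
REFERENCE_SAMPLE_RATE_HZ = 192_000
REFERENCE_BIT_DEPTH = 24


@dataclass(frozen=True)
class AudioRecording:
    """A mono audio signal with amplitudes in [-1, 1].

    Parameters
    ----------
    samples:
        1-D float array of amplitudes in [-1, 1].
    sample_rate_hz:
        Sampling rate in Hz (reference 192000).
    bit_depth:
        Bit depth of the source or intended container (reference 24).
        Informational once samples are normalized.
    """

    samples: np.ndarray
    sample_rate_hz: int
    bit_depth: int = REFERENCE_BIT_DEPTH

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if samples.size and (np.min(samples) < -1.0 or np.max(samples) > 1.0):
            raise ValueError("amplitudes must lie in [-1, 1]")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def __len__(self) -> int:
        return self.samples.size


def _decode_pcm(raw: bytes, sampwidth: int, n_channels: int) -> np.ndarray:
    """Decode interleaved little-endian PCM frames to float in [-1, 1]."""
    if sampwidth == 2:
        data = np.frombuffer(raw, dtype="<i2").astype(np.float64)
        data /= 2.0**15
    elif sampwidth == 3:
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        # sign-extend 24-bit little-endian into int32
        as32 = (
            b[:, 0].astype(np.int32)
            | (b[:, 1].astype(np.int32) << 8)
            | (b[:, 2].astype(np.int32) << 16)
        )
        as32 = np.where(as32 >= 1 << 23, as32 - (1 << 24), as32)
        data = as32.astype(np.float64) / 2.0**23
    else:
        raise ValueError(f"unsupported PCM sample width {sampwidth} bytes")
    if n_channels > 1:
        data = data.reshape(-1, n_channels).mean(axis=1)
    return data


def _read_float32_wav(path: Path) -> tuple[np.ndarray, int, int]:
    """Minimal RIFF parser for IEEE-float WAVs (stdlib wave rejects them)."""
    with open(path, "rb") as fh:
        riff, _, wave_id = struct.unpack("<4sI4s", fh.read(12))
        if riff != b"RIFF" or wave_id != b"WAVE":
            raise ValueError(f"{path} is not a RIFF/WAVE file")
        fmt = None
        data = None
        while True:
            header = fh.read(8)
            if len(header) < 8:
                break
            chunk_id, size = struct.unpack("<4sI", header)
            payload = fh.read(size + (size & 1))
            if chunk_id == b"fmt ":
                fmt = struct.unpack("<HHIIHH", payload[:16])
            elif chunk_id == b"data":
                data = payload[:size]
        if fmt is None or data is None:
            raise ValueError(f"{path}: missing fmt or data chunk")
    audio_format, n_channels, rate, _, _, bits = fmt
    if audio_format != 3 or bits != 32:
        raise ValueError(
            f"{path}: unsupported encoding (format tag {audio_format}, {bits}-bit)"
        )
    samples = np.frombuffer(data, dtype="<f4").astype(np.float64)
    if n_channels > 1:
        samples = samples.reshape(-1, n_channels).mean(axis=1)
    return samples, rate, 32


def read_wav(path: str | Path) -> AudioRecording:
    """Read a PCM WAV file as a mono :class:`AudioRecording`.

    Integer samples are scaled to [-1, 1] by ``2**(bits-1)``; multi-channel
    input is downmixed to mono by channel averaging. Supported encodings:
    16/24-bit integer PCM and 32-bit IEEE float.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with wave.open(str(path), "rb") as wf:
            n_channels = wf.getnchannels()
            sampwidth = wf.getsampwidth()
            rate = wf.getframerate()
            raw = wf.readframes(wf.getnframes())
    except wave.Error as exc:
        # stdlib wave rejects IEEE-float; fall back to a direct RIFF parse
        try:
            samples, rate, bits = _read_float32_wav(path)
        except ValueError:
            raise ValueError(f"{path}: unsupported WAV encoding ({exc})") from exc
        if samples.size and np.max(np.abs(samples)) > 1.0:
            samples = np.clip(samples, -1.0, 1.0)
        return AudioRecording(samples, rate, bit_depth=bits)
    if sampwidth not in (2, 3):
        raise ValueError(
            f"{path}: unsupported PCM width {8 * sampwidth} bits "
            "(expected 16- or 24-bit integer, or 32-bit float)"
        )
    samples = _decode_pcm(raw, sampwidth, n_channels)
    return AudioRecording(samples, rate, bit_depth=8 * sampwidth)


def write_wav(
    recording: AudioRecording, path: str | Path, bit_depth: int = REFERENCE_BIT_DEPTH
) -> Path:
    """Write a recording as integer PCM WAV.

    Amplitudes outside [-1, 1] are an error (never silently clipped); the
    AudioRecording invariant normally guarantees this.
    """
    if bit_depth not in (16, 24):
        raise ValueError(f"bit_depth must be 16 or 24, got {bit_depth}")
    samples = np.asarray(recording.samples, dtype=np.float64)
    if samples.size and (np.min(samples) < -1.0 or np.max(samples) > 1.0):
        raise ValueError("amplitudes outside [-1, 1]; refusing to clip on write")
    path = Path(path)
    full_scale = 2 ** (bit_depth - 1)
    # round-to-nearest; +1.0 maps to the largest representable code
    ints = np.clip(np.rint(samples * full_scale), -full_scale, full_scale - 1)
    ints = ints.astype(np.int32)
    if bit_depth == 16:
        raw = ints.astype("<i2").tobytes()
        sampwidth = 2
    else:
        u = ints.astype(np.uint32) & 0xFFFFFF
        b = np.empty((ints.size, 3), dtype=np.uint8)
        b[:, 0] = u & 0xFF
        b[:, 1] = (u >> 8) & 0xFF
        b[:, 2] = (u >> 16) & 0xFF
        raw = b.tobytes()
        sampwidth = 3
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(sampwidth)
        wf.setframerate(recording.sample_rate_hz)
        wf.writeframes(raw)
    return path


def slice_audio(recording: AudioRecording, start_s: float, end_s: float) -> AudioRecording:
    """Extract ``[start_s, end_s)`` as a new recording (half-open, 0-based).

    Sample indices are ``floor(t * rate)``; the sample rate is preserved.
    """
    if not (0.0 <= start_s < end_s):
        raise ValueError(f"invalid interval [{start_s}, {end_s})")
    if end_s > recording.duration_s + 1e-12:
        raise ValueError(
            f"interval end {end_s} s exceeds duration {recording.duration_s} s"
        )
    rate = recording.sample_rate_hz
    i0 = int(np.floor(start_s * rate))
    i1 = int(np.floor(min(end_s, recording.duration_s) * rate))
    return AudioRecording(
        recording.samples[i0:i1], rate, bit_depth=recording.bit_depth
    )
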