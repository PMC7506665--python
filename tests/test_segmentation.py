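"""Envelope, spline smoothing, convex-range detection and the gate."""

import numpy as np
import pytest

from bruitnet import synth
from bruitnet.audio_io import AudioRecording
from bruitnet.segmentation import (
    BeatCandidate,
    Envelope,
    GateDecision,
    band_energy_envelope,
    detect_convex_ranges,
    gate_candidates,
    spline_smooth,
    train_gate,
)

FS = 192_000


def tone(freq, dur=1.0, amp=0.5):
    t = np.arange(int(dur * FS)) / FS
    return AudioRecording(amp * np.sin(2 * np.pi * freq * t), FS)


def bump_train(durations, floor=0.02, gap=0.3, peak=0.5):
    """Raised-cosine envelope bumps on a low floor, as a test waveform.

    Returns (recording, onset times). The carrier is in-band (300 Hz)
    noise-free sine so the band-energy envelope follows the bump shape.
    """
    total = gap + sum(d + gap for d in durations)
    n = int(total * FS)
    t = np.arange(n) / FS
    env = np.full(n, floor)
    onsets = []
    cursor = gap
    for d in durations:
        onsets.append(cursor)
        seg = (t >= cursor) & (t < cursor + d)
        env[seg] = floor + (peak - floor) * np.sin(
            np.pi * (t[seg] - cursor) / d
        ) ** 2
        cursor += d + gap
    x = env * np.sin(2 * np.pi * 300.0 * t)
    return AudioRecording(x, FS), onsets


class TestEnvelope:
    def test_in_band_tone_dominates_out_of_band(self):
        env_in = band_energy_envelope(tone(300))
        env_out = band_energy_envelope(tone(1500))
        assert env_out.values.mean() < 0.01 * env_in.values.mean()

    def test_silence_is_zero(self):
        env = band_energy_envelope(AudioRecording(np.zeros(FS), FS))
        assert np.allclose(env.values, 0.0)

    def test_linear_in_amplitude(self):
        rec = tone(300, amp=0.25)
        env1 = band_energy_envelope(rec)
        env2 = band_energy_envelope(AudioRecording(2 * rec.samples, FS))
        assert np.allclose(env2.values, 2 * env1.values, rtol=1e-6)

    def test_invariant_to_energy_above_band(self):
        base = tone(300, amp=0.3)
        high = AudioRecording(
            np.clip(base.samples + tone(5000, amp=0.3).samples, -1, 1), FS
        )
        env_a = band_energy_envelope(base)
        env_b = band_energy_envelope(high)
        rel = np.abs(env_b.values - env_a.values).max() / env_a.values.max()
        assert rel < 0.01

    def test_band_validation(self):
        with pytest.raises(ValueError):
            band_energy_envelope(tone(300), band_hz=(750.0, 2.0))
        with pytest.raises(ValueError):
            band_energy_envelope(AudioRecording(np.zeros(100), FS))

    def test_envelope_type_invariants(self):
        with pytest.raises(ValueError):
            Envelope(np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            Envelope(np.array([0.0, 1.0]), np.array([1.0, -1.0]))


class TestSpline:
    def test_constant_envelope_unchanged(self):
        env = Envelope(np.linspace(0, 1, 50), np.full(50, 3.0))
        out = spline_smooth(env)
        assert np.allclose(out.values, 3.0, atol=1e-8)

    def test_noise_reduces_extrema_count(self):
        t = np.linspace(0, 4, 400)
        clean = np.sin(2 * np.pi * 1.0 * t) ** 2
        noisy = clean + 0.1 * np.random.default_rng(0).standard_normal(400)
        env = Envelope(t, np.clip(noisy + 1.0, 0, None))
        smooth = spline_smooth(env)

        def n_maxima(v):
            return int(np.sum((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])))

        assert n_maxima(smooth.values) < n_maxima(env.values)

    def test_zero_smoothing_interpolates(self):
        rng = np.random.default_rng(1)
        env = Envelope(np.linspace(0, 1, 20), rng.uniform(0.5, 1.0, 20))
        out = spline_smooth(env, smoothing=0.0)
        assert np.allclose(out.values, env.values, atol=1e-8)

    def test_too_few_frames(self):
        env = Envelope(np.array([0.0, 0.1, 0.2]), np.ones(3))
        with pytest.raises(ValueError, match="4 frames"):
            spline_smooth(env)


class TestConvexRanges:
    def _detect(self, durations, **kw):
        rec, onsets = bump_train(durations)
        env = spline_smooth(band_energy_envelope(rec))
        return detect_convex_ranges(env, **kw), onsets

    def test_five_unit_bumps_detected_with_accurate_onsets(self):
        cands, onsets = self._detect([1.0] * 5)
        assert len(cands) == 5
        for cand, onset in zip(cands, onsets):
            assert abs(cand.start_s - onset) < 0.1

    @pytest.mark.parametrize("dur", [0.3, 2.5])
    def test_out_of_range_durations_rejected(self, dur):
        cands, _ = self._detect([dur])
        assert cands == []

    def test_candidates_sorted_nonoverlapping_within_bounds(self):
        cands, _ = self._detect([1.0, 0.8, 1.2, 0.9])
        for a, b in zip(cands, cands[1:]):
            assert a.end_s <= b.start_s + 1e-9
        for c in cands:
            assert 0.5 <= c.duration_s <= 2.0

    def test_silence_yields_no_candidates(self):
        env = Envelope(np.linspace(0, 10, 1000), np.zeros(1000))
        assert detect_convex_ranges(env) == []


class TestGate:
    def test_decision_threshold_is_strict(self):
        cand = BeatCandidate(0.0, 1.0, 1.0)
        assert not GateDecision(cand, 0.5).accepted
        assert GateDecision(cand, 0.51).accepted
        assert not GateDecision(cand, 0.49).accepted

    def test_training_requires_both_classes(self):
        beat = synth.synth_beat(synth.BeatSpec("normal", 1.0, seed=0))
        with pytest.raises(ValueError, match="environment"):
            train_gate([beat], [])
        with pytest.raises(ValueError, match="environment"):
            train_gate([], [beat])

    def test_untrained_gate_rejected_by_scorer(self):
        from bruitnet.features import FeatureConfig
        from bruitnet.segmentation import GateModel, _build_gate_net

        model = GateModel(
            _build_gate_net(32, np.random.default_rng(0)),
            FeatureConfig(n_mels=32, target_frames=64),
        )
        rec = synth.synth_beat(synth.BeatSpec("normal", 1.0, seed=0))
        with pytest.raises(ValueError, match="trained"):
            gate_candidates([BeatCandidate(0.0, 1.0, 1.0)], rec, model)


class TestTrainedGate:
    """Checks against the session-trained gate (shared fixture)."""

    def test_held_out_auc_at_least_095(self, trained_gate):
        from bruitnet.evaluation import roc_auc

        gate, beats, clips = trained_gate
        scores = [gate.predict_proba(r) for r in clips + beats]
        labels = [False] * len(clips) + [True] * len(beats)
        assert roc_auc(scores, labels).auc >= 0.95

    def test_gate_decisions_on_candidates(self, trained_gate):
        gate, beats, clips = trained_gate
        rec, gt = synth.synth_recording(
            [synth.BeatSpec("normal", 1.0, seed=i) for i in range(3)],
            gap_s=0.2, seed=9,
        )
        cands = [BeatCandidate(s, e, 1.0) for s, e, _ in gt.beats]
        decisions = gate_candidates(cands, rec, gate)
        assert len(decisions) == 3
        assert all(0.0 <= d.avf_probability <= 1.0 for d in decisions)
        assert sum(d.accepted for d in decisions) >= 2
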