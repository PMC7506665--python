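"""Class signatures, mixing, determinism and corpus structure of the
synthetic bruit generator."""

import numpy as np
import pytest
from scipy import signal

from bruitnet import synth
from bruitnet.synth import BeatSpec, CorpusParams, GroundTruth

FS = 192_000


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.asarray(x) ** 2)))


def test_intermittent_diastole_is_nearly_silent():
    rec = synth.synth_beat(BeatSpec("intermittent", 1.0, seed=2), FS)
    x = rec.samples
    n = len(x)
    diastole = x[int(0.6 * n):]          # final 40 %
    systole = x[: int(0.35 * n)]
    assert rms(diastole) < 0.05 * rms(systole)


def test_whistle_has_narrowband_peak():
    rec = synth.synth_beat(BeatSpec("whistle", 1.0, whistle_hz=1000.0, seed=3), FS)
    f, p = signal.periodogram(rec.samples, fs=FS)
    peak_band = p[(f > 950) & (f < 1050)].max()
    floor = np.median(p[((f > 700) & (f < 900)) | ((f > 1100) & (f < 1300))])
    assert 10 * np.log10(peak_band / floor) >= 10.0


def test_hard_systolic_peak_exceeds_three_times_normal_ratio():
    def ratio(cls):
        rec = synth.synth_beat(BeatSpec(cls, 1.0, seed=5), FS)
        x = rec.samples
        n = len(x)
        return rms(x[: int(0.35 * n)]) / rms(x[int(0.5 * n): int(0.9 * n)])

    assert ratio("hard") >= 3.0 * ratio("normal")


def test_high_concentrates_energy_in_250_750_during_systole():
    rec = synth.synth_beat(BeatSpec("high", 1.0, seed=6), FS)
    sysw = rec.samples[: int(0.35 * len(rec))]
    f, p = signal.periodogram(sysw, fs=FS)
    in_band = p[(f >= 250) & (f <= 750)].sum()
    assert in_band / p.sum() >= 0.8


@pytest.mark.parametrize("cls", synth.CLASSES)
def test_band_energy_below_2khz(cls):
    rec = synth.synth_beat(BeatSpec(cls, 1.0, seed=4), FS)
    f, p = signal.periodogram(rec.samples, fs=FS)
    assert p[f < 2000].sum() / p.sum() >= 0.90


@pytest.mark.parametrize("cls", synth.CLASSES)
def test_seeded_determinism(cls):
    a = synth.synth_beat(BeatSpec(cls, 0.8, seed=11), FS)
    b = synth.synth_beat(BeatSpec(cls, 0.8, seed=11), FS)
    assert np.array_equal(a.samples, b.samples)
    c = synth.synth_beat(BeatSpec(cls, 0.8, seed=12), FS)
    assert not np.array_equal(a.samples, c.samples)


def test_beat_spec_validation():
    with pytest.raises(ValueError):
        BeatSpec("gurgle")
    with pytest.raises(ValueError):
        BeatSpec("normal", beat_duration_s=0.1)
    with pytest.raises(ValueError):
        BeatSpec("normal", systolic_fraction=1.5)


def test_environment_kinds():
    silence = synth.synth_environment("silence", 0.5, 0, FS)
    assert np.all(silence.samples == 0.0)
    hum = synth.synth_environment("hum", 2.0, 1, FS)
    f, p = signal.periodogram(hum.samples, fs=FS)
    assert abs(f[np.argmax(p)] - 50.0) < 2.0
    babble = synth.synth_environment("babble", 1.0, 2, FS)
    f, p = signal.periodogram(babble.samples, fs=FS)
    assert p[(f >= 100) & (f <= 4000)].sum() / p.sum() > 0.95
    with pytest.raises(ValueError):
        synth.synth_environment("doorbell", 1.0, 0, FS)
    with pytest.raises(ValueError):
        synth.synth_environment("hum", -1.0, 0, FS)


def test_recording_construction_and_ground_truth():
    specs = [BeatSpec("normal", 1.0, seed=i) for i in range(10)]
    rec, gt = synth.synth_recording(specs, gap_s=0.1, seed=0, sample_rate_hz=FS)
    assert len(gt.beats) == 10
    assert rec.duration_s == pytest.approx(10 * 1.0 + 11 * 0.1, abs=0.01)
    starts = [b[0] for b in gt.beats]
    assert starts == sorted(starts)


def test_recording_empty_beats_gives_pure_environment():
    rec, gt = synth.synth_recording([], environment_kinds=["hum"], seed=0,
                                    sample_rate_hz=FS)
    assert gt.beats == ()
    assert len(gt.environment_intervals) == 1
    assert np.any(rec.samples != 0.0)


def test_snr_zero_mixes_beat_and_environment_at_equal_rms():
    specs = [BeatSpec("normal", 1.0, snr_db=0.0, seed=i) for i in range(5)]
    rec, gt = synth.synth_recording(specs, gap_s=0.2, environment_kinds=["babble"],
                                    seed=3, sample_rate_hz=FS)
    # re-synthesize the beats-only track to isolate the environment residual
    only, _ = synth.synth_recording(specs, gap_s=0.2, seed=3, sample_rate_hz=FS)
    env = rec.samples[: len(only.samples)] - only.samples
    mask = np.zeros(len(only.samples), dtype=bool)
    for s, e, _ in gt.beats:
        mask[int(s * FS): int(e * FS)] = True
    ratio_db = 20 * np.log10(rms(only.samples[mask]) / rms(env[env != 0.0]))
    assert abs(ratio_db) <= 1.0


def test_duration_overflow_rejected():
    specs = [BeatSpec("normal", 3.0, seed=i) for i in range(120)]
    with pytest.raises(ValueError, match="300"):
        synth.synth_recording(specs, sample_rate_hz=FS)


def test_ground_truth_invariants():
    with pytest.raises(ValueError):
        GroundTruth(beats=((1.0, 2.0, "normal"), (0.0, 0.5, "hard")))
    with pytest.raises(ValueError):
        GroundTruth(beats=((0.0, 1.0, "normal"), (0.5, 1.5, "hard")))


class TestCorpus:
    PARAMS = CorpusParams(duration_range=(0.5, 0.6), n_patients=10)

    def test_default_mix_follows_reference_training_counts(self):
        beats, manifest = synth.synth_corpus(params=self.PARAMS, seed=0)
        counts = manifest["class"].value_counts().to_dict()
        assert counts == {"normal": 394, "hard": 578, "high": 670,
                          "intermittent": 91, "whistle": 91}

    def test_single_class_request(self):
        beats, manifest = synth.synth_corpus({"normal": 10}, self.PARAMS, seed=0)
        assert len(beats) == 10
        assert all(b.sound_class == "normal" for b in beats)

    def test_patient_grouped_split_is_disjoint(self):
        _, manifest = synth.synth_corpus({c: 20 for c in synth.CLASSES},
                                         self.PARAMS, seed=1)
        train_p = set(manifest.loc[manifest.split == "train", "patient_id"])
        test_p = set(manifest.loc[manifest.split == "test", "patient_id"])
        assert train_p and test_p
        assert not (train_p & test_p)

    def test_corpus_is_seeded(self):
        a, ma = synth.synth_corpus({"hard": 3}, self.PARAMS, seed=5)
        b, mb = synth.synth_corpus({"hard": 3}, self.PARAMS, seed=5)
        assert all(
            np.array_equal(x.recording.samples, y.recording.samples)
            for x, y in zip(a, b)
        )
        assert ma.equals(mb)

    def test_empty_and_invalid_requests(self):
        with pytest.raises(ValueError):
            synth.synth_corpus({c: 0 for c in synth.CLASSES}, self.PARAMS)
        with pytest.raises(ValueError):
            synth.synth_corpus({"normal": -1}, self.PARAMS)
        with pytest.raises(ValueError):
            synth.synth_corpus({"squeak": 5}, self.PARAMS)
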