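"""ROC/AUC against the pairwise-concordance oracle, model selection,
stacking and metric reports."""

import numpy as np
import pytest

from bruitnet.evaluation import (
    class_trend,
    fit_stacker,
    macro_ovr_auc,
    metrics_report,
    roc_auc,
    select_best_models,
    stacker_predict,
)
from bruitnet.synth import CLASSES


def pairwise_concordance_auc(scores, labels):
    """Independent oracle: (concordant + 0.5 * tied) / all positive-negative
    pairs, by exhaustive enumeration."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = concordant = tied = 0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                concordant += 1
            elif p == n:
                tied += 1
    return (concordant + 0.5 * tied) / total


class TestRocAuc:
    def test_perfect_and_reversed_separation(self):
        labels = [True, True, False, False]
        assert roc_auc([1.0, 1.0, 0.0, 0.0], labels).auc == 1.0
        assert roc_auc([0.0, 0.0, 1.0, 1.0], labels).auc == 0.0

    def test_printed_example(self):
        res = roc_auc([0.9, 0.8, 0.7, 0.6], [True, False, True, False])
        assert res.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [True, True])

    def test_curve_monotone_and_trapezoid_consistent(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=40)
        labels = rng.uniform(size=40) < 0.4
        res = roc_auc(scores, labels)
        assert np.all(np.diff(res.fpr) >= 0)
        assert np.all(np.diff(res.tpr) >= 0)
        assert res.auc == pytest.approx(np.trapezoid(res.tpr, res.fpr))

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for trial in range(30):
            n = int(rng.integers(4, 50))
            scores = rng.integers(0, 6, n) / 5.0  # heavy ties
            labels = rng.uniform(size=n) < 0.5
            if labels.all() or (~labels).all():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                pairwise_concordance_auc(scores, labels), abs=1e-12
            )

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        aucs = [
            roc_auc(rng.uniform(size=200), rng.uniform(size=200) < 0.5).auc
            for _ in range(50)
        ]
        # AUC variance for n1=n2=100 under the null is about 0.0011
        assert abs(np.mean(aucs) - 0.5) < 3 * np.sqrt(0.0011 / 50)


#: per-class AUC table as printed by the reference study (feature count ×
#: model kind); used as input data for the selection rule
TABLE4 = {}
_T4 = {
    "normal": {64: (0.58, 0.59, 0.60), 128: (0.70, 0.72, 0.64), 256: (0.69, 0.73, 0.66),
               512: (0.69, 0.72, 0.66), 1024: (0.70, 0.72, 0.65)},
    "hard": {64: (0.70, 0.70, 0.68), 128: (0.81, 0.81, 0.69), 256: (0.84, 0.87, 0.78),
             512: (0.83, 0.90, 0.85), 1024: (0.83, 0.91, 0.73)},
    "high": {64: (0.77, 0.77, 0.76), 128: (0.80, 0.77, 0.78), 256: (0.80, 0.80, 0.80),
             512: (0.78, 0.80, 0.80), 1024: (0.79, 0.76, 0.77)},
    "intermittent": {64: (0.83, 0.88, 0.77), 128: (0.78, 0.85, 0.82),
                     256: (0.83, 0.78, 0.77), 512: (0.87, 0.87, 0.82),
                     1024: (0.84, 0.94, 0.92)},
    "whistle": {64: (0.89, 0.85, 0.85), 128: (0.89, 0.89, 0.86),
                256: (0.89, 0.89, 0.89), 512: (0.87, 0.87, 0.87),
                1024: (0.88, 0.88, 0.86)},
}
for cls, by_mels in _T4.items():
    for mels, (cnn, gru, lstm) in by_mels.items():
        TABLE4[(cls, "cnn", mels)] = cnn
        TABLE4[(cls, "gru", mels)] = gru
        TABLE4[(cls, "lstm", mels)] = lstm


class TestSelectBestModels:
    def test_published_argmax_cells(self):
        chosen = select_best_models(TABLE4)
        assert chosen["hard"] == ("gru", 1024)        # 0.91
        assert chosen["intermittent"] == ("gru", 1024)  # 0.94

    def test_tie_breaks_toward_smaller_feature_count_then_cnn(self):
        chosen = select_best_models(TABLE4)
        # high ties at 0.80 from 128 features up; whistle ties at 0.89 from 64
        assert chosen["high"] == ("cnn", 128)
        assert chosen["whistle"] == ("cnn", 64)

    def test_dominant_model_chosen_everywhere(self):
        table = {}
        for cls in CLASSES:
            table[(cls, "cnn", 64)] = 0.7
            table[(cls, "lstm", 128)] = 0.95
        chosen = select_best_models(table)
        assert all(v == ("lstm", 128) for v in chosen.values())

    def test_missing_class_rejected(self):
        table = {("normal", "cnn", 64): 0.8}
        with pytest.raises(ValueError, match="absent"):
            select_best_models(table)


def _synthetic_scores(seed, informative_for):
    """Base-model scores informative only for the given class."""
    rng = np.random.default_rng(seed)
    n = 400
    labels = rng.integers(0, 5, n)
    probs = rng.dirichlet(np.ones(5), size=n)
    c = CLASSES.index(informative_for)
    boost = np.where(labels == c, 0.65, 0.05) + rng.uniform(0, 0.15, n)
    probs[:, c] = boost
    probs /= probs.sum(axis=1, keepdims=True)
    return probs, labels


class TestStacking:
    def test_stack_dominates_specialist_base_models(self):
        probs_a, labels = _synthetic_scores(0, "hard")
        probs_b, _ = _synthetic_scores(0, "whistle")
        base = {"A": probs_a, "B": probs_b}
        half = len(labels) // 2
        spec = fit_stacker(
            {k: v[:half] for k, v in base.items()}, labels[:half], seed=0
        )
        stacked = stacker_predict(spec, {k: v[half:] for k, v in base.items()})
        stacked_auc = macro_ovr_auc(stacked, labels[half:])
        single = max(
            macro_ovr_auc(probs_a[half:], labels[half:]),
            macro_ovr_auc(probs_b[half:], labels[half:]),
        )
        assert stacked_auc >= single

    def test_single_base_model_preserves_ranking(self):
        # a base model informative for every class: the degenerate stack's
        # per-class meta score is a monotone map of the base score
        rng = np.random.default_rng(3)
        n = 400
        labels = rng.integers(0, 5, n)
        logits = rng.standard_normal((n, 5))
        logits[np.arange(n), labels] += 2.0
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        spec = fit_stacker({"only": probs}, labels, seed=0)
        stacked = stacker_predict(spec, {"only": probs}, renormalize=False)
        for c in range(5):
            pos = labels == c
            assert roc_auc(stacked[:, c], pos).auc == pytest.approx(
                roc_auc(probs[:, c], pos).auc, abs=1e-6
            )

    def test_seeded_fit_reproducible(self):
        probs, labels = _synthetic_scores(4, "hard")
        a = stacker_predict(fit_stacker({"m": probs}, labels, seed=1), {"m": probs})
        b = stacker_predict(fit_stacker({"m": probs}, labels, seed=1), {"m": probs})
        assert np.allclose(a, b)

    def test_leaked_beats_rejected(self):
        probs, labels = _synthetic_scores(5, "hard")
        with pytest.raises(ValueError, match="leaked"):
            fit_stacker(
                {"m": probs}, labels, base_train_ids=[1, 2, 3],
                beat_ids=list(range(len(labels))),
            )

    def test_output_is_renormalized(self):
        probs, labels = _synthetic_scores(6, "whistle")
        stacked = stacker_predict(fit_stacker({"m": probs}, labels), {"m": probs})
        assert np.allclose(stacked.sum(axis=1), 1.0, atol=1e-9)


class TestMetricsReport:
    def test_perfect_predictions_score_one(self):
        labels = np.repeat(np.arange(5), 4)
        probs = np.eye(5)[labels] * 0.9 + 0.02
        report = metrics_report(probs, labels)
        for metric in ("accuracy", "precision", "recall", "specificity", "f1", "auc"):
            for cls in CLASSES:
                assert report[metric, cls] == pytest.approx(1.0)

    def test_always_positive_predictor_has_zero_specificity(self):
        labels = np.array([0, 0, 1, 2, 3, 4])
        probs = np.full((6, 5), 0.01)
        probs[:, 0] = 0.96
        report = metrics_report(probs, labels)
        assert report["specificity", "normal"] == 0.0
        assert report["recall", "normal"] == 1.0

    def test_hand_computed_confusion(self):
        # one-vs-rest confusion for class "normal": TP=43, FN=49, FP=54, TN=254
        tp, fn, fp, tn = 43, 49, 54, 254
        rng = np.random.default_rng(0)
        labels = np.concatenate([np.zeros(tp + fn, int), rng.integers(1, 5, fp + tn)])
        pred_pos = np.concatenate(
            [np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn)]
        ).astype(bool)
        probs = np.full((len(labels), 5), 0.1)
        probs[pred_pos, 0] = 0.9
        probs[~pred_pos, 1] = 0.9
        report = metrics_report(probs, labels)
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert report["accuracy", "normal"] == pytest.approx((tp + tn) / 400)
        assert report["precision", "normal"] == pytest.approx(precision)
        assert report["recall", "normal"] == pytest.approx(recall)
        assert report["specificity", "normal"] == pytest.approx(tn / (tn + fp))
        assert report["f1", "normal"] == pytest.approx(
            2 * precision * recall / (precision + recall)
        )

    def test_per_class_threshold_rule(self):
        labels = np.array([0, 0, 1, 1])
        probs = np.array(
            [[0.4, 0.6, 0, 0, 0], [0.35, 0.65, 0, 0, 0],
             [0.2, 0.8, 0, 0, 0], [0.1, 0.9, 0, 0, 0]]
        )
        report = metrics_report(probs, labels, thresholds={"normal": 0.3})
        assert report["recall", "normal"] == 1.0  # both normals above 0.3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics_report(np.zeros((3, 5)), np.zeros(4, int))


class TestClassTrend:
    def test_single_date_all_hard(self):
        probs = np.tile([0.05, 0.8, 0.05, 0.05, 0.05], (7, 1))
        trend = class_trend({"2024-01-01": probs})
        hard = trend[(trend["class"] == "hard")]
        assert hard["argmax_share"].iloc[0] == 1.0
        assert hard["mean_probability"].iloc[0] == pytest.approx(0.8)

    def test_ramping_intermittent_is_nondecreasing(self):
        days = {}
        for i, date in enumerate(["d1", "d2", "d3", "d4"]):
            p = np.full((10, 5), 0.1)
            p[:, 3] = 0.1 + 0.2 * i
            days[date] = p / p.sum(axis=1, keepdims=True)
        trend = class_trend(days)
        inter = trend[trend["class"] == "intermittent"]["mean_probability"].values
        assert np.all(np.diff(inter) >= 0)

    def test_chronological_order_regardless_of_input_order(self):
        p = np.full((2, 5), 0.2)
        trend = class_trend({"2024-02-01": p, "2024-01-01": p})
        dates = trend["date"].unique().tolist()
        assert dates == ["2024-01-01", "2024-02-01"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            class_trend({})
        with pytest.raises(ValueError):
            class_trend({"d": np.zeros((2, 3))})
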