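"""Evaluation metrics against hand-computed and confusion-matrix oracles."""

import numpy as np
import pytest

from phasecast import (PhaseTimeline, anticipation_mae, cap_eos,
                       horizon_scores, rsd_mae, seg_f1, select_model,
                       weighted_f1)
from phasecast.metrics import horizon_seg_f1
from phasecast.timelines import Segment, SegmentList, labels_to_segments

EOS = 7


def confusion_matrix_weighted_f1(preds, targets, n_classes):
    """Independent reference: per-class F1 from an explicit confusion
    matrix, averaged with weights proportional to target support."""
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for p, t in zip(preds, targets):
        cm[t, p] += 1
    total = 0.0
    for c in range(n_classes):
        support = cm[c].sum()
        if support == 0:
            continue
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = support - tp
        f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
        total += support * f1
    return total / len(targets)


class TestWeightedF1:
    def test_perfect_predictions(self):
        assert weighted_f1([1, 2, 3], [1, 2, 3]) == 1.0

    def test_all_wrong_single_class(self):
        assert weighted_f1([1, 1, 1], [2, 2, 2]) == 0.0

    def test_hand_computed_two_class_average(self):
        # supports 3 and 1; per-class F1 1.0 and 0.0 -> 0.75
        targets = [0, 0, 0, 1]
        preds = [0, 0, 0, 2]
        assert weighted_f1(preds, targets) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_confusion_matrix_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        targets = rng.integers(0, 8, n)
        preds = rng.integers(0, 8, n)
        assert weighted_f1(preds, targets) == pytest.approx(
            confusion_matrix_weighted_f1(preds, targets, 8), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_f1([1, 2], [1])


class TestCapEOS:
    def test_trailing_eos_capped_to_four(self):
        seq = np.array([[1, 2] + [EOS] * 10])
        keep = cap_eos(seq, 4, EOS)
        assert keep[0].tolist() == [True] * 6 + [False] * 6

    def test_no_eos_unchanged(self):
        seq = np.array([[1, 2, 3, 4]])
        assert cap_eos(seq, 4, EOS).all()

    def test_cap_zero_excludes_all_eos(self):
        seq = np.array([[1, EOS, EOS]])
        assert cap_eos(seq, 0, EOS)[0].tolist() == [True, False, False]

    def test_negative_cap_rejected(self):
        with pytest.raises(ValueError):
            cap_eos(np.array([[1]]), -1, EOS)


def segs(*triples):
    return SegmentList(tuple(Segment(*t) for t in triples))


class TestSegF1:
    def test_identical_segmentations(self):
        a = segs((0, 10, 1), (10, 20, 2))
        assert seg_f1(a, a) == 1.0

    def test_disjoint_phases_score_zero(self):
        assert seg_f1(segs((0, 10, 1)), segs((0, 10, 2))) == 0.0

    def test_worked_split_segment_case(self):
        """One GT segment split in two: each half has IoU 0.5, one matches
        at threshold 0.5 -> TP=1, FP=1, FN=0 -> F1 = 2/3."""
        pred = segs((0, 5, 1), (5, 10, 1))
        gt = segs((0, 10, 1))
        assert seg_f1(pred, gt, iou_threshold=0.5) == pytest.approx(2 / 3)

    def test_empty_prediction_scores_zero(self):
        pred = labels_to_segments([1, 1])  # wrong phase everywhere
        gt = labels_to_segments([2, 2])
        assert seg_f1(pred, gt) == 0.0

    def test_oversegmentation_weakly_decreases_score(self):
        gt = segs((0, 30, 1))
        scores = []
        for pieces in (1, 2, 3):
            bounds = np.linspace(0, 30, pieces + 1).astype(int)
            pred = segs(*[(int(a), int(b), 1)
                          for a, b in zip(bounds, bounds[1:])])
            scores.append(seg_f1(pred, gt, iou_threshold=0.3))
        assert scores[0] >= scores[1] >= scores[2]

    def test_order_invariance(self):
        pred = segs((0, 5, 1), (5, 12, 2))
        gt = segs((0, 6, 1), (6, 12, 2))
        rev = SegmentList(tuple(pred.segments))
        assert seg_f1(pred, gt) == seg_f1(rev, gt)

    def test_horizon_seg_f1_applies_cap(self):
        pred = [1, 1, EOS, EOS, EOS, EOS]
        target = [1, 1, EOS, EOS, EOS, EOS]
        assert horizon_seg_f1(pred, target, EOS, eos_cap=2) == 1.0


class TestAnticipationMAE:
    def test_perfect_predictions_zero_error(self):
        t = np.array([[0.0, 1.5, 5.0]])
        rep = anticipation_mae(t, t, horizon=5)
        assert rep.wmae == 0.0 and rep.inmae == 0.0 and rep.outmae == 0.0

    def test_single_in_horizon_sample(self):
        rep = anticipation_mae(np.array([[0.5]]), np.array([[1.0]]),
                               horizon=5)
        assert rep.inmae == pytest.approx(0.5)
        assert np.isnan(rep.outmae)

    def test_constant_horizon_predictor_closed_form(self):
        """Predicting 'will not occur' everywhere: outMAE 0, inMAE equals
        the mean distance of in-horizon targets to the horizon."""
        targets = np.array([[1.0], [3.0], [5.0]])  # last is out-sample
        preds = np.full((3, 1), 5.0)
        rep = anticipation_mae(preds, targets, horizon=5)
        assert rep.outmae == 0.0
        assert rep.inmae == pytest.approx((4.0 + 2.0) / 2)
        assert rep.wmae == pytest.approx((0.0 + 3.0) / 2)

    def test_per_class_averaging(self):
        targets = np.array([[1.0, 5.0], [2.0, 5.0]])
        preds = np.array([[2.0, 5.0], [2.0, 4.0]])
        rep = anticipation_mae(preds, targets, horizon=5)
        assert rep.per_class_inmae[0] == pytest.approx(0.5)
        assert rep.per_class_outmae[1] == pytest.approx(0.5)
        assert np.isnan(rep.per_class_outmae[0])

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ValueError):
            anticipation_mae(np.zeros((1, 2)), np.zeros((1, 2)), horizon=0)


class TestRSD:
    def _timeline(self, vocab, minutes):
        return PhaseTimeline("v", np.zeros(minutes * 60, int), vocab)

    def test_oracle_predictor_is_exact(self, vocab):
        tl = self._timeline(vocab, 10)
        rsd = (len(tl) - np.arange(len(tl))) / 60.0
        rep = rsd_mae([rsd], [tl])
        assert rep.mae_5 == (0.0, 0.0)
        assert rep.mae_all == (0.0, 0.0)

    def test_zero_predictor_closed_form(self, vocab):
        """Predicting 0 always: MAE-ALL is the mean of the RSD series."""
        tl = self._timeline(vocab, 10)
        t = np.arange(len(tl))
        rsd = (len(tl) - t) / 60.0
        rep = rsd_mae([np.zeros(len(tl))], [tl])
        assert rep.mae_all[0] == pytest.approx(rsd.mean())
        assert rep.mae_5[0] == pytest.approx(rsd[rsd <= 5].mean())

    def test_sample_set_nesting(self, vocab):
        """MAE-5 samples are a subset of MAE-30, of MAE-ALL: a predictor
        wrong only late in surgery hurts MAE-5 at least as much."""
        tl = self._timeline(vocab, 40)
        t = np.arange(len(tl))
        rsd = (len(tl) - t) / 60.0
        pred = rsd + np.where(rsd <= 5, 2.0, 0.0)  # error only near the end
        rep = rsd_mae([pred], [tl])
        assert rep.mae_5[0] >= rep.mae_30[0] >= 0.0
        n5 = (rsd <= 5).sum()
        n30 = (rsd <= 30).sum()
        assert rep.mae_30[0] == pytest.approx(2.0 * n5 / n30)

    def test_empty_series_rejected(self, vocab):
        with pytest.raises(ValueError):
            rsd_mae([np.array([])], [self._timeline(vocab, 2)])


class TestSelectModel:
    def test_single_candidate_returned(self):
        assert select_model([("only", 0.3)], "classification") == "only"

    def test_classification_picks_highest_f1(self):
        cands = [("a", 0.3), ("b", 0.4)]
        assert select_model(cands, "classification") == "b"

    def test_regression_picks_lowest_wmae(self):
        cands = [("a", 0.5), ("b", 0.4)]
        assert select_model(cands, "regression") == "b"

    def test_ties_break_to_earliest(self):
        cands = [("first", 0.4), ("second", 0.4)]
        assert select_model(cands, "classification") == "first"
        assert select_model(cands, "regression") == "first"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_model([], "classification")


class TestHorizonScores:
    def test_scores_bounded_and_capped(self):
        rng = np.random.default_rng(0)
        targets = np.concatenate(
            [rng.integers(0, 7, (30, 6)), np.full((30, 6), EOS)], axis=1)
        preds = rng.integers(0, 8, (30, 12))
        hs = horizon_scores(preds, targets, EOS, eos_cap=4)
        assert all(0.0 <= v <= 1.0 for v in hs.per_horizon_f1.values())
        assert 0.0 <= hs.mean_f1 <= 1.0
        # steps 11 and 12 are pure EOS beyond the cap: not scored
        assert 11 not in hs.per_horizon_f1 and 12 not in hs.per_horizon_f1

    def test_accuracy_aggregation(self):
        targets = np.array([[1, 2], [1, 2]])
        preds = np.array([[1, 0], [1, 2]])
        hs = horizon_scores(preds, targets, EOS)
        assert hs.per_horizon_acc[1] == 1.0
        assert hs.per_horizon_acc[2] == 0.5
        assert hs.acc_up_to[2] == pytest.approx(0.75)
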