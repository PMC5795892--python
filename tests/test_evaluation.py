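"""Pixel-level Jaccard, ASA and confusion-matrix scoring."""

import numpy as np
import pytest

from visceraseg.data_model import (BACKGROUND, HEART, IGNORE, LIVER, LUNG,
                                   MISC, LabelImage)
from visceraseg.evaluation import (asa, best_relabeling,
                                   confusion_and_jaccard,
                                   normalize_confusion, pooled_report,
                                   project_to_pixels)
from visceraseg.overseg import Oversegmentation


def _overseg_from_ids(ids):
    ids = np.asarray(ids, dtype=np.int32)
    n = ids.max() + 1
    return Oversegmentation(ids=ids, n_segments=n,
                            centroid_px=np.zeros((n, 2)),
                            mean_lab=np.zeros((n, 3)), mode="2D")


def brute_force_jaccard(pred, gt):
    """Direct tp/fp/fn counting oracle over evaluable pixels."""
    out = {}
    evaluable = np.isin(gt, (MISC, HEART, LIVER, LUNG))
    for cls in (MISC, HEART, LIVER, LUNG):
        tp = np.count_nonzero(evaluable & (gt == cls) & (pred == cls))
        fp = np.count_nonzero(evaluable & (gt != cls) & (pred == cls))
        fn = np.count_nonzero(evaluable & (gt == cls) & (pred != cls))
        if tp + fn == 0:
            out[cls] = None
        else:
            out[cls] = 100.0 * tp / (tp + fp + fn) if tp + fp + fn else 100.0
    return out


def brute_force_asa(ids, gt):
    """Best-relabel-then-accuracy oracle."""
    evaluable = np.isin(gt, (MISC, HEART, LIVER, LUNG))
    correct = 0
    for k in np.unique(ids[ids >= 0]):
        members = (ids == k) & evaluable
        if not members.any():
            continue
        counts = [np.count_nonzero(gt[members] == c)
                  for c in (MISC, HEART, LIVER, LUNG)]
        correct += max(counts)
    return correct / evaluable.sum()


class TestProjection:
    def test_single_superpixel(self):
        ov = _overseg_from_ids(np.zeros((3, 3)))
        out = project_to_pixels(ov, np.array([LIVER]))
        assert np.all(out.labels == LIVER)

    def test_partitions_along_superpixel_boundary(self):
        ids = np.array([[0, 0, 1, 1]])
        out = project_to_pixels(_overseg_from_ids(ids),
                                np.array([HEART, LUNG]))
        np.testing.assert_array_equal(out.labels,
                                      [[HEART, HEART, LUNG, LUNG]])

    def test_counting_oracle(self, rng):
        ids = rng.integers(0, 6, size=(20, 20)).astype(np.int32)
        ids[0, :5] = -1
        ov = _overseg_from_ids(np.maximum(ids, -1))
        ov.n_segments = 6
        labels = rng.integers(1, 5, size=6)
        out = project_to_pixels(ov, labels)
        for k in range(6):
            assert np.count_nonzero(out.labels[ids == k] == labels[k]) == \
                np.count_nonzero(ids == k)
        assert np.all(out.labels[ids == -1] == BACKGROUND)

    def test_missing_label_rejected(self):
        ov = _overseg_from_ids(np.array([[0, 1]]))
        with pytest.raises(ValueError):
            project_to_pixels(ov, np.array([MISC]))


class TestJaccard:
    def test_perfect_prediction_scores_100(self, rng):
        gt = rng.choice([MISC, HEART, LIVER, LUNG],
                        size=(12, 12)).astype(np.uint8)
        rep = confusion_and_jaccard(LabelImage(gt.copy()), LabelImage(gt))
        assert all(v == 100.0 for v in rep.per_class_jaccard.values())
        assert rep.class_average_jaccard == 100.0

    def test_hand_counted_toy(self):
        """6x6 fixture with tp=4, fp=2, fn=2 for heart -> J_heart = 50."""
        gt = np.full((6, 6), MISC, dtype=np.uint8)
        gt[0, :6] = HEART                      # 6 heart pixels
        pred = np.full((6, 6), MISC, dtype=np.uint8)
        pred[0, :4] = HEART                    # 4 correct heart
        pred[1, :2] = HEART                    # 2 false heart
        rep = confusion_and_jaccard(LabelImage(pred), LabelImage(gt))
        assert rep.per_class_jaccard[HEART] == 50.0

    def test_all_misc_prediction_closed_form(self):
        """On a 70/20/5/5 ground truth, predicting everything as misc
        gives J_misc = 70 and zero for the organs."""
        gt = np.empty(1000, dtype=np.uint8)
        gt[:700] = MISC
        gt[700:900] = LIVER
        gt[900:950] = HEART
        gt[950:] = LUNG
        gt = gt.reshape(25, 40)
        pred = np.full_like(gt, MISC)
        rep = confusion_and_jaccard(LabelImage(pred), LabelImage(gt))
        assert rep.per_class_jaccard[MISC] == 70.0
        assert rep.per_class_jaccard[LIVER] == 0.0
        assert rep.class_average_jaccard == 17.5

    def test_matches_brute_force_on_random_images(self, rng):
        for _ in range(10):
            gt = rng.choice([BACKGROUND, MISC, HEART, LIVER, LUNG, IGNORE],
                            size=(16, 16)).astype(np.uint8)
            pred = rng.choice([MISC, HEART, LIVER, LUNG],
                              size=(16, 16)).astype(np.uint8)
            rep = confusion_and_jaccard(LabelImage(pred), LabelImage(gt))
            oracle = brute_force_jaccard(pred, gt)
            for cls, expect in oracle.items():
                if expect is None:
                    assert np.isnan(rep.per_class_jaccard[cls])
                else:
                    assert abs(rep.per_class_jaccard[cls] - expect) < 1e-9

    def test_ignore_and_background_excluded(self):
        gt = np.full((4, 4), IGNORE, dtype=np.uint8)
        gt[0, 0] = MISC
        gt[0, 1] = BACKGROUND
        pred = np.full((4, 4), MISC, dtype=np.uint8)
        rep = confusion_and_jaccard(LabelImage(pred), LabelImage(gt))
        assert rep.n_evaluated == 1
        assert rep.per_class_jaccard[MISC] == 100.0

    def test_no_evaluable_pixels_rejected(self):
        gt = LabelImage(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            confusion_and_jaccard(gt, gt)

    def test_permutation_equivariance(self, rng):
        gt = rng.choice([MISC, HEART, LIVER, LUNG],
                        size=(10, 10)).astype(np.uint8)
        pred = rng.choice([MISC, HEART, LIVER, LUNG],
                          size=(10, 10)).astype(np.uint8)
        rep = confusion_and_jaccard(LabelImage(pred), LabelImage(gt))
        # swap heart <-> lung consistently in both images
        perm = {MISC: MISC, HEART: LUNG, LIVER: LIVER, LUNG: HEART}
        gt2 = np.vectorize(perm.get)(gt).astype(np.uint8)
        pr2 = np.vectorize(perm.get)(pred).astype(np.uint8)
        rep2 = confusion_and_jaccard(LabelImage(pr2), LabelImage(gt2))
        assert rep2.per_class_jaccard[LUNG] == rep.per_class_jaccard[HEART]
        assert rep2.class_average_jaccard == \
            pytest.approx(rep.class_average_jaccard)


class TestASA:
    def test_perfect_oversegmentation(self):
        ids = np.array([[0, 0, 1, 1]])
        gt = LabelImage(np.array([[HEART, HEART, LIVER, LIVER]],
                                 dtype=np.uint8))
        value, per_class = asa(_overseg_from_ids(ids), gt)
        assert value == 1.0
        assert per_class[HEART] == 100.0

    def test_straddling_superpixel_forced_split(self):
        ids = np.zeros((1, 4), dtype=np.int32)
        gt = LabelImage(np.array([[HEART, HEART, LIVER, LIVER]],
                                 dtype=np.uint8))
        value, _ = asa(_overseg_from_ids(ids), gt)
        assert value == 0.5

    def test_tie_goes_to_lower_class_code(self):
        ids = np.zeros((1, 4), dtype=np.int32)
        gt = LabelImage(np.array([[LIVER, LIVER, HEART, HEART]],
                                 dtype=np.uint8))
        labels = best_relabeling(_overseg_from_ids(ids), gt)
        assert labels[0] == HEART             # 2 < 3

    def test_matches_brute_force_on_random_scenes(self, rng):
        for _ in range(10):
            ids = rng.integers(0, 8, size=(24, 24)).astype(np.int32)
            gt = rng.choice([BACKGROUND, MISC, HEART, LIVER, LUNG, IGNORE],
                            size=(24, 24), p=[.1, .4, .15, .15, .1, .1]) \
                .astype(np.uint8)
            value, _ = asa(_overseg_from_ids(ids), LabelImage(gt))
            assert abs(value - brute_force_asa(ids, gt)) < 1e-12

    def test_accuracy_bounded_by_asa(self, rng):
        """Any projected superpixel labeling scores at most ASA."""
        ids = rng.integers(0, 10, size=(20, 20)).astype(np.int32)
        ov = _overseg_from_ids(ids)
        gt = LabelImage(rng.choice([MISC, HEART, LIVER, LUNG],
                                   size=(20, 20)).astype(np.uint8))
        value, _ = asa(ov, gt)
        for _ in range(5):
            labels = rng.integers(1, 5, size=10)
            pred = project_to_pixels(ov, labels)
            rep = confusion_and_jaccard(pred, gt)
            assert rep.pixel_accuracy <= value + 1e-12


class TestNormalizedConfusion:
    def test_identity_counts(self):
        np.testing.assert_array_equal(normalize_confusion(np.eye(4)),
                                      np.eye(4))

    def test_row_shares(self):
        out = normalize_confusion(np.array([[70, 10, 10, 10]]))
        np.testing.assert_allclose(out, [[0.7, 0.1, 0.1, 0.1]])

    def test_rows_sum_to_one_or_zero(self, rng):
        counts = rng.integers(0, 50, size=(4, 4))
        counts[2] = 0
        out = normalize_confusion(counts)
        sums = out.sum(axis=1)
        assert abs(sums[0] - 1) < 1e-12 and sums[2] == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            normalize_confusion(np.array([[-1, 2]]))


def test_pooled_report_pools_counts_not_scores(rng):
    """Pooled Jaccard equals Jaccard of summed confusion counts, not the
    mean of per-image scores."""
    gts, preds = [], []
    for _ in range(3):
        gt = rng.choice([MISC, HEART, LIVER, LUNG],
                        size=(10, 10)).astype(np.uint8)
        pred = rng.choice([MISC, HEART, LIVER, LUNG],
                          size=(10, 10)).astype(np.uint8)
        gts.append(gt)
        preds.append(pred)
    rep = pooled_report([(LabelImage(p), LabelImage(g))
                         for p, g in zip(preds, gts)])
    stacked = confusion_and_jaccard(
        LabelImage(np.concatenate(preds, axis=1)),
        LabelImage(np.concatenate(gts, axis=1)))
    assert rep.class_average_jaccard == \
        pytest.approx(stacked.class_average_jaccard)
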