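"""Detector primitives (IoU, anchors, matching, focal loss, NMS) and training."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from podfusion.detector import (
    AnchorConfig,
    BoundingBox,
    DetectorConfig,
    IGNORE,
    NEGATIVE,
    boxes_to_array,
    detect,
    focal_loss,
    generate_anchors,
    iou,
    iou_matrix,
    match_anchors,
    nms,
    train_detector,
)

boxes = st.builds(
    lambda x, y, w, h: BoundingBox(x, y, x + w, y + h),
    st.floats(0, 50), st.floats(0, 50), st.floats(1, 40), st.floats(1, 40),
)


class TestIoU:
    def test_identity_and_disjoint(self):
        a = BoundingBox(0, 0, 10, 10)
        assert iou(a, a) == 1.0
        assert iou(a, BoundingBox(20, 20, 30, 30)) == 0.0

    def test_half_overlap_hand_value(self):
        # intersection 50, union 150
        v = iou(BoundingBox(0, 0, 10, 10), BoundingBox(5, 0, 15, 10))
        assert v == pytest.approx(50 / 150)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(5, 5, 5, 10)

    @given(a=boxes, b=boxes)
    def test_symmetric_and_bounded(self, a, b):
        v = iou(a, b)
        assert v == pytest.approx(iou(b, a))
        assert 0.0 <= v <= 1.0

    @given(a=boxes)
    def test_self_iou_is_one(self, a):
        assert iou(a, a) == pytest.approx(1.0)


class TestAnchors:
    def test_single_cell_grid_counts(self):
        cfg = AnchorConfig(base_sizes=(16,), aspect_ratios=(1.0,), scales=(1.0,),
                           strides=(32,))
        assert generate_anchors(cfg, (64, 64)).shape == (4, 4)

    def test_ratio_scale_multiplicity(self):
        cfg = AnchorConfig(base_sizes=(16,), aspect_ratios=(0.5, 1, 2),
                           scales=(1, 1.3, 1.6), strides=(32,))
        assert generate_anchors(cfg, (64, 64)).shape == (36, 4)

    def test_centers_sit_on_stride_lattice(self):
        cfg = AnchorConfig(base_sizes=(16,), aspect_ratios=(0.5, 1, 2),
                           scales=(1, 2), strides=(8,))
        a = generate_anchors(cfg, (64, 48))
        for c in [(a[:, 0] + a[:, 2]) / 2, (a[:, 1] + a[:, 3]) / 2]:
            off = (c - 4.0) % 8.0
            assert np.allclose(np.minimum(off, 8.0 - off), 0.0, atol=1e-9)

    def test_stride_larger_than_image_rejected(self):
        cfg = AnchorConfig(base_sizes=(16,), strides=(128,))
        with pytest.raises(ValueError):
            generate_anchors(cfg, (64, 64))


class TestMatching:
    cfg = DetectorConfig()

    def test_no_truths_all_negative(self):
        anchors = generate_anchors(self.cfg.anchors, (64, 64))
        out = match_anchors(anchors, np.zeros((0, 4)), self.cfg)
        assert (out == NEGATIVE).all()

    def test_anchor_identical_to_truth_is_positive(self):
        anchors = np.array([[10, 10, 30, 30], [100, 100, 120, 120]], float)
        truths = np.array([[10, 10, 30, 30]], float)
        out = match_anchors(anchors, truths, self.cfg)
        assert out[0] == 0
        assert out[1] == NEGATIVE

    def test_intermediate_iou_is_ignored(self):
        # [0,0,10,10] vs [0,0,10,4.5]: inter 45, union 100 -> IoU 0.45
        anchors = np.array([[0, 0, 10, 10]], float)
        truths = np.array([[0, 0, 10, 4.5]], float)
        assert iou_matrix(anchors, truths)[0, 0] == pytest.approx(0.45)
        assert match_anchors(anchors, truths, self.cfg)[0] == IGNORE

    def test_every_reachable_truth_gets_a_positive_anchor(self, rng):
        cfg = DetectorConfig()
        anchors = generate_anchors(cfg.anchors, (96, 96))
        for _ in range(20):
            t = rng.uniform(4, 60, size=(6, 2))
            wh = rng.uniform(8, 30, size=(6, 2))
            truths = np.concatenate([t, t + wh], axis=1)
            out = match_anchors(anchors, truths, cfg)
            m = iou_matrix(anchors, truths)
            for j in range(truths.shape[0]):
                if m[:, j].max() >= cfg.iou_pos_threshold:
                    assert (out == j).any()


class TestFocalLoss:
    def test_cross_entropy_limit(self):
        assert focal_loss(0.5, 1, alpha=1.0, gamma=0.0) == pytest.approx(np.log(2))

    def test_perfect_prediction_limit(self):
        assert focal_loss(1 - 1e-13, 1, alpha=0.25, gamma=2.0) < 1e-10

    def test_direct_formula_value(self):
        v = focal_loss(0.9, 1, alpha=0.25, gamma=2.0)
        assert v == pytest.approx(0.25 * 0.01 * -np.log(0.9), rel=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(0.5, 1, alpha=1.5)
        with pytest.raises(ValueError):
            focal_loss(0.5, 1, gamma=-1.0)

    @given(p=st.floats(1e-6, 1 - 1e-6), y=st.sampled_from([0, 1]),
           alpha=st.floats(0, 1))
    def test_gamma_zero_equals_weighted_bce(self, p, y, alpha):
        bce = -(np.log(p) if y == 1 else np.log(1 - p))
        w = alpha if y == 1 else 1 - alpha
        assert focal_loss(p, y, alpha=alpha, gamma=0.0) == pytest.approx(
            w * bce, abs=1e-9, rel=1e-9)

    @given(p=st.floats(1e-4, 1 - 1e-4), y=st.sampled_from([0, 1]))
    def test_focusing_never_increases_loss(self, p, y):
        assert focal_loss(p, y, 0.25, 2.0) <= focal_loss(p, y, 0.25, 0.0) + 1e-12


def nms_oracle(dets, thr):
    """Independent O(n^2) reference: explicit suppressed-set bookkeeping."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    kept, suppressed = [], set()
    for i in order:
        if i in suppressed:
            continue
        kept.append(i)
        for j in order:
            if j != i and j not in suppressed and iou(dets[i], dets[j]) > thr:
                suppressed.add(j)
    return [dets[i] for i in kept]


class TestNMS:
    def test_single_detection_kept(self):
        d = [BoundingBox(0, 0, 10, 10, score=0.7)]
        assert nms(d, 0.5) == d

    def test_duplicate_boxes_keep_higher_score(self):
        d = [BoundingBox(0, 0, 10, 10, score=0.8), BoundingBox(0, 0, 10, 10, score=0.9)]
        kept = nms(d, 0.5)
        assert len(kept) == 1 and kept[0].score == 0.9

    def test_matches_oracle_on_random_instances(self, rng):
        for trial in range(30):
            n = int(rng.integers(1, 51))
            xy = rng.uniform(0, 80, size=(n, 2))
            wh = rng.uniform(5, 30, size=(n, 2))
            sc = np.round(rng.uniform(0, 1, size=n), 2)  # induce score ties
            dets = [BoundingBox(x, y, x + w, y + h, score=float(s))
                    for (x, y), (w, h), s in zip(xy, wh, sc)]
            thr = float(rng.uniform(0.2, 0.7))
            got = nms(dets, thr)
            want = nms_oracle(dets, thr)
            assert [id(b) for b in got] == [id(b) for b in want]


class TestTraining:
    def test_loss_trace_decreases_on_fixture(self, overfit_detector):
        _, trace = overfit_detector
        assert trace[-1] < trace[0]
        # smoothed trace is monotone non-increasing front to back
        sm = np.convolve(trace, np.ones(20) / 20, mode="valid")
        assert sm[-1] <= sm[0]

    def test_overfit_scene_recall_at_least_090(self, overfit_detector, overfit_scene):
        model, _ = overfit_detector
        dets = detect(model, overfit_scene.views[0])
        truths = boxes_to_array(overfit_scene.annotations[0])
        m = iou_matrix(boxes_to_array(dets), truths)
        recall = (m.max(axis=0) >= 0.5).mean()
        assert recall >= 0.9

    def test_detection_count_bounded_by_anchor_count(self, overfit_detector, overfit_scene):
        model, _ = overfit_detector
        dets = detect(model, overfit_scene.views[0])
        h, w = overfit_scene.views[0].shape[:2]
        assert 0 < len(dets) <= model.anchors_for((w, h)).shape[0]
        for b in dets:
            assert b.score >= model.config.score_threshold
            assert 0 <= b.x_min < b.x_max <= w
            assert 0 <= b.y_min < b.y_max <= h

    def test_untrained_model_silent_at_high_threshold(self):
        from podfusion.detector import Detector
        cfg = DetectorConfig(score_threshold=0.99)
        model = Detector(cfg, seed=0)
        blank = np.full((64, 64, 3), 12, np.uint8)
        assert detect(model, blank, cfg) == []

    def test_fixed_seed_reproduces_loss_trace(self, overfit_scene):
        sample = [(overfit_scene.views[0], overfit_scene.annotations[0])]
        _, t1 = train_detector(sample, DetectorConfig(), epochs=3, seed=5)
        _, t2 = train_detector(sample, DetectorConfig(), epochs=3, seed=5)
        assert t1 == t2

    def test_unannotated_training_set_rejected(self):
        img = np.zeros((64, 64, 3), np.uint8)
        with pytest.raises(ValueError):
            train_detector([(img, [])], DetectorConfig(), epochs=1)


class TestCheckpoint:
    def test_round_trip_preserves_detections(self, overfit_detector, overfit_scene, tmp_path):
        from podfusion.detector import load_checkpoint, save_checkpoint
        model, _ = overfit_detector
        path = tmp_path / "det.npz"
        save_checkpoint(path, model)
        loaded = load_checkpoint(path)
        img = overfit_scene.views[0]
        a = detect(model, img)
        b = detect(loaded, img)
        assert len(a) == len(b)
        assert boxes_to_array(a) == pytest.approx(boxes_to_array(b))
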