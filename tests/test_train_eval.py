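import math

import numpy as np
import pytest

from appledet._nn import Tensor
from appledet.data_io import NormBox
from appledet.model_builder import Detection, ModelConfig, build_model
from appledet.synthetic_orchard import easy_config, generate_scene
from appledet.train_eval import (ConfusionCounts, IOU_SWEEP, TrainParams,
                                 ap_from_pr, ap_from_records, build_targets,
                                 ciou_loss, cosine_lr, detection_loss,
                                 evaluate_detections, evaluate_model,
                                 map50_95, match_detections,
                                 precision_recall_f1, train_model)

TP_TEST_ANCHORS = np.array([[[10, 13], [16, 30], [33, 23]],
                            [[30, 61], [62, 45], [59, 119]],
                            [[116, 90], [156, 198], [373, 326]]], dtype=float)


def _ciou_oracle(p, t):
    """Independent CIoU transcription (center/size boxes, float64)."""
    px, py, pw, ph = p
    tx, ty, tw, th = t
    ix1, iy1 = max(px - pw / 2, tx - tw / 2), max(py - ph / 2, ty - th / 2)
    ix2, iy2 = min(px + pw / 2, tx + tw / 2), min(py + ph / 2, ty + th / 2)
    inter = max(ix2 - ix1, 0) * max(iy2 - iy1, 0)
    iou = inter / (pw * ph + tw * th - inter)
    ex1, ey1 = min(px - pw / 2, tx - tw / 2), min(py - ph / 2, ty - th / 2)
    ex2, ey2 = max(px + pw / 2, tx + tw / 2), max(py + ph / 2, ty + th / 2)
    c2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2
    rho2 = (px - tx) ** 2 + (py - ty) ** 2
    v = 4 / math.pi ** 2 * (math.atan(tw / th) - math.atan(pw / ph)) ** 2
    alpha = v / (1 - iou + v) if v > 0 else 0.0
    return iou - rho2 / c2 - alpha * v


class TestCIoU:
    def test_identical_boxes_zero(self):
        assert ciou_loss((0, 0, 2, 2), (0, 0, 2, 2)) == 0.0

    def test_matches_independent_oracle(self):
        p, t = (0, 0, 2, 2), (2, 2, 2, 2)
        assert ciou_loss(p, t) == pytest.approx(1 - _ciou_oracle(p, t),
                                                abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_pairs_match_oracle(self, seed):
        r = np.random.default_rng(seed)
        p = (*r.uniform(-5, 5, 2), *r.uniform(0.1, 6, 2))
        t = (*r.uniform(-5, 5, 2), *r.uniform(0.1, 6, 2))
        assert ciou_loss(p, t) == pytest.approx(1 - _ciou_oracle(p, t),
                                                abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_bounded_below_three(self, seed):
        r = np.random.default_rng(100 + seed)
        p = (*r.uniform(-100, 100, 2), *r.uniform(0.01, 50, 2))
        t = (*r.uniform(-100, 100, 2), *r.uniform(0.01, 50, 2))
        assert 0 <= ciou_loss(p, t) < 3.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            ciou_loss((0, 0, 0, 2), (0, 0, 2, 2))


class TestBuildTargets:
    def test_gt_matching_anchor_at_cell_center_is_assigned(self):
        # anchor (16, 30) at stride 8; GT of exactly that size
        gt = [NormBox(0, 0.5, 0.5, 16 / 160, 30 / 160)]
        out = build_targets([gt], TP_TEST_ANCHORS, 160)
        assigned = [(s, a) for s, t in enumerate(out) for a in t["a"]]
        assert (0, 1) in assigned

    def test_oversized_gt_gets_no_assignment(self):
        anchors = TP_TEST_ANCHORS / 10.0
        gt = [NormBox(0, 0.5, 0.5, 0.9, 0.9)]
        out = build_targets([gt], anchors / 4, 160)
        assert all(len(t["b"]) == 0 for t in out)

    def test_counts_match_brute_force_matcher(self):
        rng = np.random.default_rng(0)
        gts = [[NormBox(0, *rng.uniform(0.2, 0.8, 2), *rng.uniform(0.05, 0.4, 2))
                for _ in range(3)] for _ in range(2)]
        out = build_targets(gts, TP_TEST_ANCHORS, 160)
        got = sum(len(t["b"]) for t in out)

        # independent enumeration of the same rule
        expected = 0
        for boxes in gts:
            for b in boxes:
                for scale, stride in enumerate((8, 16, 32)):
                    gw = 160 // stride
                    for aw, ah in TP_TEST_ANCHORS[scale] / stride:
                        rw, rh = b.w * gw / aw, b.h * gw / ah
                        if max(rw, 1 / rw, rh, 1 / rh) >= 4.0:
                            continue
                        n_cells = 1
                        fx, fy = (b.cx * gw) % 1, (b.cy * gw) % 1
                        if fx < 0.5 and b.cx * gw > 1:
                            n_cells += 1
                        if fx >= 0.5 and b.cx * gw < gw - 1:
                            n_cells += 1
                        if fy < 0.5 and b.cy * gw > 1:
                            n_cells += 1
                        if fy >= 0.5 and b.cy * gw < gw - 1:
                            n_cells += 1
                        expected += n_cells
        assert got == expected


class TestDetectionLoss:
    def _one_cell_setup(self, logits):
        # single 1x1 grid at stride 8, one anchor group
        anchors = np.array([[[8, 8], [100, 100], [200, 200]],
                            [[300, 300], [301, 301], [302, 302]],
                            [[400, 400], [401, 401], [402, 402]]], dtype=float)
        pred = Tensor(np.full((1, 3, 1, 1, 6), 0.0, dtype=np.float32)
                      + np.asarray(logits, dtype=np.float32))
        gt = [NormBox(0, 0.5, 0.5, 1.0, 1.0)]          # 8x8 px at img 8
        targets = build_targets([gt], anchors, 8, neighbor_cells=False)
        return [pred], targets[:1], anchors, TrainParams(input_size=8)

    def test_hand_computed_components_on_one_cell(self):
        preds, targets, anchors, params = self._one_cell_setup(0.0)
        total, comps = detection_loss(preds, targets, anchors, params)
        # zero logits: pxy = (0.5, 0.5), pwh = anchor -> perfect box, CIoU = 1
        assert comps["box"] == pytest.approx(0.0, abs=1e-6)
        # obj: matched cell target 1, logit 0 -> ln 2; unmatched cells
        # target 0, logit 0 -> ln 2; mean over 3 cells is ln 2, balance 4.0
        assert comps["obj"] == pytest.approx(4 * math.log(2), rel=1e-5)
        # cls: single class target 1 at logit 0 -> ln 2
        assert comps["cls"] == pytest.approx(math.log(2), rel=1e-5)

    def test_no_gt_and_cold_objectness_drives_loss_to_zero(self):
        anchors = TP_TEST_ANCHORS
        preds = [Tensor(np.full((1, 3, s, s, 6), -30.0, dtype=np.float32))
                 for s in (20, 10, 5)]
        targets = build_targets([[]], anchors, 160)
        total, comps = detection_loss(preds, targets, anchors,
                                      TrainParams(input_size=160))
        assert comps["total"] == pytest.approx(0.0, abs=1e-6)

    def test_doubling_box_weight_doubles_box_term_only(self):
        rng = np.random.default_rng(1)
        anchors = TP_TEST_ANCHORS
        preds = [Tensor(rng.standard_normal((1, 3, s, s, 6)).astype(np.float32))
                 for s in (20, 10, 5)]
        gt = [[NormBox(0, 0.4, 0.6, 0.2, 0.25)]]
        targets = build_targets(gt, anchors, 160)
        p1 = TrainParams(input_size=160, box_weight=0.05)
        p2 = TrainParams(input_size=160, box_weight=0.10)
        t1, c1 = detection_loss(preds, targets, anchors, p1)
        t2, c2 = detection_loss(preds, targets, anchors, p2)
        assert c1["box"] == pytest.approx(c2["box"])
        assert c1["obj"] == pytest.approx(c2["obj"])
        assert (float(t2.data) - float(t1.data)
                == pytest.approx(0.05 * c1["box"], rel=1e-4))


class TestCosineLR:
    PARAMS = TrainParams()

    def test_initial_rate(self):
        assert cosine_lr(0, self.PARAMS) == pytest.approx(0.01)

    def test_final_rate_is_floor(self):
        assert cosine_lr(200, self.PARAMS) == pytest.approx(0.0001)

    def test_midpoint(self):
        assert cosine_lr(100, self.PARAMS) == pytest.approx(0.00505)

    def test_monotone_nonincreasing(self):
        rates = [cosine_lr(e, self.PARAMS) for e in range(201)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    @pytest.mark.parametrize("epoch", [-1, 201])
    def test_out_of_range_rejected(self, epoch):
        with pytest.raises(ValueError):
            cosine_lr(epoch, self.PARAMS)


class TestMatchDetections:
    GT = [(0.0, 0.0, 10.0, 10.0)]

    def test_iou_above_threshold_is_tp(self):
        dets = [Detection((0, 0, 10, 6.0), 0.9, 0)]   # IoU 0.6
        c = match_detections(dets, self.GT, 0.5)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_duplicate_detection_is_fp(self):
        dets = [Detection((0, 0, 10, 10), 0.9, 0),
                Detection((0, 0, 10, 10), 0.8, 0)]
        c = match_detections(dets, self.GT, 0.5)
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_low_iou_is_fp_and_fn(self):
        dets = [Detection((0, 0, 10, 4.0), 0.9, 0)]   # IoU 0.4
        c = match_detections(dets, self.GT, 0.5)
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_tp_plus_fn_equals_gt_count(self, rng):
        gts = [(i * 20.0, 0.0, i * 20.0 + 10, 10.0) for i in range(5)]
        dets = [Detection((i * 20.0, 0, i * 20.0 + 10, 10), 0.5, 0)
                for i in range(3)]
        c = match_detections(dets, gts, 0.5)
        assert c.tp + c.fn == 5


class TestPrecisionRecallF1:
    def test_direct_formula(self):
        p, r, f1 = precision_recall_f1(ConfusionCounts(tp=9, fp=1, fn=0))
        assert (p, r) == (0.9, 1.0)
        assert f1 == pytest.approx(18 / 19, abs=5e-4)  # ~0.947

    def test_f1_equals_p_when_p_equals_r(self):
        p, r, f1 = precision_recall_f1(ConfusionCounts(tp=6, fp=2, fn=2))
        assert p == r == f1 == 0.75

    def test_published_f1_from_printed_p_r(self):
        p, r = 97.81, 97.32
        f1 = 2 * p * r / (p + r)
        assert f1 == pytest.approx(97.55, abs=0.02)

    def test_zero_denominator_conventions(self):
        assert precision_recall_f1(ConfusionCounts()) == (0.0, 0.0, 0.0)


def _ap_oracle(records, n_gt):
    """Brute force: enumerate every confidence cut, exact staircase area."""
    order = sorted(records, key=lambda rc: -rc[0])
    cuts = []
    tp = fp = 0
    for conf, is_tp in order:
        tp, fp = tp + is_tp, fp + (not is_tp)
        cuts.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for level in sorted({r for r, _ in cuts}):
        pmax = max(p for r, p in cuts if r >= level)
        ap += (level - prev_r) * pmax
        prev_r = level
    return ap


class TestAP:
    def test_all_correct_gives_one(self):
        recs = [(0.9, True), (0.8, True), (0.7, True)]
        assert ap_from_records(recs, 3) == pytest.approx(1.0)

    def test_hand_enumerated_three_point_curve(self):
        # 2 GT, ranked [TP, FP, TP]: AP = 0.5*1.0 + 0.5*(2/3)
        recs = [(0.9, True), (0.8, False), (0.7, True)]
        assert ap_from_records(recs, 2) == pytest.approx(0.5 + 0.5 * 2 / 3)

    def test_no_tp_gives_zero(self):
        assert ap_from_records([(0.9, False), (0.5, False)], 2) == 0.0

    def test_zero_gt_rejected(self):
        with pytest.raises(ValueError):
            ap_from_records([(0.9, True)], 0)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        n_gt = int(r.integers(1, 8))
        n_det = int(r.integers(0, 15))
        n_tp = int(r.integers(0, min(n_gt, n_det) + 1)) if n_det else 0
        flags = [True] * n_tp + [False] * (n_det - n_tp)
        r.shuffle(flags)
        recs = [(float(c), f) for c, f in zip(r.random(n_det), flags)]
        got = ap_from_records(recs, n_gt)
        if recs:
            assert got == pytest.approx(_ap_oracle(recs, n_gt), abs=1e-12)
        else:
            assert got == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_adding_tp_never_decreases_ap(self, seed):
        r = np.random.default_rng(1000 + seed)
        n_gt = int(r.integers(2, 8))
        recs = [(float(c), bool(f)) for c, f in
                zip(r.random(6), r.integers(0, 2, 6))]
        base = ap_from_records(recs, n_gt)
        more = recs + [(float(r.random()), True)]
        assert ap_from_records(more, n_gt) >= base - 1e-12

    @pytest.mark.parametrize("seed", range(20))
    def test_adding_fp_never_increases_ap(self, seed):
        r = np.random.default_rng(2000 + seed)
        n_gt = int(r.integers(2, 8))
        recs = [(float(c), bool(f)) for c, f in
                zip(r.random(6), r.integers(0, 2, 6))]
        base = ap_from_records(recs, n_gt)
        more = recs + [(float(r.random()), False)]
        assert ap_from_records(more, n_gt) <= base + 1e-12


class TestMAP:
    def test_constant_aps_average_to_constant(self):
        assert map50_95([0.7] * 10) == pytest.approx(0.7)

    def test_perfect_detector_all_thresholds(self):
        gts = [(0.0, 0.0, 10.0, 10.0), (20.0, 20.0, 40.0, 40.0)]
        dets = [Detection(g, 1.0, 0) for g in gts]
        aps = [ap_from_pr([(dets, gts)], thr) for thr in IOU_SWEEP]
        assert map50_95(aps) == pytest.approx(1.0)

    def test_single_class_map_equals_ap(self):
        gts = [(0.0, 0.0, 10.0, 10.0)]
        dets = [Detection((0, 0, 10, 9.0), 0.8, 0)]
        ap = ap_from_pr([(dets, gts)], 0.5)
        assert map50_95([ap] * 10) == pytest.approx(ap)

    def test_wrong_threshold_count_rejected(self):
        with pytest.raises(ValueError):
            map50_95([1.0] * 9)


class TestEvaluate:
    def _oracle_dataset(self, n=4, size=96):
        cfg = easy_config(size)
        return [generate_scene(cfg, 500 + i) for i in range(n)], size

    def test_ground_truth_replay_scores_perfectly(self):
        samples, size = self._oracle_dataset()
        params = TrainParams(input_size=96)
        per_image = []
        for _, boxes in samples:
            gts = np.array([[(b.cx - b.w / 2) * size, (b.cy - b.h / 2) * size,
                             (b.cx + b.w / 2) * size, (b.cy + b.h / 2) * size]
                            for b in boxes])
            dets = [Detection(tuple(g), 1.0, 0) for g in gts]
            per_image.append((dets, gts))
        rep = evaluate_detections(per_image, params)
        assert rep.precision == rep.recall == rep.f1 == 1.0
        assert rep.ap50 == rep.map50_95 == 1.0

    def test_empty_detections_zero_precision_recall(self):
        gts = np.array([[0.0, 0.0, 10.0, 10.0]])
        rep = evaluate_detections([([], gts)], TrainParams())
        assert rep.precision == 0.0 and rep.recall == 0.0

    def test_report_invariants(self):
        gts = np.array([[0.0, 0.0, 10.0, 10.0], [30.0, 30.0, 50.0, 50.0]])
        dets = [Detection((0, 0, 10, 10), 0.9, 0),
                Detection((100, 100, 120, 120), 0.6, 0)]
        rep = evaluate_detections([(dets, gts)], TrainParams())
        assert rep.f1 <= max(rep.precision, rep.recall) + 1e-12
        assert rep.f1 <= 2 * min(rep.precision, rep.recall) + 1e-12
        assert 0 <= rep.ap50 <= 1

    def test_evaluate_model_deterministic(self):
        samples, size = self._oracle_dataset(n=2)
        model = build_model(ModelConfig(variant="cs", nc=1, input_size=96),
                            seed=0)
        params = TrainParams(input_size=96)
        r1 = evaluate_model(model, samples, params)
        r2 = evaluate_model(model, samples, params)
        assert r1 == r2

    def test_empty_dataset_rejected(self):
        model = build_model(ModelConfig(variant="cs", nc=1, input_size=96))
        with pytest.raises(ValueError):
            evaluate_model(model, [], TrainParams(input_size=96))


class TestTrainModel:
    def _setup(self, n=6, size=96, epochs=2):
        cfg = easy_config(size)
        train = [generate_scene(cfg, i) for i in range(n)]
        model = build_model(ModelConfig(variant="cs", nc=1, input_size=size),
                            seed=0)
        params = TrainParams(epochs=epochs, batch=3, input_size=size,
                             box_weight=1.0)
        return model, train, params

    def test_empty_dataset_rejected(self):
        model, _, params = self._setup()
        with pytest.raises(ValueError):
            train_model(model, [], [], params)

    def test_same_seed_same_epoch0_loss(self):
        m1, train, params = self._setup(epochs=1)
        _, h1 = train_model(m1, train, [], params, seed=4)
        m2 = build_model(ModelConfig(variant="cs", nc=1, input_size=96), seed=0)
        _, h2 = train_model(m2, train, [], params, seed=4)
        assert h1[0]["total"] == h2[0]["total"]

    def test_loss_decreases_over_short_run(self):
        model, train, params = self._setup(n=6, epochs=6)
        _, hist = train_model(model, train, [], params, seed=0)
        assert hist[-1]["total"] < hist[0]["total"]

    def test_checkpoint_roundtrip_preserves_metrics(self, tmp_path):
        model, train, params = self._setup(n=4, epochs=1)
        model, _ = train_model(model, train, [], params, seed=0)
        rep1 = evaluate_model(model, train, params)
        model.save(tmp_path / "ckpt.npz")
        from appledet.model_builder import Model
        again = Model.load(tmp_path / "ckpt.npz")
        rep2 = evaluate_model(again, train, params)
        assert rep1 == rep2

    def test_warm_start_loads_weights(self, tmp_path):
        model, train, params = self._setup(n=4, epochs=1)
        model.save(tmp_path / "init.npz")
        fresh = build_model(ModelConfig(variant="cs", nc=1, input_size=96),
                            seed=99)
        train_model(fresh, train, [], TrainParams(epochs=0, input_size=96),
                    seed=0, warm_start=str(tmp_path / "init.npz"))
        s1, s2 = model.state_dict(), fresh.state_dict()
        # epochs=0 -> pure load, so weights must equal the checkpoint
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)
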