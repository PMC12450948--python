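"""Detector assembly, assignment, loss, inference, persistence, video."""

import itertools

import numpy as np
import pytest

from maizedet.data import DetectionDataset
from maizedet.detector import (
    AssignerConfig, Detector, DetectorConfig, LossWeights, TrainConfig,
    assign_targets, build_model, compute_loss, count_seedlings, load_checkpoint,
    nms, predict, process_video, save_checkpoint, train,
)
from maizedet.labels_io import Detection, ImageAnnotation, NormalizedBox
from maizedet.nn import Tensor, no_grad
from maizedet.synthetic_field import FieldConfig, render_field

TINY = dict(input_size=64, width_multiple=0.25)


def tiny_model(seed=0, **flags):
    return build_model(DetectorConfig(**TINY, **flags), seed=seed)


class TestBuildVariants:
    @pytest.mark.parametrize("rep,bifpn,tdadh",
                             list(itertools.product((False, True), repeat=3)))
    def test_all_eight_variants_build_and_run(self, rng, rep, bifpn, tdadh):
        m = tiny_model(rep_backbone=rep, bifpn_neck=bifpn, tdadh_head=tdadh)
        m.eval()
        with no_grad():
            cls_out, reg_out = m(Tensor(rng.normal(size=(1, 3, 64, 64)).astype(np.float32)))
        assert [c.shape[-1] for c in cls_out] == [8, 4, 2]
        assert [r.shape[1] for r in reg_out] == [64, 64, 64]

    def test_indivisible_input_names_required_multiple(self, rng):
        m = tiny_model()
        with pytest.raises(ValueError, match="multiple of 32"):
            m(Tensor(np.zeros((1, 3, 50, 50), np.float32)))

    def test_output_levels_at_640_input(self):
        m = build_model(DetectorConfig(rep_backbone=False, bifpn_neck=False,
                                       tdadh_head=False), seed=0)
        m.eval()
        with no_grad():
            cls_out, _ = m(Tensor(np.zeros((1, 3, 640, 640), np.float32)))
        assert [tuple(c.shape[-2:]) for c in cls_out] == [(80, 80), (40, 40), (20, 20)]


class TestAssignment:
    def test_perfect_anchor_gets_matched(self):
        scores = np.array([[1.0]], np.float32)
        boxes = np.array([[0, 0, 10, 10]], np.float32)
        pts = np.array([[5, 5]], np.float32)
        gt = np.array([[0, 0, 10, 10]], np.float32)
        fg, matched, t = assign_targets(scores, boxes, pts, gt,
                                        np.array([0]))
        assert fg[0] and matched[0] == 0
        assert t[0, 0] == pytest.approx(1.0)

    def test_zero_score_annihilates_alignment(self):
        scores = np.array([[0.0]], np.float32)
        boxes = np.array([[0, 0, 10, 10]], np.float32)
        pts = np.array([[5, 5]], np.float32)
        fg, _, t = assign_targets(scores, boxes, pts,
                                  np.array([[0, 0, 10, 10]], np.float32), np.array([0]))
        assert not fg.any() and t.sum() == 0

    def test_empty_ground_truth_all_background(self, rng):
        fg, matched, t = assign_targets(
            rng.uniform(0, 1, (7, 1)).astype(np.float32),
            rng.uniform(0, 10, (7, 4)).astype(np.float32),
            rng.uniform(0, 10, (7, 2)).astype(np.float32),
            np.zeros((0, 4), np.float32), np.zeros(0, np.int64))
        assert not fg.any() and (matched == -1).all()

    def test_matches_exhaustive_enumeration_small_scenes(self, rng):
        """Oracle: direct enumeration of the top-k + conflict rule."""
        cfg = AssignerConfig(alpha=0.5, beta=6.0, topk=2)
        for _ in range(30):
            A, G = int(rng.integers(1, 6)), int(rng.integers(1, 3))
            scores = rng.uniform(0, 1, (A, 1)).astype(np.float32)
            pts = rng.uniform(0, 20, (A, 2)).astype(np.float32)
            half = rng.uniform(1, 6, (A, 2)).astype(np.float32)
            boxes = np.concatenate([pts - half, pts + half], 1)
            gtc = np.concatenate([rng.uniform(0, 20, (G, 2))] * 2, 1).astype(np.float32)
            gt = gtc + np.array([-4, -4, 4, 4], np.float32)
            fg, matched, _ = assign_targets(scores, boxes, pts, gt,
                                            np.zeros(G, np.int64), cfg)
            # oracle
            from maizedet.detector import _pairwise_iou_xyxy
            ious = _pairwise_iou_xyxy(boxes, gt)
            expected = np.full(A, -1)
            tmat = np.zeros((A, G))
            for a in range(A):
                for g in range(G):
                    inside = (gt[g, 0] < pts[a, 0] < gt[g, 2]
                              and gt[g, 1] < pts[a, 1] < gt[g, 3])
                    tmat[a, g] = (scores[a, 0] ** 0.5) * (ious[a, g] ** 6.0) * inside
            cand = np.zeros((A, G), bool)
            for g in range(G):
                order = sorted(range(A), key=lambda a: (-tmat[a, g], a))[:2]
                for a in order:
                    if tmat[a, g] > 0:
                        cand[a, g] = True
            for a in range(A):
                gs = [g for g in range(G) if cand[a, g]]
                if gs:
                    expected[a] = max(gs, key=lambda g: tmat[a, g])
            assert np.array_equal(matched, expected)
            assert np.array_equal(fg, expected >= 0)


class TestLoss:
    def _outputs(self, model, rng, batch=1):
        model.train()
        x = Tensor(rng.uniform(0, 1, (batch, 3, 64, 64)).astype(np.float32))
        return model(x)

    def _ann(self):
        return ImageAnnotation("a", 64, 64, [NormalizedBox(0, 0.5, 0.5, 0.25, 0.25)])

    def test_components_finite_nonnegative(self, rng):
        m = tiny_model()
        cls_out, reg_out = self._outputs(m, rng)
        losses = compute_loss(m, cls_out, reg_out, [self._ann()], (64, 64))
        for k in ("total", "box", "cls", "dfl"):
            v = float(losses[k].data)
            assert np.isfinite(v) and v >= 0

    def test_doubling_weights_doubles_total(self, rng):
        m = tiny_model()
        cls_out, reg_out = self._outputs(m, rng)
        l1 = compute_loss(m, cls_out, reg_out, [self._ann()], (64, 64),
                          LossWeights(7.5, 0.5, 1.5))
        l2 = compute_loss(m, cls_out, reg_out, [self._ann()], (64, 64),
                          LossWeights(15.0, 1.0, 3.0))
        assert float(l2["total"].data) == pytest.approx(2 * float(l1["total"].data), rel=1e-5)

    def test_no_ground_truth_gives_zero_box_dfl(self, rng):
        m = tiny_model()
        cls_out, reg_out = self._outputs(m, rng)
        empty = ImageAnnotation("e", 64, 64, [])
        losses = compute_loss(m, cls_out, reg_out, [empty], (64, 64))
        assert float(losses["box"].data) == 0 and float(losses["dfl"].data) == 0
        assert float(losses["cls"].data) > 0

    def test_dfl_integer_distance_is_single_bin_nll(self):
        """At a side distance exactly on bin k, the bracketing cross-entropy
        reduces to -log p(k)."""
        rm = 16
        logits = np.zeros((1, 4, rm), np.float32)
        tdist = np.array([[3.0, 3.0, 3.0, 3.0]])
        lo = np.floor(tdist).astype(int)
        w_hi = tdist - lo
        z = np.exp(logits)
        p = z / z.sum(-1, keepdims=True)
        ce = -(np.log(p[0, np.arange(4), lo[0]]) * (1 - w_hi[0])
               + np.log(p[0, np.arange(4), (lo[0] + 1) % rm]) * w_hi[0])
        assert np.allclose(ce, -np.log(p[0, 0, 3]))


class TestInference:
    def test_conf_threshold_one_empty(self, rng):
        m = tiny_model()
        img = rng.uniform(0, 1, (64, 64, 3)).astype(np.float32)
        assert predict(m, img, conf_threshold=1.0) == []

    def test_nms_identical_boxes_keep_one(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], np.float32)
        keep = nms(boxes, np.array([0.9, 0.8], np.float32), 0.5)
        assert list(keep) == [0]

    def test_nms_matches_greedy_oracle(self, rng):
        from maizedet.detector import _pairwise_iou_xyxy
        for _ in range(20):
            n = int(rng.integers(1, 12))
            c = rng.uniform(0, 50, (n, 2)).astype(np.float32)
            half = rng.uniform(2, 8, (n, 2)).astype(np.float32)
            boxes = np.concatenate([c - half, c + half], 1)
            scores = rng.uniform(0, 1, n).astype(np.float32)
            keep = list(nms(boxes, scores, 0.5))
            # O(n^2) reference
            order = np.argsort(-scores, kind="stable")
            ref, dead = [], set()
            for i in order:
                if i in dead:
                    continue
                ref.append(i)
                for j in order:
                    if j not in dead and j != i and \
                            _pairwise_iou_xyxy(boxes[i:i+1], boxes[j:j+1])[0, 0] > 0.5:
                        dead.add(j)
            assert keep == ref

    def test_detections_sorted_and_count(self, rng):
        m = tiny_model()
        img = rng.uniform(0, 1, (64, 64, 3)).astype(np.float32)
        dets = predict(m, img, conf_threshold=0.0)
        confs = [d.confidence for d in dets]
        assert confs == sorted(confs, reverse=True)
        assert count_seedlings(dets) == len(dets)
        assert count_seedlings([]) == 0


class TestPersistence:
    def test_checkpoint_roundtrip(self, rng, tmp_path):
        m = tiny_model(seed=3)
        p = tmp_path / "ck.npz"
        save_checkpoint(m, p, epoch=7)
        m2, meta = load_checkpoint(p)
        assert meta["epoch"] == 7 and not meta["fused"]
        x = rng.uniform(0, 1, (1, 3, 64, 64)).astype(np.float32)
        m.eval(); m2.eval()
        with no_grad():
            a = m(Tensor(x))[0][0].data
            b = m2(Tensor(x))[0][0].data
        assert np.array_equal(a, b)


class TestTrainLoop:
    def test_one_epoch_smoke_and_log_row(self, tmp_path):
        cfg = FieldConfig(image_size_px=(64, 64), density=2,
                          seedling_rel_width_range=(0.15, 0.3),
                          seedling_rel_height_range=(0.15, 0.3),
                          plant_spacing_cm=200.0)
        ds = DetectionDataset.synthetic(cfg, 4, seed=0, ratios=(1, 1e-9, 1e-9))
        m = tiny_model()
        log = train(m, ds, TrainConfig(epochs=1, batch_size=2, eval_interval=1),
                    out_dir=tmp_path)
        assert len(log) == 1
        assert {"epoch", "loss_total", "map50"} <= set(log[0])
        assert (tmp_path / "last.npz").exists()
        # resume continues epoch numbering
        m2, meta = load_checkpoint(tmp_path / "last.npz")
        log2 = train(m2, ds, TrainConfig(epochs=2, batch_size=2, eval_interval=2),
                     start_epoch=meta["epoch"] + 1)
        assert log2[0]["epoch"] == 1

    def test_seed_determinism(self):
        cfg = FieldConfig(image_size_px=(64, 64), density=2,
                          seedling_rel_width_range=(0.15, 0.3),
                          seedling_rel_height_range=(0.15, 0.3),
                          plant_spacing_cm=200.0)
        ds = DetectionDataset.synthetic(cfg, 4, seed=0, ratios=(1, 1e-9, 1e-9))
        logs = []
        for _ in range(2):
            m = tiny_model(seed=5)
            logs.append(train(m, ds, TrainConfig(epochs=1, batch_size=2,
                                                 eval_interval=9, seed=11)))
        assert logs[0][0]["loss_total"] == pytest.approx(logs[1][0]["loss_total"], abs=1e-7)


class TestVideo:
    def test_frame_directory_processing(self, rng, tmp_path):
        from PIL import Image
        m = tiny_model()
        img = (rng.uniform(0, 1, (64, 64, 3)) * 255).astype(np.uint8)
        for i in range(3):
            Image.fromarray(img).save(tmp_path / f"f{i}.png")
        out = process_video(m, tmp_path, conf_threshold=0.5)
        assert len(out["frames"]) == 3
        assert out["fps"] > 0
        # static clip: identical detections every frame
        counts = {r["count"] for r in out["frames"]}
        assert len(counts) == 1

    def test_iterable_source_and_fps_identity(self, rng):
        m = tiny_model()
        frames = [rng.uniform(0, 1, (64, 64, 3)).astype(np.float32)] * 2
        out = process_video(m, frames)
        assert len(out["frames"]) == 2
        assert out["fps"] == pytest.approx(1.0 / out["seconds_per_frame"], rel=1e-6)

    def test_undecodable_frame_skipped_with_warning(self, rng):
        m = tiny_model()
        frames = [rng.uniform(0, 1, (64, 64, 3)).astype(np.float32), None]
        with pytest.warns(UserWarning, match="skipped"):
            out = process_video(m, frames)
        assert out["skipped"] == 1 and len(out["frames"]) == 1


class TestReparamEndToEnd:
    def test_deployed_model_equals_training_structure(self, rng):
        from maizedet.backbone import reparameterize
        from maizedet.metrics import count_params
        m = tiny_model(seed=1)
        # realistic BN stats
        m.train()
        for _ in range(2):
            m(Tensor(rng.uniform(0, 1, (2, 3, 64, 64)).astype(np.float32)))
        m.eval()
        x = rng.uniform(0, 1, (1, 3, 64, 64)).astype(np.float32)
        with no_grad():
            c0, r0 = m(Tensor(x))
        n0 = count_params(m).total_params
        reparameterize(m)
        with no_grad():
            c1, r1 = m(Tensor(x))
        assert count_params(m).total_params < n0
        for a, b in zip(c0 + r0, c1 + r1):
            assert np.abs(a.data - b.data).max() <= 1e-5
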