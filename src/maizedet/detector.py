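"""Detector assembly: backbone + neck + head, label assignment, loss, training,
inference, counting and frame-stream processing.

The three improvement flags (reparameterizable backbone, bidirectional
weighted neck, shared-conv task-aligned head) are independent, so all eight
ablation variants are constructible; all-flags-off is the reference baseline
detector and all-flags-on the full lightweight model.

Label assignment is task-aligned (TAL): each ground truth claims the top-k
anchors by the alignment metric t = score^alpha * IoU^beta among anchors whose
center lies inside the box; an anchor claimed twice goes to the higher t.
The loss is the family-standard weighted sum of binary cross-entropy on
alignment-weighted class targets, complete-IoU on matched boxes, and
distribution-focal cross-entropy on the two bins bracketing each true side
distance.
"""

from __future__ import annotations

import json
import math
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from maizedet.backbone import (
    BackboneConfig, CSPBackbone, RepHGBackbone, reparameterize,
)
from maizedet.head import (
    DecoupledHead, TDADH, build_head, dfl_expectation, make_anchor_points,
)
from maizedet.labels_io import Detection, ImageAnnotation, NormalizedBox
from maizedet.neck import BiFPN, BiFPNConfig, PANetNeck
from maizedet.nn import Module, SGD, Tensor, no_grad
from maizedet.nn import tensor as T

__all__ = [
    "DetectorConfig", "TrainConfig", "AssignerConfig", "LossWeights",
    "Detector", "build_model", "assign_targets", "compute_loss",
    "train", "predict", "count_seedlings", "process_video", "nms",
    "save_checkpoint", "load_checkpoint",
]

STRIDES = (8, 16, 32)


@dataclass
class DetectorConfig:
    """Variant flags and structural hyperparameters of the detector.

    The default widths are the canonical calibrated configuration of the
    improved model; ``width_multiple`` scales every width for desk-scale
    experiments without touching the topology.
    """

    input_size: int = 640
    num_classes: int = 1
    rep_backbone: bool = True
    bifpn_neck: bool = True
    tdadh_head: bool = True
    reg_max: int = 16
    gn_groups: int = 16
    neck_repeats: tuple[int, int, int, int] | int = (1, 1, 1, 4)
    neck_expansion: float = 0.25
    neck_down_groups: int = 4
    head_width: int = 96
    backbone: BackboneConfig | None = None
    width_multiple: float = 1.0

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d)

    @staticmethod
    def from_json(s: str) -> "DetectorConfig":
        d = json.loads(s)
        bb = d.pop("backbone", None)
        if isinstance(d.get("neck_repeats"), list):
            d["neck_repeats"] = tuple(d["neck_repeats"])
        cfg = DetectorConfig(**d)
        if bb is not None:
            from maizedet.backbone import StageSpec
            stages = [StageSpec(**st) for st in bb.pop("stages")]
            cfg.backbone = BackboneConfig(stages=stages, **bb)
        return cfg


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults are the printed study settings."""

    lr0: float = 0.01
    lrf: float = 0.01           # final lr = lr0 * lrf (linear decay to 1e-4)
    momentum: float = 0.937
    batch_size: int = 16
    epochs: int = 400
    workers: int = 4            # kept for config parity; loading is in-process
    seed: int = 0
    eval_interval: int = 1
    grad_clip: float = 10.0
    warmup_epochs: float = 3.0         # linear lr/momentum ramp-in
    warmup_momentum: float = 0.8
    stop_at_map: float | None = None   # early-stop once eval mAP@0.5 reaches this


@dataclass
class AssignerConfig:
    alpha: float = 0.5
    beta: float = 6.0
    topk: int = 10


@dataclass
class LossWeights:
    box: float = 7.5
    cls: float = 0.5
    dfl: float = 1.5

    def __post_init__(self):
        if min(self.box, self.cls, self.dfl) < 0:
            raise ValueError("loss weights must be non-negative")


class Detector(Module):
    """The assembled detector; forward yields per-level (cls, reg) outputs."""

    def __init__(self, config: DetectorConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config
        rng = rng or np.random.default_rng(0)
        wm = config.width_multiple

        def scale_w(w, q=16):
            return max(q, int(round(w * wm / q) * q)) if wm != 1.0 else w

        if config.rep_backbone:
            bb_cfg = config.backbone or BackboneConfig()
            if wm != 1.0:
                from maizedet.backbone import StageSpec
                bb_cfg = BackboneConfig(
                    stem_mid=scale_w(bb_cfg.stem_mid, 8), stem_out=scale_w(bb_cfg.stem_out, 8),
                    stages=[StageSpec(scale_w(s.mid_channels, 8), scale_w(s.out_channels, 8),
                                      s.n_blocks, s.n_light, s.downsample)
                            for s in bb_cfg.stages])
            self.backbone = RepHGBackbone(bb_cfg, rng=rng)
        else:
            self.backbone = CSPBackbone(rng=rng)
        if config.bifpn_neck:
            self.neck = BiFPN(BiFPNConfig(repeats=config.neck_repeats,
                                          expansion=config.neck_expansion,
                                          down_groups=config.neck_down_groups),
                              self.backbone.out_specs, rng=rng)
        else:
            self.neck = PANetNeck(self.backbone.out_specs, rng=rng)
        in_ch = tuple(s.channels for s in self.neck.out_specs)
        self.head = build_head(in_ch, config.num_classes, config.reg_max,
                               config.gn_groups, width=scale_w(config.head_width),
                               shared=config.tdadh_head, rng=rng)

    def forward(self, x: Tensor) -> tuple[list[Tensor], list[Tensor]]:
        h, w = x.shape[-2:]
        if h % 32 or w % 32:
            raise ValueError(f"input spatial size {h}x{w} must be a multiple of 32")
        return self.head(self.neck(self.backbone(x)))

    # ---- decode helpers -----------------------------------------------------
    def _scale_tensors(self) -> list:
        if isinstance(self.head, TDADH):
            return [s.value for s in self.head.scales]
        return [Tensor(np.float32(1.0))] * 3

    def flatten_outputs(self, cls_list, reg_list):
        """-> (cls_logits (B,A,nc), dist_bins (B,A,4) Tensor, reg_logits (B,A,4,regmax))."""
        b = cls_list[0].shape[0]
        nc, rm = self.config.num_classes, self.config.reg_max
        cls_flat, reg_flat, dist_parts = [], [], []
        scales = self._scale_tensors()
        for cl, rg, sc in zip(cls_list, reg_list, scales):
            h, w = cl.shape[-2:]
            cls_flat.append(cl.reshape(b, nc, h * w).transpose(0, 2, 1))
            r = rg.reshape(b, 4, rm, h * w).transpose(0, 3, 1, 2)  # (B,HW,4,rm)
            reg_flat.append(r)
            dist_parts.append(dfl_expectation(r, rm) * sc)
        return (T.concat(cls_flat, axis=1), T.concat(dist_parts, axis=1),
                T.concat(reg_flat, axis=1))

    def anchor_data(self, input_hw: tuple[int, int]):
        """(anchor_points_px (A,2), stride_per_anchor (A,), level sizes)."""
        sizes = [(input_hw[0] // s, input_hw[1] // s) for s in STRIDES]
        pts = make_anchor_points(sizes, list(STRIDES))
        stride_arr = np.concatenate([
            np.full(h * w, s, dtype=np.float32) for (h, w), s in zip(sizes, STRIDES)])
        return pts, stride_arr, sizes


def build_model(config: DetectorConfig, seed: int = 0) -> Detector:
    """Build any of the eight ablation variants from its flag combination."""
    return Detector(config, rng=np.random.default_rng(seed))


# =====================================================================
# Assignment
# =====================================================================

def _pairwise_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix between (N,4) and (M,4) corner boxes."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)), dtype=np.float32)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.prod(np.clip(a[:, 2:] - a[:, :2], 0, None), axis=1)
    area_b = np.prod(np.clip(b[:, 2:] - b[:, :2], 0, None), axis=1)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0).astype(np.float32)


def assign_targets(scores: np.ndarray, pred_boxes: np.ndarray,
                   anchor_points: np.ndarray, gt_boxes: np.ndarray,
                   gt_classes: np.ndarray,
                   assigner: AssignerConfig = AssignerConfig()):
    """Task-aligned assignment for one image (all arrays in pixel units).

    Parameters are per-anchor class scores (A, nc) in [0,1], decoded candidate
    boxes (A, 4), anchor centers (A, 2), and ground truth (G, 4)/(G,).

    Returns ``(fg_mask (A,), matched_gt (A,), target_scores (A, nc))`` where
    target scores are the alignment metrics normalized per ground truth so the
    best anchor's target equals that ground truth's best IoU.
    """
    A, nc = scores.shape
    fg = np.zeros(A, dtype=bool)
    matched = np.full(A, -1, dtype=np.int64)
    tgt_scores = np.zeros((A, nc), dtype=np.float32)
    G = len(gt_boxes)
    if G == 0:
        return fg, matched, tgt_scores
    inside = ((anchor_points[:, None, 0] > gt_boxes[None, :, 0]) &
              (anchor_points[:, None, 0] < gt_boxes[None, :, 2]) &
              (anchor_points[:, None, 1] > gt_boxes[None, :, 1]) &
              (anchor_points[:, None, 1] < gt_boxes[None, :, 3]))      # (A,G)
    ious = _pairwise_iou_xyxy(pred_boxes, gt_boxes)                     # (A,G)
    s = scores[:, gt_classes]                                           # (A,G)
    t = (s ** assigner.alpha) * (ious ** assigner.beta) * inside
    # top-k anchors per gt (ties broken by anchor index: stable argsort)
    cand = np.zeros_like(t, dtype=bool)
    k = min(assigner.topk, A)
    order = np.argsort(-t, axis=0, kind="stable")[:k]                   # (k, G)
    for g in range(G):
        sel = order[:, g]
        sel = sel[t[sel, g] > 0]
        cand[sel, g] = True
    # resolve conflicts: anchor goes to the gt with the higher t
    t_cand = np.where(cand, t, -1.0)
    best_gt = t_cand.argmax(axis=1)
    has = t_cand.max(axis=1) > 0
    fg[has] = True
    matched[has] = best_gt[has]
    # normalized target scores (per-gt max alignment scaled to max IoU)
    for g in range(G):
        sel = np.where(fg & (matched == g))[0]
        if len(sel) == 0:
            continue
        tmax = t[sel, g].max()
        umax = ious[sel, g].max()
        norm = t[sel, g] * (umax / (tmax + 1e-9))
        tgt_scores[sel, gt_classes[g]] = norm
    return fg, matched, tgt_scores


# =====================================================================
# Loss
# =====================================================================

def _ciou(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Complete IoU between predicted (N,4) corner boxes (autograd) and
    constant targets; the aspect-term coefficient is treated as constant."""
    tgt = Tensor(target)
    ix1 = pred[:, 0].maximum(tgt[:, 0])
    iy1 = pred[:, 1].maximum(tgt[:, 1])
    ix2 = pred[:, 2].minimum(tgt[:, 2])
    iy2 = pred[:, 3].minimum(tgt[:, 3])
    iw = (ix2 - ix1).clip(0, None)
    ih = (iy2 - iy1).clip(0, None)
    inter = iw * ih
    pw = (pred[:, 2] - pred[:, 0]).clip(eps, None)
    ph = (pred[:, 3] - pred[:, 1]).clip(eps, None)
    tw = np.clip(target[:, 2] - target[:, 0], eps, None)
    th = np.clip(target[:, 3] - target[:, 1], eps, None)
    union = pw * ph + Tensor(tw * th) - inter + eps
    iou = inter / union
    # enclosing box diagonal
    cx1 = pred[:, 0].minimum(tgt[:, 0])
    cy1 = pred[:, 1].minimum(tgt[:, 1])
    cx2 = pred[:, 2].maximum(tgt[:, 2])
    cy2 = pred[:, 3].maximum(tgt[:, 3])
    c2 = (cx2 - cx1) ** 2 + (cy2 - cy1) ** 2 + eps
    rho2 = (((pred[:, 0] + pred[:, 2]) - (tgt[:, 0] + tgt[:, 2])) ** 2 +
            ((pred[:, 1] + pred[:, 3]) - (tgt[:, 1] + tgt[:, 3])) ** 2) * 0.25
    v = (4 / math.pi ** 2) * ((Tensor(np.arctan(tw / th)) - (pw / ph).atan()) ** 2)
    alpha = v.data / (1.0 - iou.data + v.data + eps)   # no grad through alpha
    return iou - rho2 / c2 - v * Tensor(alpha)


def compute_loss(model: Detector, cls_list, reg_list, annotations,
                 input_hw: tuple[int, int],
                 weights: LossWeights = LossWeights(),
                 assigner: AssignerConfig = AssignerConfig()) -> dict:
    """Total and per-component loss for a batch.

    ``annotations`` is one ImageAnnotation per batch element; boxes are
    converted to pixel units of the network input.
    """
    cfg = model.config
    cls_logits, dist_bins, reg_logits = model.flatten_outputs(cls_list, reg_list)
    b, A, nc = cls_logits.shape
    rm = cfg.reg_max
    pts, stride_arr, _ = model.anchor_data(input_hw)
    scale_per_anchor = np.concatenate([
        np.full((input_hw[0] // s) * (input_hw[1] // s), sv, dtype=np.float32)
        for s, sv in zip(STRIDES, [float(t.data) for t in model._scale_tensors()])])
    # decoded boxes in pixels (autograd): anchors -/+ dist*stride
    dist_px = dist_bins * Tensor(stride_arr[None, :, None])
    h_img, w_img = input_hw

    scores_np = 1.0 / (1.0 + np.exp(-cls_logits.data))
    boxes_np = np.stack([pts[None, :, 0] - dist_px.data[..., 0],
                         pts[None, :, 1] - dist_px.data[..., 1],
                         pts[None, :, 0] + dist_px.data[..., 2],
                         pts[None, :, 1] + dist_px.data[..., 3]], axis=-1)

    tgt_scores_all = np.zeros((b, A, nc), dtype=np.float32)
    fg_all = np.zeros((b, A), dtype=bool)
    gt_box_of = np.zeros((b, A, 4), dtype=np.float32)
    for i, ann in enumerate(annotations):
        gtb = np.array([[(bx.cx - bx.w / 2) * w_img, (bx.cy - bx.h / 2) * h_img,
                         (bx.cx + bx.w / 2) * w_img, (bx.cy + bx.h / 2) * h_img]
                        for bx in ann.instances], dtype=np.float32).reshape(-1, 4)
        gtc = np.array([bx.class_id for bx in ann.instances], dtype=np.int64)
        fg, matched, tgt = assign_targets(scores_np[i], boxes_np[i], pts, gtb, gtc, assigner)
        tgt_scores_all[i] = tgt
        fg_all[i] = fg
        if fg.any():
            gt_box_of[i, fg] = gtb[matched[fg]]

    # classification BCE on alignment-weighted targets (all anchors)
    tgt_t = Tensor(tgt_scores_all)
    p = cls_logits
    # stable BCE-with-logits: max(p,0) - p*t + log(1+exp(-|p|))
    bce = p.clip(0, None) - p * tgt_t + (1.0 + (-(p.maximum(-p))).exp()).log()
    norm = max(float(tgt_scores_all.sum()), 1.0)
    loss_cls = bce.sum() / norm

    n_fg = int(fg_all.sum())
    if n_fg:
        bi, ai = np.where(fg_all)
        w_fg = tgt_scores_all[bi, ai].sum(axis=-1)
        pred_fg = T.stack([
            Tensor(pts[ai, 0]) - dist_px[bi, ai, 0],
            Tensor(pts[ai, 1]) - dist_px[bi, ai, 1],
            Tensor(pts[ai, 0]) + dist_px[bi, ai, 2],
            Tensor(pts[ai, 1]) + dist_px[bi, ai, 3]], axis=1)
        tgt_fg = gt_box_of[bi, ai]
        ciou = _ciou(pred_fg, tgt_fg)
        loss_box = ((1.0 - ciou) * Tensor(w_fg)).sum() / norm
        # DFL: target side distances in bin units at each anchor's stride/scale
        s_fg = stride_arr[ai] * scale_per_anchor[ai]
        tdist = np.stack([pts[ai, 0] - tgt_fg[:, 0], pts[ai, 1] - tgt_fg[:, 1],
                          tgt_fg[:, 2] - pts[ai, 0], tgt_fg[:, 3] - pts[ai, 1]],
                         axis=1) / s_fg[:, None]
        tdist = np.clip(tdist, 0, rm - 1 - 1e-3)
        lo = np.floor(tdist).astype(np.int64)
        hi = lo + 1
        w_hi = tdist - lo
        w_lo = 1.0 - w_hi
        logits_fg = reg_logits[bi, ai]                   # (N,4,rm)
        logp = (logits_fg.softmax(axis=-1) + 1e-9).log()
        n = len(bi)
        rows = np.arange(n)[:, None]
        cols = np.arange(4)[None, :]
        ce = -(logp[rows, cols, lo] * Tensor(w_lo) + logp[rows, cols, hi] * Tensor(w_hi))
        loss_dfl = (ce.mean(axis=1) * Tensor(w_fg)).sum() / norm
    else:
        loss_box = Tensor(np.float32(0.0))
        loss_dfl = Tensor(np.float32(0.0))

    total = loss_box * weights.box + loss_cls * weights.cls + loss_dfl * weights.dfl
    return {"total": total, "box": loss_box, "cls": loss_cls, "dfl": loss_dfl,
            "n_fg": n_fg}


# =====================================================================
# Inference
# =====================================================================

def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy class-agnostic non-maximum suppression; returns kept indices."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for idx in order:
        if suppressed[idx]:
            continue
        keep.append(idx)
        rest = order[~suppressed[order]]
        ious = _pairwise_iou_xyxy(boxes[idx:idx + 1], boxes[rest])[0]
        suppressed[rest[ious > iou_threshold]] = True
        suppressed[idx] = True
    return np.array(keep, dtype=np.int64)


def _prepare_image(image: np.ndarray, input_size: int) -> tuple[np.ndarray, tuple]:
    """HWC uint8/float image -> (1,3,S,S) float32 in [0,1], plus original size."""
    img = np.asarray(image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 255.0
    h0, w0 = img.shape[:2]
    if (h0, w0) != (input_size, input_size):
        # nearest-neighbor letterbox-free resize (aspect is preserved upstream
        # by the square synthetic canvases; real images are squashed)
        yi = np.clip((np.arange(input_size) + 0.5) * h0 / input_size, 0, h0 - 1).astype(int)
        xi = np.clip((np.arange(input_size) + 0.5) * w0 / input_size, 0, w0 - 1).astype(int)
        img = img[yi][:, xi]
    return img.transpose(2, 0, 1)[None].astype(np.float32), (h0, w0)


def predict(model: Detector, image: np.ndarray, conf_threshold: float = 0.25,
            iou_threshold: float = 0.7, max_det: int = 300) -> list[Detection]:
    """Run the detector on one image and return NMS-filtered detections.

    Detections carry normalized boxes and are sorted by confidence descending.
    """
    s = model.config.input_size
    x, _ = _prepare_image(image, s)
    model.eval()
    with no_grad():
        cls_list, reg_list = model(Tensor(x))
        cls_logits, dist_bins, _ = model.flatten_outputs(cls_list, reg_list)
    pts, stride_arr, _ = model.anchor_data((s, s))
    scores = 1.0 / (1.0 + np.exp(-cls_logits.data[0]))      # (A, nc)
    dist_px = dist_bins.data[0] * stride_arr[:, None]
    boxes = np.stack([pts[:, 0] - dist_px[:, 0], pts[:, 1] - dist_px[:, 1],
                      pts[:, 0] + dist_px[:, 2], pts[:, 1] + dist_px[:, 3]], axis=1)
    conf = scores.max(axis=1)
    cls_id = scores.argmax(axis=1)
    m = conf >= conf_threshold
    if not m.any():
        return []
    boxes, conf, cls_id = boxes[m], conf[m], cls_id[m]
    keep = nms(boxes, conf, iou_threshold)[:max_det]
    out = []
    for i in keep:
        x1, y1, x2, y2 = np.clip(boxes[i], 0, s)
        if x2 - x1 <= 0 or y2 - y1 <= 0:
            continue
        out.append(Detection(
            NormalizedBox(int(cls_id[i]),
                          cx=float((x1 + x2) / 2 / s), cy=float((y1 + y2) / 2 / s),
                          w=float((x2 - x1) / s), h=float((y2 - y1) / s)),
            confidence=float(conf[i])))
    out.sort(key=lambda d: -d.confidence)
    return out


def count_seedlings(detections: list[Detection]) -> int:
    """Stand count: the number of post-suppression detections."""
    return len(detections)


def process_video(model: Detector, source, conf_threshold: float = 0.25,
                  iou_threshold: float = 0.7) -> dict:
    """Frame-by-frame detection over an image-sequence 'video'.

    ``source`` may be a directory of frames, a multi-frame TIFF/GIF file, or
    any iterable of HWC arrays. Returns per-frame records and the mean FPS
    (frames per second = 1 / mean seconds per frame). Undecodable frames are
    skipped with a warning and counted.
    """
    frames = _iter_frames(source)
    records = []
    skipped = 0
    t0 = time.perf_counter()
    for i, frame in enumerate(frames):
        try:
            if frame is None:
                raise ValueError("undecodable frame")
            dets = predict(model, frame, conf_threshold, iou_threshold)
        except Exception as exc:  # undecodable frame
            warnings.warn(f"frame {i} skipped: {exc}")
            skipped += 1
            continue
        records.append({"frame": i, "detections": dets, "count": len(dets)})
    elapsed = time.perf_counter() - t0
    n = len(records)
    fps = n / elapsed if elapsed > 0 and n else 0.0
    return {"frames": records, "skipped": skipped, "fps": fps,
            "seconds_per_frame": (elapsed / n) if n else float("nan")}


def _iter_frames(source):
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.is_dir():
            import imageio.v3 as iio
            for f in sorted(p.iterdir()):
                if f.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"):
                    try:
                        yield iio.imread(f)
                    except Exception:
                        yield None
            return
        import imageio.v3 as iio
        for frame in iio.imiter(p):
            yield np.asarray(frame)
        return
    yield from source


# =====================================================================
# Training
# =====================================================================

def _eval_map(model: Detector, images, annotations, conf=0.05, iou_nms=0.7):
    from maizedet.metrics import evaluate_detections
    all_dets, all_gts = [], []
    for img, ann in zip(images, annotations):
        all_dets.append(predict(model, img, conf_threshold=conf, iou_threshold=iou_nms))
        all_gts.append(ann)
    return evaluate_detections(all_dets, all_gts, iou_threshold=0.5)


def save_checkpoint(model: Detector, path: str | Path, epoch: int = 0,
                    extra: dict | None = None) -> None:
    """Single-file archive: config JSON + weights + fusion state flag."""
    state = model.state_dict()
    fused = any(getattr(m, "fused", False) for m in model.modules())
    meta = {"config": json.loads(model.config.to_json()), "epoch": epoch,
            "fused": bool(fused), **(extra or {})}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | Path) -> tuple[Detector, dict]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
    cfg = DetectorConfig.from_json(json.dumps(meta["config"]))
    model = Detector(cfg)
    if meta.get("fused"):
        reparameterize(model)
    model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta


def train(model: Detector, dataset, config: TrainConfig = TrainConfig(),
          out_dir: str | Path | None = None,
          weights: LossWeights = LossWeights(),
          assigner: AssignerConfig = AssignerConfig(),
          start_epoch: int = 0, log_fn=None) -> list[dict]:
    """SGD training loop with linear learning-rate decay.

    ``dataset`` must expose ``train_images``, ``train_annotations`` (and
    optionally ``val_*``) as sequences of HWC arrays / ImageAnnotations.
    Returns the per-epoch log (loss components, P, R, mAP@0.5). Seeded and
    deterministic in single-threaded execution. Aborts on non-finite loss.
    """
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.parameters(), lr=config.lr0, momentum=config.momentum)
    imgs = dataset.train_images
    anns = dataset.train_annotations
    n = len(imgs)
    s = model.config.input_size
    log: list[dict] = []
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    best_map = -1.0
    batches_per_epoch = max(1, -(-n // config.batch_size))
    warmup_iters = config.warmup_epochs * batches_per_epoch
    for epoch in range(start_epoch, config.epochs):
        model.train()
        frac = epoch / max(config.epochs, 1)
        lr_sched = config.lr0 * (1.0 - frac * (1.0 - config.lrf))
        order = rng.permutation(n)
        sums = {"total": 0.0, "box": 0.0, "cls": 0.0, "dfl": 0.0}
        nb = 0
        for start in range(0, n, config.batch_size):
            it = epoch * batches_per_epoch + nb
            if it < warmup_iters:
                # ramp lr from ~0 and momentum from its warmup value to avoid
                # the early collapse where boxes shrink before scores align
                w = it / warmup_iters
                opt.lr = lr_sched * w
                opt.momentum = (config.warmup_momentum
                                + (config.momentum - config.warmup_momentum) * w)
            else:
                opt.lr = lr_sched
                opt.momentum = config.momentum
            idx = order[start:start + config.batch_size]
            batch = np.stack([_prepare_image(imgs[i], s)[0][0] for i in idx])
            cls_list, reg_list = model(Tensor(batch, requires_grad=False))
            losses = compute_loss(model, cls_list, reg_list,
                                  [anns[i] for i in idx], (s, s), weights, assigner)
            tot = losses["total"]
            if not np.isfinite(tot.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: "
                    f"box={losses['box'].data} cls={losses['cls'].data} dfl={losses['dfl'].data}")
            opt.zero_grad()
            tot.backward()
            if config.grad_clip:
                gnorm = math.sqrt(sum(float((p.grad ** 2).sum())
                                      for p in opt.params if p.grad is not None))
                if gnorm > config.grad_clip:
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad *= config.grad_clip / gnorm
            opt.step()
            for k in sums:
                sums[k] += float(losses[k].data)
            nb += 1
        row = {"epoch": epoch, "lr": lr_sched,
               **{f"loss_{k}": v / max(nb, 1) for k, v in sums.items()}}
        if (epoch + 1) % config.eval_interval == 0 or epoch == config.epochs - 1:
            ev_imgs = getattr(dataset, "val_images", None) or imgs
            ev_anns = getattr(dataset, "val_annotations", None) or anns
            m = _eval_map(model, ev_imgs, ev_anns)
            row.update({"precision": m["precision"], "recall": m["recall"],
                        "map50": m["map50"]})
            if out_dir and m["map50"] > best_map:
                best_map = m["map50"]
                save_checkpoint(model, out_dir / "best.npz", epoch)
        log.append(row)
        if log_fn:
            log_fn(row)
        if out_dir:
            save_checkpoint(model, out_dir / "last.npz", epoch)
            with open(out_dir / "log.jsonl", "a") as fh:
                fh.write(json.dumps(row) + "\n")
        if (config.stop_at_map is not None
                and row.get("map50", 0.0) >= config.stop_at_map):
            break
    return log
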