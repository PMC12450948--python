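"""Detection-quality metrics and model-complexity accounting.

Quality side: greedy confidence-ordered matching at an IoU threshold,
precision/recall with the 0/0 -> 0 convention, and average precision as the
area under the monotone precision envelope over recall (all-point
interpolation). With a single class, mAP equals AP.

Complexity side: parameter accounting by per-layer traversal
(Cin/g * Cout * K^2 [+ Cout] per conv, 2C per norm, plus standalone
scalars) and FLOP accounting as 2 * multiply-accumulates per conv under a
fixed input size, each multiplication and addition counting as one FLOP.
Elementwise normalization work is tallied separately so both conv-only and
with-elementwise totals are available.
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass, field

import numpy as np

from maizedet.labels_io import Detection, ImageAnnotation, iou as box_iou
from maizedet.nn import BatchNorm2d, Conv2d, GroupNorm, Module, Tensor, no_grad

__all__ = [
    "ConfusionCounts", "PRCurve", "ProfileReport", "TimingResult",
    "match_detections", "precision", "recall", "pr_curve",
    "average_precision", "map50", "evaluate_detections",
    "count_params", "count_flops", "profile_model", "measure_fps",
    "profile_variants",
]


# =====================================================================
# Quality metrics
# =====================================================================

@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class PRCurve:
    """(precision, recall) points swept from high to low confidence."""

    precisions: np.ndarray
    recalls: np.ndarray
    n_classes: int = 1


def match_detections(detections: list[Detection], ground_truths: ImageAnnotation,
                     iou_threshold: float = 0.5) -> ConfusionCounts:
    """Greedy matching: each detection, in confidence order, takes the
    highest-IoU still-unmatched ground truth with IoU >= threshold."""
    dets = sorted(detections, key=lambda d: -d.confidence)
    used = [False] * len(ground_truths.instances)
    tp = fp = 0
    for d in dets:
        best, best_iou = -1, iou_threshold
        for gi, g in enumerate(ground_truths.instances):
            if used[gi] or g.class_id != d.box.class_id:
                continue
            v = box_iou(d.box, g)
            if v >= best_iou:
                best, best_iou = gi, v
        if best >= 0:
            used[best] = True
            tp += 1
        else:
            fp += 1
    fn = used.count(False)
    return ConfusionCounts(tp, fp, fn)


def precision(counts: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 by convention when the denominator is empty."""
    d = counts.tp + counts.fp
    return counts.tp / d if d else 0.0


def recall(counts: ConfusionCounts) -> float:
    """TP / (TP + FN); 0 by convention when the denominator is empty."""
    d = counts.tp + counts.fn
    return counts.tp / d if d else 0.0


def pr_curve(detections_per_image: list[list[Detection]],
             ground_truths: list[ImageAnnotation],
             iou_threshold: float = 0.5) -> PRCurve:
    """Precision-recall sweep over every detection confidence.

    Detections from all images are pooled and sorted by confidence; each, in
    order, greedily matches the best unmatched ground truth of its image with
    IoU >= threshold.
    """
    n_gt = sum(len(g) for g in ground_truths)
    flat = []
    for img_i, dets in enumerate(detections_per_image):
        for d in dets:
            flat.append((d.confidence, img_i, d))
    flat.sort(key=lambda t: -t[0])
    used = [[False] * len(g) for g in ground_truths]
    tps = np.zeros(len(flat))
    for k, (_, img_i, d) in enumerate(flat):
        g_ann = ground_truths[img_i]
        best, best_iou = -1, iou_threshold
        for gi, g in enumerate(g_ann.instances):
            if used[img_i][gi] or g.class_id != d.box.class_id:
                continue
            v = box_iou(d.box, g)
            if v >= best_iou:
                best, best_iou = gi, v
        if best >= 0:
            used[img_i][best] = True
            tps[k] = 1
    cum_tp = np.cumsum(tps)
    cum_fp = np.cumsum(1 - tps)
    rec = cum_tp / n_gt if n_gt else np.zeros(len(flat))
    prec = np.where(cum_tp + cum_fp > 0, cum_tp / (cum_tp + cum_fp), 0.0)
    return PRCurve(precisions=prec, recalls=rec)


def average_precision(curve: PRCurve) -> float:
    """Area under the precision envelope vs recall (all-point interpolation).

    Precision is replaced by its running maximum from high recall backwards,
    then integrated over recall; an empty curve has AP 0.
    """
    if len(curve.recalls) == 0:
        return 0.0
    r = np.concatenate([[0.0], curve.recalls, [curve.recalls[-1]]])
    p = np.concatenate([[0.0], curve.precisions, [0.0]])
    # monotone envelope from the high-recall end
    p = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def map50(per_class_aps: list[float]) -> float:
    """Mean over classes; with one class this equals AP exactly."""
    if not per_class_aps:
        return 0.0
    return float(np.mean(per_class_aps))


def evaluate_detections(detections_per_image, ground_truths,
                        iou_threshold: float = 0.5) -> dict:
    """AP/mAP plus precision and recall at the max-F1 confidence point."""
    curve = pr_curve(detections_per_image, ground_truths, iou_threshold)
    ap = average_precision(curve)
    if len(curve.recalls):
        f1 = 2 * curve.precisions * curve.recalls / np.clip(
            curve.precisions + curve.recalls, 1e-9, None)
        k = int(np.argmax(f1))
        p_best, r_best = float(curve.precisions[k]), float(curve.recalls[k])
    else:
        p_best = r_best = 0.0
    return {"map50": map50([ap]), "ap": ap, "precision": p_best, "recall": r_best}


# =====================================================================
# Complexity accounting
# =====================================================================

@dataclass
class ProfileReport:
    total_params: int
    total_flops: int
    flops_elementwise: int
    breakdown: list[tuple[str, int, int]] = field(default_factory=list)
    input_size: int | None = None

    @property
    def params_millions(self) -> float:
        return round(self.total_params / 1e6, 2)

    @property
    def gflops(self) -> float:
        return round(self.total_flops / 1e9, 1)

    def weight_bytes(self, bits: int = 32) -> int:
        """Serialized weight size at 32- or 16-bit float encoding."""
        return self.total_params * bits // 8


@dataclass
class TimingResult:
    seconds_per_image: float
    fps: float
    hardware: str = ""


def _module_own_params(m: Module) -> int:
    n = 0
    for v in vars(m).values():
        if isinstance(v, Tensor) and v.requires_grad:
            n += v.numel()
    return n


def count_params(model: Module) -> ProfileReport:
    """Parameter totals by module traversal.

    Convolutions contribute Cin/groups * Cout * K^2 (+ Cout with bias), norm
    layers 2C, and standalone scalars (fusion weights, per-level scales,
    affine shunts) their element counts; the total equals the sum over all
    learnable tensors exactly.
    """
    breakdown = []
    total = 0
    for name, m in model.named_modules():
        if isinstance(m, Conv2d):
            n = (m.cin // m.groups) * m.cout * m.k * m.k + (m.cout if m.bias is not None else 0)
        elif isinstance(m, (BatchNorm2d, GroupNorm)):
            n = 2 * m.channels
        else:
            n = _module_own_params(m)
        if n:
            breakdown.append((name or "<root>", n, 0))
            total += n
    return ProfileReport(total_params=total, total_flops=0,
                         flops_elementwise=0, breakdown=breakdown)


def count_flops(model, input_size: int = 640) -> ProfileReport:
    """FLOP totals at a fixed input size by per-layer traversal.

    One forward pass on a dummy input resolves every layer's output shape;
    each conv then contributes 2 * (Hout * Wout * Cout * Cin/groups * K^2)
    plus its bias adds, and the deformable-alignment convolution of the
    shared head contributes its equivalent gathered-1x1-conv term.
    Normalization elementwise work is reported separately.
    """
    from maizedet.head import TDADH

    was_training = getattr(model, "training", False)
    model.eval()
    profiled = [m for m in model.modules()
                if isinstance(m, (Conv2d, BatchNorm2d, GroupNorm))]
    for m in profiled:
        m._profile = []
    try:
        with no_grad():
            model(Tensor(np.zeros((1, 3, input_size, input_size), dtype=np.float32)))
        total = 0
        elementwise = 0
        breakdown = []
        for name, m in model.named_modules():
            f = 0
            if isinstance(m, Conv2d):
                if not m._profile:
                    raise RuntimeError(f"conv {name} did not run in the profiling forward")
                for cin, cout, k, hout, wout, groups in m._profile:
                    f += 2 * hout * wout * cout * (cin // groups) * k * k
                    if m.bias is not None:
                        f += cout * hout * wout
            elif isinstance(m, (BatchNorm2d, GroupNorm)):
                elementwise += 2 * sum(m._profile)
            elif isinstance(m, TDADH):
                for cin9, cout, h, w in m.last_align_shapes:
                    f += 2 * h * w * cout * cin9
            if f:
                breakdown.append((name or "<root>", 0, f))
                total += f
    finally:
        for m in profiled:
            m._profile = None
        if was_training:
            model.train()
    params = count_params(model)
    return ProfileReport(total_params=params.total_params, total_flops=total,
                         flops_elementwise=elementwise,
                         breakdown=breakdown, input_size=input_size)


def profile_model(model, input_size: int = 640) -> ProfileReport:
    """Joint parameter + FLOP profile of a built model."""
    return count_flops(model, input_size)


def measure_fps(model, images: list[np.ndarray], warmup: int = 1) -> TimingResult:
    """Mean wall-clock seconds per image (after warm-up) and FPS = 1/T."""
    from maizedet.detector import predict

    if not images:
        raise ValueError("need at least one image")
    for img in images[:warmup]:
        predict(model, img)
    t0 = time.perf_counter()
    for img in images:
        predict(model, img)
    t = (time.perf_counter() - t0) / len(images)
    hw = f"{platform.processor() or platform.machine()} / {platform.system()}"
    return TimingResult(seconds_per_image=t, fps=1.0 / t, hardware=hw)


def profile_variants(configs, input_size: int = 640, seed: int = 0):
    """Profile a list of detector configs into a comparison table.

    Returns (rows, text_table); each row carries the variant flags, params in
    millions (2 decimals), GFLOPs (1 decimal), and weight MB at 32- and
    16-bit encodings.
    """
    from maizedet.detector import build_model

    rows = []
    for cfg in configs:
        model = build_model(cfg, seed=seed)
        rep = profile_model(model, input_size)
        rows.append({
            "rep_backbone": cfg.rep_backbone, "bifpn_neck": cfg.bifpn_neck,
            "tdadh_head": cfg.tdadh_head,
            "params_m": rep.params_millions, "gflops": rep.gflops,
            "weights_mb_fp32": round(rep.weight_bytes(32) / 2**20, 1),
            "weights_mb_fp16": round(rep.weight_bytes(16) / 2**20, 1),
        })
    hdr = ["rep", "bifpn", "tdadh", "params/M", "FLOPs/G", "MB(fp32)", "MB(fp16)"]
    lines = ["  ".join(f"{h:>9}" for h in hdr)]
    for r in rows:
        lines.append("  ".join([
            f"{'x' if r['rep_backbone'] else '':>9}",
            f"{'x' if r['bifpn_neck'] else '':>9}",
            f"{'x' if r['tdadh_head'] else '':>9}",
            f"{r['params_m']:>9.2f}", f"{r['gflops']:>9.1f}",
            f"{r['weights_mb_fp32']:>9.1f}", f"{r['weights_mb_fp16']:>9.1f}"]))
    return rows, "\n".join(lines)
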