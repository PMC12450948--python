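"""Synthetic top-down maize-seedling field images with exact ground truth.

The generator emulates low-altitude UAV acquisition over a drip-irrigated
field: paired crop rows (25 cm within a pair, 50 cm between pairs at a ground
sampling distance of 0.07 cm/px at the original 5280-px frame width, preserved
as ratios on desk-size canvases), small early-stage seedlings at the
"2-leaf + 1-center" morphology with relative widths 0.02-0.07 and heights
0.02-0.10, textured soil background, and an optional weed-like distractor
population that emits no labels.

The emitted label of every seedling is the tight bounding box of its rendered
pixels, so ground truth is exact by construction. The augmentation suite
covers the offline enhancement operations (flips, quarter-turn rotation,
Gaussian and salt-and-pepper noise, brightness shifts) with exact label
equivariance for the geometric members, plus the one-representative-per-
original de-duplication rule.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from maizedet.labels_io import (
    DatasetManifest, ImageAnnotation, NormalizedBox, split_dataset,
    write_yolo_labels,
)

__all__ = [
    "FieldConfig", "AugmentationSpec", "AUGMENTATION_OPS",
    "render_field", "augment", "sample_representative", "generate_dataset",
]

# original acquisition geometry that the desk-scale canvas preserves as ratios
_SOURCE_WIDTH_PX = 5280
_SOURCE_GSD_CM = 0.07

AUGMENTATION_OPS = (
    "gaussian_noise", "salt_pepper_noise", "brightness_down", "vertical_flip",
    "horizontal_flip", "horizontal_and_vertical_flip", "rotate90",
    "brightness_up",
)


@dataclass
class FieldConfig:
    """Scene parameters of one synthetic field image."""

    image_size_px: tuple[int, int] = (640, 640)
    gsd_cm_per_px: float = _SOURCE_GSD_CM
    narrow_row_cm: float = 25.0
    wide_row_cm: float = 50.0
    plant_spacing_cm: float = 22.0
    spacing_jitter: float = 0.35
    seedling_rel_width_range: tuple[float, float] = (0.02, 0.07)
    seedling_rel_height_range: tuple[float, float] = (0.02, 0.10)
    density: int = 40
    soil_texture_params: tuple[float, float] = (0.05, 0.02)  # (blob amp, grain amp)
    distractor_rate: float = 0.0
    max_place_attempts: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.seedling_rel_width_range, self.seedling_rel_height_range):
            if not (0 < lo <= hi <= 1):
                raise ValueError("size ranges must satisfy 0 < lo <= hi <= 1")
        if min(self.narrow_row_cm, self.wide_row_cm, self.plant_spacing_cm,
               self.gsd_cm_per_px) <= 0:
            raise ValueError("physical lengths must be positive")

    def cm_to_px(self, cm: float) -> float:
        """Physical length to canvas pixels, preserving the source ratios."""
        src_px = cm / _SOURCE_GSD_CM
        return src_px / _SOURCE_WIDTH_PX * self.image_size_px[0]


@dataclass
class AugmentationSpec:
    """One enhancement operation with its parameters and seed."""

    operation: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.operation not in AUGMENTATION_OPS:
            raise ValueError(f"unknown augmentation {self.operation!r}; "
                             f"expected one of {AUGMENTATION_OPS}")


# ---------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------

def _fill_ellipse(canvas: np.ndarray, cx: float, cy: float, a: float, b: float,
                  theta: float, color: np.ndarray, rng) -> None:
    """Paint a rotated filled ellipse with slight per-pixel color jitter."""
    h, w = canvas.shape[:2]
    r = max(a, b)
    x0, x1 = max(0, int(cx - r - 1)), min(w, int(cx + r + 2))
    y0, y1 = max(0, int(cy - r - 1)), min(h, int(cy + r + 2))
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs + 0.5 - cx, ys + 0.5 - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    jitter = rng.normal(0, 0.02, size=(mask.sum(), 3))
    canvas[y0:y1, x0:x1][mask] = np.clip(color + jitter, 0, 1)


def _render_seedling(canvas: np.ndarray, cx: float, cy: float, w_px: float,
                     h_px: float, rng) -> tuple[int, int, int, int] | None:
    """Draw a 2-leaf + apical-center seedling roughly filling (w_px, h_px).

    Returns the tight bounding box (x1, y1, x2, y2) of the painted pixels.
    """
    h, w = canvas.shape[:2]
    green = np.array([0.18, 0.45, 0.12]) + rng.normal(0, 0.03, 3)
    green = np.clip(green, 0.05, 0.9)
    before = canvas.copy()
    # two leaf pairs along the box diagonals, tips exactly at the corners so
    # the tight box of painted pixels matches the sampled extent
    mirror = rng.random() < 0.5
    for k, (sx, sy) in enumerate(((1, 1), (-1, -1), (1, -1), (-1, 1))):
        if mirror:
            sx = -sx
        tipx = cx + sx * max(w_px / 2 - 1.0, 1.0)
        tipy = cy + sy * max(h_px / 2 - 1.0, 1.0)
        mx, my = (cx + tipx) / 2, (cy + tipy) / 2
        length = math.hypot(tipx - cx, tipy - cy)
        width = length * (0.22 if k < 2 else 0.18)
        _fill_ellipse(canvas, mx, my, max(length / 2, 1.0), max(width, 0.7),
                      math.atan2(tipy - cy, tipx - cx),
                      green * (1.0 if k < 2 else 0.9), rng)
    # apical center point, brighter
    _fill_ellipse(canvas, cx, cy, max(w_px * 0.12, 0.8), max(h_px * 0.12, 0.8),
                  0.0, np.clip(green * 1.5, 0, 1), rng)
    changed = np.any(canvas != before, axis=2)
    if not changed.any():
        return None
    ys, xs = np.where(changed)
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def _soil_background(shape: tuple[int, int], params, rng) -> np.ndarray:
    """Brown soil with low-frequency patchiness and high-frequency grain."""
    h, w = shape
    blob_amp, grain_amp = params
    base = np.array([0.42, 0.33, 0.24])
    coarse = rng.normal(0, 1, (h // 16 + 1, w // 16 + 1))
    coarse = np.kron(coarse, np.ones((16, 16)))[:h, :w]
    img = base[None, None, :] + blob_amp * coarse[..., None]
    img = img + rng.normal(0, grain_amp, (h, w, 3))
    return np.clip(img, 0, 1)


def _row_positions(cfg: FieldConfig, rng) -> list[float]:
    """x positions of crop rows: pairs 25 cm apart, 50 cm between pairs."""
    w = cfg.image_size_px[0]
    narrow = cfg.cm_to_px(cfg.narrow_row_cm)
    wide = cfg.cm_to_px(cfg.wide_row_cm)
    xs = []
    x = rng.uniform(0, narrow + wide)
    while x < w:
        xs.append(x)
        xs.append(x + narrow)
        x += narrow + wide
    return [v for v in xs if 0 <= v < w]


def render_field(config: FieldConfig) -> tuple[np.ndarray, ImageAnnotation]:
    """Render one field image (HWC float32 in [0,1]) with exact labels.

    Deterministic given ``config.seed``. Every rendered seedling emits exactly
    one label (the tight box of its painted pixels, normalized); distractors
    emit none. Raises if fewer than the requested density can be placed within
    the bounded per-seedling retry budget.
    """
    rng = np.random.default_rng(config.seed)
    w_img, h_img = config.image_size_px
    canvas = _soil_background((h_img, w_img), config.soil_texture_params, rng)

    rows = _row_positions(config, rng)
    spacing = config.cm_to_px(config.plant_spacing_cm)
    slots = []
    for rx in rows:
        y = rng.uniform(0, spacing)
        while y < h_img:
            jx = rng.normal(0, 0.12 * spacing)
            jy = rng.normal(0, config.spacing_jitter * spacing / 2)
            slots.append((rx + jx, y + jy))
            y += spacing
    rng.shuffle(slots)

    boxes: list[NormalizedBox] = []
    placed_centers: list[tuple[float, float]] = []
    attempts = 0
    wlo, whi = config.seedling_rel_width_range
    hlo, hhi = config.seedling_rel_height_range
    for (cx, cy) in slots:
        if len(boxes) >= config.density:
            break
        attempts += 1
        if attempts > config.density * config.max_place_attempts:
            break
        rel_w = rng.uniform(wlo, whi)
        rel_h = rng.uniform(hlo, hhi)
        w_px = rel_w * w_img
        h_px = rel_h * h_img
        margin = max(w_px, h_px) / 2 + 2
        if not (margin < cx < w_img - margin and margin < cy < h_img - margin):
            continue
        if any(abs(cx - px) < (w_px + 4) * 0.8 and abs(cy - py) < (h_px + 4) * 0.8
               for px, py in placed_centers):
            continue
        bbox = _render_seedling(canvas, cx, cy, w_px, h_px, rng)
        if bbox is None:
            continue
        x1, y1, x2, y2 = bbox
        boxes.append(NormalizedBox(
            0, cx=(x1 + x2) / 2 / w_img, cy=(y1 + y2) / 2 / h_img,
            w=(x2 - x1) / w_img, h=(y2 - y1) / h_img))
        placed_centers.append((cx, cy))
    if len(boxes) < config.density:
        raise RuntimeError(
            f"placed only {len(boxes)} of {config.density} seedlings "
            f"within the retry budget; reduce density or jitter")
    # unlabeled weed-like distractors
    n_distract = rng.poisson(config.distractor_rate * config.density) \
        if config.distractor_rate > 0 else 0
    for _ in range(n_distract):
        dx, dy = rng.uniform(0, w_img), rng.uniform(0, h_img)
        col = np.clip(np.array([0.25, 0.38, 0.18]) + rng.normal(0, 0.05, 3), 0, 1)
        _fill_ellipse(canvas, dx, dy, rng.uniform(1, 4), rng.uniform(1, 4),
                      rng.uniform(0, math.pi), col, rng)
    ann = ImageAnnotation(f"field_{config.seed}", w_img, h_img, boxes)
    return canvas.astype(np.float32), ann


# ---------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------

def _flip_box_h(b: NormalizedBox) -> NormalizedBox:
    return NormalizedBox(b.class_id, 1.0 - b.cx, b.cy, b.w, b.h)


def _flip_box_v(b: NormalizedBox) -> NormalizedBox:
    return NormalizedBox(b.class_id, b.cx, 1.0 - b.cy, b.w, b.h)


def _rot90_box(b: NormalizedBox) -> NormalizedBox:
    # one quarter-turn: (cx, cy, w, h) -> (cy, 1-cx, h, w)
    return NormalizedBox(b.class_id, b.cy, 1.0 - b.cx, b.h, b.w)


def augment(image: np.ndarray, ann: ImageAnnotation,
            spec: AugmentationSpec) -> tuple[np.ndarray, ImageAnnotation]:
    """Apply one enhancement operation; geometric ops transform labels exactly,
    photometric ops leave them unchanged. Instance count is preserved."""
    rng = np.random.default_rng(spec.seed)
    op = spec.operation
    img = image
    boxes = ann.instances
    if op == "gaussian_noise":
        sigma = spec.params.get("sigma", 10 / 255)
        img = np.clip(image + rng.normal(0, sigma, image.shape), 0, 1).astype(np.float32)
    elif op == "salt_pepper_noise":
        rate = spec.params.get("rate", 0.02)
        img = image.copy()
        flip = rng.random(image.shape[:2]) < rate
        salt = rng.random(image.shape[:2]) < 0.5
        img[flip & salt] = 1.0
        img[flip & ~salt] = 0.0
    elif op == "brightness_down":
        f = spec.params.get("factor", 0.75)
        img = np.clip(image * f, 0, 1).astype(np.float32)
    elif op == "brightness_up":
        f = spec.params.get("factor", 1.25)
        img = np.clip(image * f, 0, 1).astype(np.float32)
    elif op == "horizontal_flip":
        img = image[:, ::-1].copy()
        boxes = [_flip_box_h(b) for b in boxes]
    elif op == "vertical_flip":
        img = image[::-1].copy()
        boxes = [_flip_box_v(b) for b in boxes]
    elif op == "horizontal_and_vertical_flip":
        img = image[::-1, ::-1].copy()
        boxes = [_flip_box_v(_flip_box_h(b)) for b in boxes]
    elif op == "rotate90":
        # quarter-turn consistent with (cx, cy, w, h) -> (cy, 1 - cx, h, w)
        img = np.rot90(image, k=1).copy()
        boxes = [_rot90_box(b) for b in boxes]
    else:  # pragma: no cover - guarded by AugmentationSpec
        raise ValueError(f"unknown operation {op!r}")
    out_h, out_w = img.shape[:2]
    return img, ImageAnnotation(ann.image_id, out_w, out_h, list(boxes))


def sample_representative(original_id: str, variants: list, seed: int = 0):
    """Uniformly pick one image among an original and its augmented variants.

    Deterministic given (original_id, seed); every original keeps exactly one
    representative, which avoids duplicated augmented copies of the same scene.
    """
    if not variants:
        raise ValueError("variant list must be non-empty")
    key = zlib.crc32(original_id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng([seed, key])
    return variants[int(rng.integers(len(variants)))]


# ---------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------

def generate_dataset(config: FieldConfig, n_originals: int, out_dir: str | Path,
                     seed: int = 0,
                     ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
                     ) -> DatasetManifest:
    """Render, augment, de-duplicate, split and write a dataset to disk.

    Layout: ``images/{split}/*.png``, ``labels/{split}/*.txt`` plus a
    ``manifest.yaml`` recording the config and every seed used. Regeneration
    with the same seed is byte-identical for label files.
    """
    from PIL import Image
    import yaml

    out = Path(out_dir)
    rng = np.random.default_rng(seed)
    ids = [f"img_{i:04d}" for i in range(n_originals)]
    manifest = split_dataset(ids, ratios, seed=seed)
    for split in ("train", "val", "test"):
        (out / "images" / split).mkdir(parents=True, exist_ok=True)
        (out / "labels" / split).mkdir(parents=True, exist_ok=True)
    gen_log = []
    for i, image_id in enumerate(ids):
        scene_seed = int(rng.integers(2 ** 31))
        cfg_i = FieldConfig(**{**asdict(config), "seed": scene_seed})
        img, ann = render_field(cfg_i)
        candidates = [(img, ann, "original")]
        for j, op in enumerate(AUGMENTATION_OPS):
            aug_seed = int(rng.integers(2 ** 31))
            aimg, aann = augment(img, ann, AugmentationSpec(op, seed=aug_seed))
            candidates.append((aimg, aann, op))
        chosen = sample_representative(image_id, candidates, seed=seed)
        cimg, cann, cop = chosen
        split = manifest.assignment[image_id]
        Image.fromarray((cimg * 255).astype(np.uint8)).save(
            out / "images" / split / f"{image_id}.png")
        cann.image_id = image_id
        write_yolo_labels(cann, out / "labels" / split / f"{image_id}.txt")
        gen_log.append({"id": image_id, "scene_seed": scene_seed,
                        "kept": cop, "split": split, "instances": len(cann)})
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump({
            "seed": seed, "ratios": list(manifest.ratios),
            "config": asdict(config), "images": gen_log,
        }, fh, sort_keys=False)
    return manifest
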