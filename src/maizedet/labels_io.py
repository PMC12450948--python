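"""Normalized box geometry and YOLO-format plain-text annotation I/O.

The YOLO label dialect is one line per object instance::

    class_id cx cy w h

with center/extent expressed as fractions of image width and height. This is
the exchange unit between the synthetic generator, the detector, and the
evaluation code. Out-of-range coordinates are rejected on read rather than
clipped, so corrupt label files surface immediately.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "NormalizedBox",
    "Detection",
    "ImageAnnotation",
    "DatasetManifest",
    "LabelParseError",
    "LabelValidationError",
    "read_yolo_labels",
    "write_yolo_labels",
    "to_pixel_corners",
    "relative_size_to_pixels",
    "iou",
    "split_dataset",
]

SPLITS = ("train", "val", "test")


class LabelParseError(ValueError):
    """A label line could not be parsed as `class cx cy w h`."""


class LabelValidationError(ValueError):
    """A parsed value violates the normalized-box invariants."""


@dataclass(frozen=True)
class NormalizedBox:
    """Axis-aligned box in normalized image coordinates (YOLO convention).

    ``cx, cy`` are the box center and ``w, h`` the box extent, all as
    fractions of image width/height in [0, 1]; ``w`` and ``h`` must be
    strictly positive.
    """

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.class_id < 0 or int(self.class_id) != self.class_id:
            raise LabelValidationError(f"class_id must be a non-negative integer, got {self.class_id}")
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise LabelValidationError(f"{name}={v} outside [0, 1]")
        if self.w <= 0 or self.h <= 0:
            raise LabelValidationError(f"degenerate box extent w={self.w}, h={self.h}")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) in normalized coordinates, unclipped."""
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class Detection:
    """A predicted box with a confidence score in [0, 1]."""

    box: NormalizedBox
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise LabelValidationError(f"confidence={self.confidence} outside [0, 1]")


@dataclass
class ImageAnnotation:
    """Ground truth for one image: its pixel size and an ordered instance list."""

    image_id: str
    width_px: int
    height_px: int
    instances: list[NormalizedBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise LabelValidationError("image dimensions must be positive")

    def __len__(self) -> int:
        return len(self.instances)


@dataclass
class DatasetManifest:
    """Assignment of image ids to train/val/test splits.

    Splits are disjoint, cover every id, and realized sizes follow
    largest-remainder apportionment of the requested ratios.
    """

    assignment: dict[str, str]
    ratios: tuple[float, float, float]
    seed: int

    def ids(self, split: str) -> list[str]:
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        return [i for i, s in self.assignment.items() if s == split]

    def counts(self) -> dict[str, int]:
        c = {s: 0 for s in SPLITS}
        for s in self.assignment.values():
            c[s] += 1
        return c


def read_yolo_labels(path: str | Path, image_size: tuple[int, int],
                     image_id: str | None = None) -> ImageAnnotation:
    """Read a YOLO-format label file into an :class:`ImageAnnotation`.

    Parameters
    ----------
    path:
        Label file location; must exist.
    image_size:
        ``(width_px, height_px)`` of the paired image.
    image_id:
        Identifier for the annotation; defaults to the file stem.

    Raises
    ------
    LabelParseError
        If a non-empty line does not have exactly 5 numeric fields
        (the message names the 1-based line number).
    LabelValidationError
        If any coordinate falls outside [0, 1]; values are never clipped.
    """
    path = Path(path)
    width_px, height_px = image_size
    boxes: list[NormalizedBox] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise LabelParseError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        try:
            cls = int(float(parts[0]))
            cx, cy, w, h = (float(p) for p in parts[1:])
        except ValueError as exc:
            raise LabelParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        try:
            boxes.append(NormalizedBox(cls, cx, cy, w, h))
        except LabelValidationError as exc:
            raise LabelValidationError(f"{path}:{lineno}: {exc}") from None
    return ImageAnnotation(image_id or path.stem, width_px, height_px, boxes)


def write_yolo_labels(ann: ImageAnnotation, path: str | Path, precision: int = 6) -> None:
    """Write an annotation as a YOLO label file, one instance per line.

    Coordinates are written with ``precision`` decimal places (default 6);
    an annotation with zero instances produces an empty file.
    """
    path = Path(path)
    lines = [
        f"{b.class_id} {b.cx:.{precision}f} {b.cy:.{precision}f} "
        f"{b.w:.{precision}f} {b.h:.{precision}f}"
        for b in ann.instances
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def to_pixel_corners(box: NormalizedBox, width_px: int, height_px: int,
                     clip: bool = True) -> tuple[float, float, float, float]:
    """Convert a normalized box to (x1, y1, x2, y2) pixel corners.

    Origin is the top-left corner, x rightward, y downward; the pixel box is
    half-open ``[x1, x2) x [y1, y2)`` in continuous coordinates. With
    ``clip=True`` corners are clipped to the image bounds.
    """
    x1 = (box.cx - box.w / 2) * width_px
    y1 = (box.cy - box.h / 2) * height_px
    x2 = (box.cx + box.w / 2) * width_px
    y2 = (box.cy + box.h / 2) * height_px
    if clip:
        x1, x2 = max(0.0, x1), min(float(width_px), x2)
        y1, y2 = max(0.0, y1), min(float(height_px), y2)
    return (x1, y1, x2, y2)


def from_pixel_corners(class_id: int, corners: Sequence[float],
                       width_px: int, height_px: int) -> NormalizedBox:
    """Inverse of :func:`to_pixel_corners` for unclipped corner boxes."""
    x1, y1, x2, y2 = corners
    return NormalizedBox(
        class_id,
        cx=(x1 + x2) / 2 / width_px,
        cy=(y1 + y2) / 2 / height_px,
        w=(x2 - x1) / width_px,
        h=(y2 - y1) / height_px,
    )


def relative_size_to_pixels(rel: float, dim_px: int) -> int:
    """Convert a relative extent to a pixel extent with round-half-up.

    Round-half-up (not banker's rounding) so e.g. a relative width of 0.02 on
    a 5280 px image gives 105.6 -> 106 px.
    """
    if not (0.0 <= rel <= 1.0):
        raise LabelValidationError(f"relative size {rel} outside [0, 1]")
    if dim_px <= 0:
        raise LabelValidationError("dim_px must be positive")
    return int(math.floor(rel * dim_px + 0.5))


def iou(a: NormalizedBox, b: NormalizedBox) -> float:
    """Intersection-over-union of two normalized boxes (corner-space)."""
    ax1, ay1, ax2, ay2 = a.corners
    bx1, by1, bx2, by2 = b.corners
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.area() + b.area() - inter
    return inter / union


def split_dataset(ids: Iterable[str], ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
                  seed: int = 0) -> DatasetManifest:
    """Partition image ids into train/val/test splits.

    Ids are shuffled with the given seed and apportioned by the
    largest-remainder method, so realized counts are within one image of the
    exact ratios for any n. Deterministic given (ids, ratios, seed).
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate image ids")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if len(ids) < len(SPLITS):
        raise ValueError(f"need at least {len(SPLITS)} ids, got {len(ids)}")
    total = sum(ratios)
    fracs = [r / total for r in ratios]
    n = len(ids)
    quotas = [f * n for f in fracs]
    counts = [int(math.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    # distribute leftover to the largest remainders (ties: earlier split wins)
    for idx in sorted(range(len(SPLITS)), key=lambda i: (-remainders[i], i))[: n - sum(counts)]:
        counts[idx] += 1
    rng = random.Random(seed)
    shuffled = ids.copy()
    rng.shuffle(shuffled)
    assignment: dict[str, str] = {}
    start = 0
    for split, c in zip(SPLITS, counts):
        for i in shuffled[start:start + c]:
            assignment[i] = split
        start += c
    return DatasetManifest(assignment=assignment, ratios=tuple(fracs), seed=seed)
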