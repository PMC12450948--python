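"""In-memory detection datasets: loading generated directories or rendering
synthetic splits directly."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from maizedet.labels_io import ImageAnnotation, read_yolo_labels, split_dataset
from maizedet.synthetic_field import FieldConfig, render_field

__all__ = ["DetectionDataset"]


@dataclass
class DetectionDataset:
    """Images (HWC float32 in [0,1]) and annotations per split."""

    train_images: list = field(default_factory=list)
    train_annotations: list = field(default_factory=list)
    val_images: list = field(default_factory=list)
    val_annotations: list = field(default_factory=list)
    test_images: list = field(default_factory=list)
    test_annotations: list = field(default_factory=list)

    @classmethod
    def from_dir(cls, root: str | Path) -> "DetectionDataset":
        """Load an `images/{split}`, `labels/{split}` directory layout."""
        from PIL import Image

        root = Path(root)
        ds = cls()
        for split in ("train", "val", "test"):
            img_dir = root / "images" / split
            if not img_dir.is_dir():
                continue
            for f in sorted(img_dir.iterdir()):
                if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                    continue
                img = np.asarray(Image.open(f).convert("RGB"), dtype=np.float32) / 255.0
                lbl = root / "labels" / split / (f.stem + ".txt")
                ann = read_yolo_labels(lbl, (img.shape[1], img.shape[0])) \
                    if lbl.exists() else ImageAnnotation(f.stem, img.shape[1], img.shape[0])
                getattr(ds, f"{split}_images").append(img)
                getattr(ds, f"{split}_annotations").append(ann)
        return ds

    @classmethod
    def synthetic(cls, config: FieldConfig, n: int, seed: int = 0,
                  ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
                  ) -> "DetectionDataset":
        """Render n scenes in memory and split them."""
        rng = np.random.default_rng(seed)
        ids = [f"img_{i:04d}" for i in range(n)]
        manifest = split_dataset(ids, ratios, seed=seed)
        ds = cls()
        for image_id in ids:
            scene_seed = int(rng.integers(2 ** 31))
            img, ann = render_field(FieldConfig(**{**asdict(config), "seed": scene_seed}))
            ann.image_id = image_id
            split = manifest.assignment[image_id]
            getattr(ds, f"{split}_images").append(img)
            getattr(ds, f"{split}_annotations").append(ann)
        return ds
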