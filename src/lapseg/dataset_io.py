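"""Reading CholecSeg8k-style datasets: mask decoding, leakage-free
case-wise splits, mask-derived bounding boxes and class pixel counts.

A dataset root contains one directory per surgical video; each frame is
an RGB PNG accompanied by a single-channel annotation mask PNG
(``<frame>_mask.png`` or the CholecSeg8k ``<frame>_endo_mask.png``
naming, possibly nested one level deeper as in the original release).
Segmentation masks are plain ``H x W`` integer arrays of contiguous
class ids; the raw-code-to-id mapping is a shipped, editable YAML file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from skimage.measure import label as cc_label
from skimage.measure import regionprops


# ---------------------------------------------------------------------------
# class map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassMap:
    """Mapping between raw mask pixel codes and contiguous class ids."""

    raw_values: tuple    # raw pixel code per entry
    class_ids: tuple     # contiguous id per entry
    class_names: tuple

    def __post_init__(self):
        k = len(self.class_ids)
        if len(set(self.raw_values)) != k:
            raise ValueError("raw mask values must be unique")
        if sorted(self.class_ids) != list(range(k)):
            raise ValueError("class ids must be contiguous 0..K-1")

    @property
    def num_classes(self) -> int:
        return len(self.class_ids)

    @property
    def lut(self) -> np.ndarray:
        """256-entry lookup table; -1 marks unknown raw values."""
        t = np.full(256, -1, dtype=np.int16)
        for v, c in zip(self.raw_values, self.class_ids):
            t[v] = c
        return t

    def name_of(self, class_id: int) -> str:
        return self.class_names[self.class_ids.index(class_id)]

    @classmethod
    def from_yaml(cls, path) -> "ClassMap":
        with open(path) as f:
            doc = yaml.safe_load(f)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: dict) -> "ClassMap":
        entries = doc["classes"]
        bg = [e for e in entries if e.get("background")]
        if len(bg) != 1 or bg[0]["id"] != 0:
            raise ValueError("exactly one class must be background with id 0")
        return cls(
            raw_values=tuple(int(e["value"]) for e in entries),
            class_ids=tuple(int(e["id"]) for e in entries),
            class_names=tuple(str(e["name"]) for e in entries),
        )

    @classmethod
    def cholecseg8k(cls) -> "ClassMap":
        """The shipped 13-class CholecSeg8k map."""
        ref = importlib.resources.files("lapseg.data") / "cholecseg8k_classes.yaml"
        return cls._from_doc(yaml.safe_load(ref.read_text()))

    @classmethod
    def identity(cls, k: int) -> "ClassMap":
        """Raw value == class id, as written by the synthetic generator."""
        names = ("background",) + tuple(f"class_{i}" for i in range(1, k))
        return cls(tuple(range(k)), tuple(range(k)), names)


def decode_annotation_mask(mask_image: np.ndarray, class_map: ClassMap) -> np.ndarray:
    """Map raw annotation-mask pixel codes to contiguous class ids."""
    m = np.asarray(mask_image)
    if m.ndim == 3:  # some tools save single-channel masks as RGB
        m = m[..., 0]
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    labels = class_map.lut[m]
    if (labels < 0).any():
        ij = np.argwhere(labels < 0)[0]
        bad = int(m[tuple(ij)])
        raise ValueError(
            f"unknown mask value {bad} at pixel (row={ij[0]}, col={ij[1]})"
        )
    return labels.astype(np.int64)


# ---------------------------------------------------------------------------
# records and splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class FrameRecord:
    video_id: str
    frame_id: str
    image_path: Path
    mask_path: Path


@dataclass
class DatasetSplit:
    train: list = field(default_factory=list)
    val: list = field(default_factory=list)
    test: list = field(default_factory=list)

    def sizes(self) -> tuple:
        return (len(self.train), len(self.val), len(self.test))


_MASK_SUFFIXES = ("_endo_mask.png", "_mask.png")
_EXCLUDE = ("_color_mask", "_watershed_mask")


def scan_dataset(root) -> list[FrameRecord]:
    """Collect frame records; the top-level directory names the video.

    Only annotation masks are used; color and watershed masks are
    ignored. Records are sorted by (video_id, frame_id) so downstream
    splits are reproducible.
    """
    root = Path(root)
    records = []
    for p in root.rglob("*.png"):
        name = p.name
        if any(tag in name for tag in _EXCLUDE):
            continue
        suffix = next((s for s in _MASK_SUFFIXES if name.endswith(s)), None)
        if suffix is None:
            continue
        stem = name[: -len(suffix)]
        img = p.with_name(stem + ("_endo.png" if suffix == "_endo_mask.png" else ".png"))
        if not img.exists():
            raise FileNotFoundError(f"no image for mask {p}")
        video_id = p.relative_to(root).parts[0]
        records.append(FrameRecord(video_id, stem, img, p))
    records.sort(key=lambda r: (r.video_id, r.frame_id))
    return records


def split_by_video(records: list, split_spec: dict) -> DatasetSplit:
    """Assign every record to exactly one subset by its video id.

    `split_spec` maps 'train'/'val'/'test' to lists of video ids. Frames
    from one video never cross subsets, preventing leakage between
    surgical cases.
    """
    subsets = {k: list(split_spec.get(k, [])) for k in ("train", "val", "test")}
    assign: dict[str, str] = {}
    for subset, vids in subsets.items():
        for v in vids:
            if v in assign:
                raise ValueError(f"video {v!r} assigned to both {assign[v]} and {subset}")
            assign[v] = subset
    out = DatasetSplit()
    for r in records:
        if r.video_id not in assign:
            raise ValueError(f"video {r.video_id!r} not assigned to any subset")
        getattr(out, assign[r.video_id]).append(r)
    return out


def split_manifest(split: DatasetSplit) -> pd.DataFrame:
    rows = [
        {"video_id": r.video_id, "frame_id": r.frame_id, "subset": subset}
        for subset in ("train", "val", "test")
        for r in getattr(split, subset)
    ]
    return pd.DataFrame(rows, columns=["video_id", "frame_id", "subset"])


# The case-wise assignment used for CholecSeg8k: 15 training videos,
# one validation video and one held-out test video.
CHOLECSEG8K_SPLIT = {
    "train": ["video01", "video09", "video12", "video17", "video18", "video20",
              "video24", "video25", "video26", "video27", "video28", "video35",
              "video37", "video48", "video52"],
    "val": ["video43"],
    "test": ["video55"],
}


# ---------------------------------------------------------------------------
# boxes and counts
# ---------------------------------------------------------------------------

def boxes_from_mask(mask: np.ndarray, min_area: int = 16) -> list:
    """Tight axis-aligned boxes around 8-connected components of every
    non-background class.

    Returns (class_id, x_center, y_center, w, h) tuples in normalized
    [0, 1] image coordinates. Components smaller than `min_area` pixels
    are treated as annotation specks and dropped.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    mask = np.asarray(mask)
    h, w = mask.shape
    boxes = []
    for k in np.unique(mask):
        if k == 0:
            continue
        comp = cc_label(mask == k, connectivity=2)
        for region in regionprops(comp):
            if region.area < min_area:
                continue
            r0, c0, r1, c1 = region.bbox  # half-open
            boxes.append((
                int(k),
                (c0 + c1) / 2.0 / w,
                (r0 + r1) / 2.0 / h,
                (c1 - c0) / w,
                (r1 - r0) / h,
            ))
    return boxes


def load_image(path) -> np.ndarray:
    """RGB image as float32 in [0, 1], shape (H, W, 3)."""
    img = np.asarray(Image.open(path).convert("RGB"), dtype=np.float32) / 255.0
    return img


def load_mask(path, class_map: ClassMap) -> np.ndarray:
    return decode_annotation_mask(np.asarray(Image.open(path)), class_map)


def class_pixel_counts(records: list, class_map: ClassMap) -> np.ndarray:
    """Per-class pixel counts N_k over a list of frame records."""
    counts = np.zeros(class_map.num_classes, dtype=np.int64)
    for r in records:
        counts += class_pixel_counts_from_masks(
            [load_mask(r.mask_path, class_map)], class_map.num_classes
        )
    return counts


def class_pixel_counts_from_masks(masks, num_classes: int) -> np.ndarray:
    counts = np.zeros(num_classes, dtype=np.int64)
    for m in masks:
        counts += np.bincount(np.asarray(m).ravel(), minlength=num_classes)[:num_classes]
    return counts
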