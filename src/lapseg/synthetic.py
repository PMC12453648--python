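"""Seeded synthetic laparoscopic-like scenes.

The generator reproduces the statistical structure the segmentation
method targets rather than photorealism: one dominant organ-like region
(the "liver"), a small minority region abutting it (the "gallbladder"),
and thin instrument-like occluders drawn last so they cut through the
organs — the geometry that makes class balance and occlusion handling
hard in real surgical frames.

Scenes are deterministic given (seed, index): each scene draws from an
independent stream keyed by ``seed ^ index`` so any scene can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

SHAPE_FAMILIES = ("large_blob", "small_blob", "thin_occluder")

# Muted per-class base colors (background + up to 6 foreground classes);
# loosely organ-like but purely cosmetic.
_PALETTE = np.array([
    [0.10, 0.08, 0.09],  # background: dark cavity
    [0.55, 0.22, 0.18],  # large organ: liver-like red-brown
    [0.50, 0.30, 0.20],  # minority organ: liver-toned with a green cast,
                         # as a partly obscured gallbladder appears — kept
                         # close to the dominant class so rarity, not
                         # color, is what makes it hard
    [0.72, 0.72, 0.76],  # instrument: metallic grey
    [0.80, 0.65, 0.40],  # fat-like yellow
    [0.60, 0.35, 0.50],  # tissue pink
    [0.35, 0.45, 0.65],  # blue drape
], dtype=np.float32)


@dataclass(frozen=True)
class ClassSpec:
    class_id: int
    shape_family: str
    target_frequency: float
    count_range: tuple = (1, 1)

    def __post_init__(self):
        if self.shape_family not in SHAPE_FAMILIES:
            raise ValueError(f"unknown shape family {self.shape_family!r}")
        if not 0 < self.target_frequency < 1:
            raise ValueError("target_frequency must be in (0, 1)")
        if self.class_id <= 0:
            raise ValueError("class_id 0 is reserved for background")


@dataclass(frozen=True)
class SceneSpec:
    """Study conditions for a synthetic dataset.

    Defaults encode the imbalance regime of interest: a dominant region
    at 35% of pixels, a minority region at 2%, occluders at 5%, the
    rest background.
    """

    height: int = 64
    width: int = 64
    classes: tuple = (
        ClassSpec(1, "large_blob", 0.35),
        ClassSpec(2, "small_blob", 0.02),
        ClassSpec(3, "thin_occluder", 0.05, (1, 2)),
    )
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.height < 32 or self.width < 32:
            raise ValueError("scene must be at least 32x32")
        total = sum(c.target_frequency for c in self.classes)
        if total >= 1.0:
            raise ValueError(f"target frequencies sum to {total:.3f} >= 1")
        ids = [c.class_id for c in self.classes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate class ids")

    @property
    def num_classes(self) -> int:
        return 1 + max((c.class_id for c in self.classes), default=0)


def _blob_mask(rng, h, w, area, center=None) -> tuple:
    """Perturbed-ellipse mask of roughly `area` pixels; returns (mask, center)."""
    r0 = np.sqrt(area / np.pi)
    if r0 > 0.45 * min(h, w):
        raise ValueError(
            f"shape of area {area:.0f}px cannot fit in a {h}x{w} scene"
        )
    if center is None:
        cy = rng.uniform(0.35, 0.65) * h
        cx = rng.uniform(0.35, 0.65) * w
    else:
        cy, cx = center
    ratio = rng.uniform(0.75, 1.35)
    ry, rx = r0 * np.sqrt(ratio), r0 / np.sqrt(ratio)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = (yy - cy) / ry, (xx - cx) / rx
    rad = np.sqrt(dy * dy + dx * dx)
    theta = np.arctan2(dy, dx)
    wobble = np.zeros_like(theta)
    for m in (2, 3, 4):
        wobble += rng.uniform(0.0, 0.12) * np.cos(m * theta + rng.uniform(0, 2 * np.pi))
    return rad <= 1.0 + wobble, (cy, cx)


def _occluder_mask(rng, h, w, area) -> np.ndarray:
    """Thin rotated bar of width 2-5 px spanning the scene."""
    thickness = rng.integers(2, 6)
    length = min(np.hypot(h, w), area / thickness)
    cy, cx = rng.uniform(0.25, 0.75) * h, rng.uniform(0.25, 0.75) * w
    ang = rng.uniform(0, np.pi)
    uy, ux = np.sin(ang), np.cos(ang)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    along = dy * uy + dx * ux
    across = -dy * ux + dx * uy
    return (np.abs(along) <= length / 2) & (np.abs(across) <= thickness / 2)


def _smooth_field(rng, h, w, coarse: int = 8, amp: float = 0.08) -> np.ndarray:
    """Low-frequency texture: coarse noise bilinearly enlarged."""
    g = rng.normal(0.0, 1.0, (coarse, coarse))
    img = np.asarray(
        Image.fromarray(g.astype(np.float32), mode="F").resize((w, h), Image.BILINEAR)
    )
    return amp * img


def generate_scene(spec: SceneSpec, index: int) -> tuple:
    """One (image, mask) pair; image in [0,1]^(H,W,3), mask of class ids.

    Occluders are painted last so they overwrite organ pixels, the way
    instruments occlude tissue; the minority blob is seeded on the
    dominant blob's boundary, the way the gallbladder abuts the liver.
    """
    rng = np.random.default_rng(spec.seed ^ index)
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=np.int64)

    order = {"large_blob": 0, "small_blob": 1, "thin_occluder": 2}
    classes = sorted(spec.classes, key=lambda c: order[c.shape_family])
    anchor = None  # boundary anchor from the most recent large blob
    for cs in classes:
        n = int(rng.integers(cs.count_range[0], cs.count_range[1] + 1))
        area_each = cs.target_frequency * h * w / n
        for _ in range(n):
            if cs.shape_family == "thin_occluder":
                m = _occluder_mask(rng, h, w, area_each)
            elif cs.shape_family == "small_blob" and anchor is not None:
                cy, cx, ry, rx = anchor
                ang = rng.uniform(0, 2 * np.pi)
                center = (cy + ry * np.sin(ang), cx + rx * np.cos(ang))
                center = (np.clip(center[0], 2, h - 3), np.clip(center[1], 2, w - 3))
                m, _ = _blob_mask(rng, h, w, area_each, center=center)
            else:
                m, (cy, cx) = _blob_mask(rng, h, w, area_each)
                if cs.shape_family == "large_blob":
                    r0 = np.sqrt(area_each / np.pi)
                    anchor = (cy, cx, r0, r0)
            mask[m] = cs.class_id

    colors = _PALETTE[np.minimum(mask, len(_PALETTE) - 1)]
    texture = _smooth_field(rng, h, w)[..., None]
    noise = rng.normal(0.0, spec.noise_sigma, (h, w, 3))
    image = np.clip(colors + texture + noise, 0.0, 1.0).astype(np.float32)
    return image, mask


def generate_dataset(spec: SceneSpec, n: int) -> list:
    """Scenes with indices 0..n-1, reproducible from spec.seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_scene(spec, i) for i in range(n)]


@dataclass
class SyntheticDataset:
    """In-memory dataset with the (image, mask) list interface used by
    training and evaluation."""

    scenes: list = field(default_factory=list)

    def __len__(self):
        return len(self.scenes)

    def __getitem__(self, i):
        return self.scenes[i]


def save_dataset(scenes, out_dir, video_id: str = "video00"):
    """Write PNG image/mask pairs in the layout `dataset_io.scan_dataset`
    reads; mask pixel codes equal class ids (identity class map)."""
    out = Path(out_dir) / video_id
    out.mkdir(parents=True, exist_ok=True)
    for i, (img, mask) in enumerate(scenes):
        stem = f"frame_{i:06d}"
        Image.fromarray((img * 255).astype(np.uint8)).save(out / f"{stem}.png")
        Image.fromarray(mask.astype(np.uint8)).save(out / f"{stem}_mask.png")


def spec_from_yaml(path) -> SceneSpec:
    import yaml

    with open(path) as f:
        doc = yaml.safe_load(f)
    classes = tuple(
        ClassSpec(
            int(c["class_id"]), c["shape_family"], float(c["target_frequency"]),
            tuple(c.get("count_range", (1, 1))),
        )
        for c in doc.get("classes", [])
    ) or SceneSpec().classes
    return SceneSpec(
        height=int(doc.get("height", 64)),
        width=int(doc.get("width", 64)),
        classes=classes,
        noise_sigma=float(doc.get("noise_sigma", 0.03)),
        seed=int(doc.get("seed", 0)),
    )
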