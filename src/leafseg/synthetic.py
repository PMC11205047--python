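"""Seeded generator of synthetic top-down rosette images with instance truth.

Emulates the geometry of top-down Arabidopsis/tobacco rosette photographs:
5–30 overlapping elliptical-to-teardrop leaves arranged at golden-angle
increments around a common centre, rendered in a green hue band over a
textured soil-like (or flat) background, optionally defocus-blurred.  Every
scene carries its exact instance label map (topmost leaf owns contested
pixels), so all downstream components are testable without any dataset
download.

Not modelled: venation, specular highlights, perspective, moss/water-tray
clutter.  Statistical resemblance suffices for exercising the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb
from skimage.draw import polygon as draw_polygon

from . import masks_io

__all__ = ["RosetteConfig", "RosetteScene", "generate_rosette", "generate_dataset"]

GOLDEN_ANGLE = np.deg2rad(137.50776)


@dataclass
class RosetteConfig:
    """Parameters of the rosette scene distribution.

    Lengths are in pixels; ``None`` scales a default with the image size.
    """

    size: int = 512
    k_min: int = 5
    k_max: int = 30
    leaf_length: tuple[float, float] | None = None  # uniform range, px
    leaf_aspect: tuple[float, float] = (0.35, 0.6)  # width as fraction of length
    angle_jitter_deg: float = 12.0  # phyllotaxis angle jitter (std, degrees)
    center_offset: float | None = None  # leaf-base offset spread, px
    hue_range: tuple[float, float] = (0.20, 0.38)  # green band of the HSV wheel
    background: str = "soil"  # "soil" (textured) or "flat"
    blur_sigma: tuple[float, float] = (0.0, 1.2)
    seed: int = 0

    def __post_init__(self):
        if self.k_min < 0 or self.k_max < self.k_min:
            raise ValueError("need 0 <= k_min <= k_max")
        if self.size < 64:
            raise ValueError("image size must be >= 64")
        if self.background not in ("soil", "flat"):
            raise ValueError(f"unknown background {self.background!r}")
        if self.leaf_length is None:
            self.leaf_length = (0.16 * self.size, 0.34 * self.size)
        if self.center_offset is None:
            self.center_offset = 0.03 * self.size


@dataclass
class RosetteScene:
    """A rendered rosette: leaf outlines in painter's order plus ground truth."""

    leaves: list[np.ndarray]  # per-leaf polygon, (n, 2) pixel (row, col), painter order
    image: np.ndarray  # (H, W, 3) uint8
    labels: np.ndarray  # (H, W) int32 instance map, ids 1..K' contiguous


def _leaf_polygon(base: np.ndarray, angle: float, length: float, width: float,
                  n_pts: int = 40) -> np.ndarray:
    """Teardrop outline: ellipse tapered by a sine envelope, pointed at the tip."""
    u = np.linspace(0.0, 1.0, n_pts)
    half_w = 0.5 * width * np.sin(np.pi * np.clip(u, 0, 1) ** 0.85) ** 0.9
    top = np.stack([u * length, half_w], axis=1)
    bottom = np.stack([u[::-1] * length, -half_w[::-1]], axis=1)
    pts = np.concatenate([top, bottom], axis=0)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return pts @ rot.T + base  # (row, col)


def generate_rosette(cfg: RosetteConfig, rng: np.random.Generator | None = None) -> RosetteScene:
    """Generate one seeded rosette scene.

    Leaves are placed at golden-angle increments with jitter and drawn
    back-to-front in a randomised painter's order; fully occluded leaves are
    removed and ids compacted to 1..K'.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    size = cfg.size
    center = np.array([size / 2.0, size / 2.0])

    k = int(rng.integers(cfg.k_min, cfg.k_max + 1))
    polys = []
    for i in range(k):
        angle = i * GOLDEN_ANGLE + np.deg2rad(rng.normal(0.0, cfg.angle_jitter_deg))
        length = rng.uniform(*cfg.leaf_length)
        width = length * rng.uniform(*cfg.leaf_aspect)
        base = center + rng.normal(0.0, cfg.center_offset, size=2)
        polys.append(_leaf_polygon(base, angle, length, width))

    order = rng.permutation(k)  # painter's order decoupled from phyllotaxis order
    labels = np.zeros((size, size), dtype=np.int32)
    hues = rng.uniform(*cfg.hue_range, size=k)
    sats = rng.uniform(0.45, 0.85, size=k)
    vals = rng.uniform(0.35, 0.75, size=k)

    img = _background(cfg, rng)
    painter_polys = []
    for paint_rank, idx in enumerate(order, start=1):
        poly = polys[idx]
        rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=labels.shape)
        labels[rr, cc] = paint_rank
        color = hsv2rgb(np.array([[[hues[idx], sats[idx], vals[idx]]]]))[0, 0]
        shade = 1.0 + 0.08 * rng.standard_normal(rr.size)
        img[rr, cc] = np.clip(color[None, :] * shade[:, None], 0, 1)
        painter_polys.append(poly)

    # drop fully occluded leaves, compact ids to 1..K'
    present = np.unique(labels)
    present = present[present > 0]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[present] = np.arange(1, present.size + 1, dtype=np.int32)
    labels = remap[labels]
    kept = [painter_polys[p - 1] for p in present]

    sigma = rng.uniform(*cfg.blur_sigma)
    if sigma > 0:
        img = gaussian_filter(img, sigma=(sigma, sigma, 0))
    image = np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)
    return RosetteScene(leaves=kept, image=image, labels=labels)


def _background(cfg: RosetteConfig, rng: np.random.Generator) -> np.ndarray:
    base = np.array([0.32, 0.24, 0.16])  # soil brown
    img = np.ones((cfg.size, cfg.size, 3)) * base
    if cfg.background == "soil":
        noise = rng.standard_normal((cfg.size, cfg.size))
        texture = gaussian_filter(noise, sigma=2.0)
        texture = texture / (np.abs(texture).max() + 1e-9)
        img *= (1.0 + 0.35 * texture)[..., None]
        grain = 0.03 * rng.standard_normal((cfg.size, cfg.size, 3))
        img = np.clip(img + grain, 0, 1)
    return img


def generate_dataset(cfg: RosetteConfig, n: int, out_dir) -> dict:
    """Write ``n`` scenes as PNG image + indexed-PNG label + polygon txt.

    Returns (and writes as ``manifest.json``) a manifest listing paths and
    per-image leaf counts.  Scene ``i`` is generated from seed
    ``cfg.seed + i`` so datasets are reproducible and extensible.
    """
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    labels_dir = out_dir / "labels_png"
    ann_dir = out_dir / "labels"
    for d in (images_dir, labels_dir, ann_dir):
        d.mkdir(parents=True, exist_ok=True)

    entries = []
    for i in range(n):
        rng = np.random.default_rng(cfg.seed + i)
        scene = generate_rosette(cfg, rng)
        stem = f"rosette_{i:04d}"
        img_path = images_dir / f"{stem}.png"
        lab_path = labels_dir / f"{stem}.png"
        txt_path = ann_dir / f"{stem}.txt"
        Image.fromarray(scene.image).save(img_path)
        masks_io.write_label_png(scene.labels, lab_path)
        ann = masks_io.mask_to_polygons(scene.labels, image_id=stem)
        masks_io.write_annotation_txt(ann, txt_path)
        entries.append(
            {
                "image": str(img_path),
                "label_png": str(lab_path),
                "annotation": str(txt_path),
                "leaf_count": int(scene.labels.max()),
            }
        )
    manifest = {"size": cfg.size, "n": n, "seed": cfg.seed, "images": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
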