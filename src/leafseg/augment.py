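"""Joint image + polygon-annotation augmentation stack.

The stack mirrors the training recipe of one-stage detectors: HSV colour
jitter, random flips, a single random affine (rotation, translation,
scale), four-image mosaic compositing, and optional random erasing.
Geometric operations transform the polygon annotations analytically rather
than resampling rasterised masks, so masks are only rasterised once, on
demand, after the full chain.

All randomness flows through an explicit ``numpy.random.Generator``; with a
fixed seed the full stack is reproducible bit-for-bit on integer images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.draw import polygon as draw_polygon
from skimage.transform import AffineTransform, warp

from .masks_io import MIN_INSTANCE_AREA, PolygonAnnotationSet, PolygonRecord

__all__ = [
    "AugmentConfig",
    "hsv_jitter",
    "apply_hsv",
    "flip",
    "affine",
    "mosaic4",
    "random_erase",
    "apply_stack",
]

# random-erasing rectangle geometry (area fraction and aspect-ratio bounds)
ERASE_AREA = (0.02, 0.2)
ERASE_RATIO = (0.3, 3.3)


@dataclass
class AugmentConfig:
    """Augmentation hyperparameters (training-config argument names)."""

    hsv_h: float = 0.015  # hue shift, fraction of the colour wheel
    hsv_s: float = 0.7  # saturation gain fraction
    hsv_v: float = 0.4  # value (brightness) gain fraction
    degrees: float = 180.0  # rotation range, degrees
    translate: float = 0.1  # translation, fraction of image size
    scale: float = 0.5  # scale gain fraction
    flipud: float = 0.5  # up-down flip probability
    fliplr: float = 0.5  # left-right flip probability
    mosaic: float = 1.0  # mosaic probability
    erasing: float = 0.4  # random-erasing probability (classification-style)
    apply_erasing: bool = False  # erasing is off for segmentation unless requested

    def __post_init__(self):
        for name in ("flipud", "fliplr", "mosaic", "erasing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if not 0.0 <= self.degrees <= 180.0:
            raise ValueError("degrees must lie in [0, 180]")
        for name in ("hsv_h", "hsv_s", "hsv_v", "translate", "scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _copy_ann(ann: PolygonAnnotationSet) -> PolygonAnnotationSet:
    return PolygonAnnotationSet(
        ann.image_id, [PolygonRecord(r.class_id, r.vertices.copy()) for r in ann.records]
    )


def hsv_jitter(image: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Random hue shift (with wraparound) plus saturation/value gains."""
    if cfg.hsv_h == 0 and cfg.hsv_s == 0 and cfg.hsv_v == 0:
        return image.copy()
    dh = rng.uniform(-cfg.hsv_h, cfg.hsv_h)
    gs = 1.0 + rng.uniform(-cfg.hsv_s, cfg.hsv_s)
    gv = 1.0 + rng.uniform(-cfg.hsv_v, cfg.hsv_v)
    return apply_hsv(image, dh, gs, gv)


def apply_hsv(image: np.ndarray, dh: float, gs: float, gv: float) -> np.ndarray:
    """Deterministic HSV transform: hue + dh (mod 1), saturation/value gains."""
    hsv = rgb2hsv(image)
    hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * gs, 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] * gv, 0.0, 1.0)
    out = hsv2rgb(hsv)
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(out * 255.0), 0, 255).astype(image.dtype)
    return out


def flip(
    image: np.ndarray,
    ann: PolygonAnnotationSet,
    axis: str,
    p: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, PolygonAnnotationSet]:
    """Mirror the image and annotation with probability ``p``.

    ``axis`` is ``"lr"`` (x → 1 − x) or ``"ud"`` (y → 1 − y).
    """
    if axis not in ("lr", "ud"):
        raise ValueError(f"axis must be 'lr' or 'ud', got {axis!r}")
    if rng.uniform() >= p:
        return image.copy(), _copy_ann(ann)
    out_ann = _copy_ann(ann)
    if axis == "lr":
        image = image[:, ::-1].copy()
        for rec in out_ann.records:
            rec.vertices[:, 0] = 1.0 - rec.vertices[:, 0]
    else:
        image = image[::-1].copy()
        for rec in out_ann.records:
            rec.vertices[:, 1] = 1.0 - rec.vertices[:, 1]
    return image, out_ann


def _pixel_area(vertices: np.ndarray, h: int, w: int) -> int:
    cols = vertices[:, 0] * w - 0.5
    rows = vertices[:, 1] * h - 0.5
    rr, _ = draw_polygon(rows, cols, shape=(h, w))
    return rr.size


def affine(
    image: np.ndarray,
    ann: PolygonAnnotationSet,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, PolygonAnnotationSet]:
    """One random similarity transform applied to pixels and vertices alike.

    Rotation in ±``degrees`` about the image centre, scale gain in
    [1 − scale, 1 + scale], translation in ±``translate`` of the image size.
    Vertices are clipped to [0, 1]; instances whose clipped outline covers
    fewer than 3 pixels are dropped.
    """
    h, w = image.shape[:2]
    theta = np.deg2rad(rng.uniform(-cfg.degrees, cfg.degrees))
    gain = 1.0 + rng.uniform(-cfg.scale, cfg.scale)
    tx = rng.uniform(-cfg.translate, cfg.translate) * w
    ty = rng.uniform(-cfg.translate, cfg.translate) * h
    if theta == 0.0 and gain == 1.0 and tx == 0.0 and ty == 0.0:
        return image.copy(), _copy_ann(ann)

    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
    to_origin = AffineTransform(translation=-center)
    rot_scale = AffineTransform(rotation=theta, scale=(gain, gain))
    back = AffineTransform(translation=center + np.array([tx, ty]))
    tform = to_origin + rot_scale + back  # forward: source px -> dest px

    img = warp(
        image.astype(float), tform.inverse, order=1, mode="constant", cval=0.0,
        preserve_range=True,
    )
    if np.issubdtype(image.dtype, np.integer):
        img = np.clip(np.rint(img), 0, 255).astype(image.dtype)

    out_ann = PolygonAnnotationSet(ann.image_id, [])
    for rec in ann.records:
        px = np.stack([rec.vertices[:, 0] * w - 0.5, rec.vertices[:, 1] * h - 0.5], axis=1)
        moved = tform(px)
        xy = np.stack([(moved[:, 0] + 0.5) / w, (moved[:, 1] + 0.5) / h], axis=1)
        xy = np.clip(xy, 0.0, 1.0)
        if _pixel_area(xy, h, w) >= MIN_INSTANCE_AREA:
            out_ann.records.append(PolygonRecord(rec.class_id, xy))
    return img, out_ann


def mosaic4(
    samples: list[tuple[np.ndarray, PolygonAnnotationSet]],
    rng: np.random.Generator,
    center: tuple[float, float] | None = None,
) -> tuple[np.ndarray, PolygonAnnotationSet]:
    """Composite four (image, annotation) samples onto a 2×2 canvas.

    The canvas is twice the sample edge; the quadrant junction is jittered
    uniformly inside the central half unless ``center`` (row, col) is given.
    Annotations are re-normalised into canvas coordinates; instances cropped
    below 3 px are dropped.
    """
    if len(samples) != 4:
        raise ValueError(f"mosaic needs exactly 4 samples, got {len(samples)}")
    s = samples[0][0].shape[0]
    for img, _ in samples:
        if img.shape[:2] != (s, s):
            raise ValueError("mosaic samples must share a square size")
    canvas_sz = 2 * s
    if center is None:
        cy = int(rng.uniform(0.5 * s, 1.5 * s))
        cx = int(rng.uniform(0.5 * s, 1.5 * s))
    else:
        cy, cx = int(center[0]), int(center[1])
    canvas = np.zeros((canvas_sz, canvas_sz) + samples[0][0].shape[2:], dtype=samples[0][0].dtype)
    out_ann = PolygonAnnotationSet(samples[0][1].image_id, [])

    # per quadrant: canvas paste window and source crop anchored at the junction
    quads = [
        (max(cy - s, 0), cy, max(cx - s, 0), cx, "br"),  # top-left, anchor bottom-right
        (max(cy - s, 0), cy, cx, min(cx + s, canvas_sz), "bl"),  # top-right
        (cy, min(cy + s, canvas_sz), max(cx - s, 0), cx, "tr"),  # bottom-left
        (cy, min(cy + s, canvas_sz), cx, min(cx + s, canvas_sz), "tl"),  # bottom-right
    ]
    for (img, ann), (y0, y1, x0, x1, anchor) in zip(samples, quads):
        hh, ww = y1 - y0, x1 - x0
        if hh <= 0 or ww <= 0:
            continue
        if anchor == "br":
            src = img[s - hh :, s - ww :]
            off = (y1 - s, x1 - s)  # source origin in canvas coords
        elif anchor == "bl":
            src = img[s - hh :, :ww]
            off = (y1 - s, x0)
        elif anchor == "tr":
            src = img[:hh, s - ww :]
            off = (y0, x1 - s)
        else:
            src = img[:hh, :ww]
            off = (y0, x0)
        canvas[y0:y1, x0:x1] = src
        for rec in ann.records:
            px = np.stack(
                [rec.vertices[:, 0] * s - 0.5 + off[1], rec.vertices[:, 1] * s - 0.5 + off[0]],
                axis=1,
            )
            xy = np.stack([(px[:, 0] + 0.5) / canvas_sz, (px[:, 1] + 0.5) / canvas_sz], axis=1)
            # clip to the visible quadrant window, then to the canvas
            xlo, xhi = x0 / canvas_sz, x1 / canvas_sz
            ylo, yhi = y0 / canvas_sz, y1 / canvas_sz
            xy[:, 0] = np.clip(xy[:, 0], xlo, xhi)
            xy[:, 1] = np.clip(xy[:, 1], ylo, yhi)
            if _pixel_area(xy, canvas_sz, canvas_sz) >= MIN_INSTANCE_AREA:
                out_ann.records.append(PolygonRecord(rec.class_id, xy))
    return canvas, out_ann


def random_erase(image: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """With probability ``erasing``, fill one random rectangle with noise."""
    if rng.uniform() >= cfg.erasing:
        return image.copy()
    h, w = image.shape[:2]
    area = rng.uniform(*ERASE_AREA) * h * w
    ratio = rng.uniform(*ERASE_RATIO)
    eh = min(h, max(1, int(round(np.sqrt(area * ratio)))))
    ew = min(w, max(1, int(round(np.sqrt(area / ratio)))))
    y0 = int(rng.integers(0, h - eh + 1))
    x0 = int(rng.integers(0, w - ew + 1))
    out = image.copy()
    if np.issubdtype(image.dtype, np.integer):
        out[y0 : y0 + eh, x0 : x0 + ew] = rng.integers(
            0, 256, size=(eh, ew) + image.shape[2:], dtype=image.dtype
        )
    else:
        out[y0 : y0 + eh, x0 : x0 + ew] = rng.uniform(size=(eh, ew) + image.shape[2:])
    return out


def apply_stack(
    sample: tuple[np.ndarray, PolygonAnnotationSet],
    pool: list[tuple[np.ndarray, PolygonAnnotationSet]],
    cfg: AugmentConfig,
    rng: np.random.Generator,
    use_mosaic: bool = True,
) -> tuple[np.ndarray, PolygonAnnotationSet]:
    """Full training-time chain: mosaic → affine → HSV → flips (→ erasing).

    ``pool`` supplies the three extra mosaic tiles.  The mosaic canvas is
    returned at twice the input size; callers resize to the network input.
    """
    image, ann = sample
    if use_mosaic and cfg.mosaic > 0 and len(pool) >= 3 and rng.uniform() < cfg.mosaic:
        picks = [pool[i] for i in rng.integers(0, len(pool), size=3)]
        image, ann = mosaic4([(image, ann)] + list(picks), rng)
    else:
        image, ann = image.copy(), _copy_ann(ann)
    image, ann = affine(image, ann, cfg, rng)
    image = hsv_jitter(image, cfg, rng)
    image, ann = flip(image, ann, "ud", cfg.flipud, rng)
    image, ann = flip(image, ann, "lr", cfg.fliplr, rng)
    if cfg.apply_erasing:
        image = random_erase(image, cfg, rng)
    return image, ann
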