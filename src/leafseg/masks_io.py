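"""Readers, writers and converters for leaf instance ground truth.

Instance label maps travel as 2-D integer arrays (0 = background, each
positive id one leaf).  On disk they are indexed/RGB PNGs (each distinct
non-background colour one instance) or flat HDF5 containers of 2-D integer
datasets.  Training labels interchange as plain-text polygon annotations:
one object per line, a class id followed by alternating x y coordinates
normalised to [0, 1].

Also provides the deterministic 3:1 train/validation split (every fourth
file of the sorted list goes to validation) and joint image/label resizing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from PIL import Image
from skimage import measure
from skimage.draw import polygon as draw_polygon
from skimage.transform import resize as _sk_resize

log = logging.getLogger(__name__)

__all__ = [
    "PolygonRecord",
    "PolygonAnnotationSet",
    "DatasetSplit",
    "read_label_png",
    "write_label_png",
    "read_label_h5",
    "mask_to_polygons",
    "polygons_to_mask",
    "write_annotation_txt",
    "read_annotation_txt",
    "split_file_list",
    "resize_pair",
]

MIN_INSTANCE_AREA = 3  # px; below this a polygon is not representable


@dataclass
class PolygonRecord:
    class_id: int
    vertices: np.ndarray  # (n, 2) float, columns (x, y) in [0, 1], implicitly closed

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)


@dataclass
class PolygonAnnotationSet:
    image_id: str = ""
    records: list[PolygonRecord] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class DatasetSplit:
    train: list[str]
    val: list[str]


# ---------------------------------------------------------------------------
# PNG label maps


def read_label_png(path) -> np.ndarray:
    """Read an instance label map from an indexed or RGB PNG.

    Each distinct non-background colour becomes a distinct positive id,
    assigned in raster-scan first-appearance order.  Background is palette
    index 0 for paletted images and black for RGB images.
    """
    with Image.open(path) as im:
        if im.mode == "P":
            arr = np.asarray(im, dtype=np.int64)
            flat_bg = arr == 0
        elif im.mode in ("L", "I", "I;16"):
            arr = np.asarray(im, dtype=np.int64)
            flat_bg = arr == 0
        elif im.mode in ("RGB", "RGBA"):
            rgb = np.asarray(im.convert("RGB"), dtype=np.int64)
            arr = (rgb[..., 0] << 16) | (rgb[..., 1] << 8) | rgb[..., 2]
            flat_bg = arr == 0
        else:
            raise ValueError(f"unsupported PNG mode {im.mode!r} for label map")
    out = np.zeros(arr.shape, dtype=np.int32)
    flat = arr.ravel()
    fg = ~flat_bg.ravel()
    if fg.any():
        vals = flat[fg]
        uniq, first_pos = np.unique(vals, return_index=True)
        # ids in raster-scan first-appearance order
        new_ids = np.empty(uniq.size, dtype=np.int32)
        new_ids[np.argsort(first_pos)] = np.arange(1, uniq.size + 1, dtype=np.int32)
        out.ravel()[fg] = new_ids[np.searchsorted(uniq, vals)]
    return out


def write_label_png(labels, path) -> None:
    """Write a label map as a paletted PNG (index = instance id).

    Ids above 255 are re-packed into the low 24 bits of an RGB image.
    """
    labels = np.asarray(labels)
    if labels.max(initial=0) <= 255:
        im = Image.fromarray(labels.astype(np.uint8), mode="P")
        palette = _distinct_palette(256)
        im.putpalette(palette.ravel().tolist())
        im.save(path)
    else:
        rgb = np.stack(
            [(labels >> 16) & 255, (labels >> 8) & 255, labels & 255], axis=-1
        ).astype(np.uint8)
        Image.fromarray(rgb, mode="RGB").save(path)


def _distinct_palette(n: int) -> np.ndarray:
    """Deterministic palette with index 0 black and visually spread colours."""
    rng = np.random.default_rng(0)
    pal = rng.integers(32, 256, size=(n, 3), dtype=np.uint8)
    pal[0] = 0
    return pal


# ---------------------------------------------------------------------------
# HDF5 label containers


def read_label_h5(path, key: str | None = None) -> list[np.ndarray]:
    """Read instance label maps from a flat HDF5 container.

    Every 2-D integer dataset under ``key`` (or the file root) yields one
    label map; iteration order is lexicographic key order.
    """
    maps: list[np.ndarray] = []
    with h5py.File(path, "r") as fh:
        group = fh[key] if key is not None else fh
        names = sorted(group.keys())
        for name in names:
            ds = group[name]
            if not isinstance(ds, h5py.Dataset):
                continue
            arr = np.asarray(ds)
            if arr.ndim != 2:
                raise ValueError(f"dataset {name!r} is {arr.ndim}-D, expected 2-D")
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(f"dataset {name!r} has non-integer dtype {arr.dtype}")
            maps.append(arr.astype(np.int32))
    return maps


# ---------------------------------------------------------------------------
# Mask <-> polygon conversion


def mask_to_polygons(labels, simplify_tol: float = 1.0, image_id: str = "") -> PolygonAnnotationSet:
    """Trace each instance's outer boundary into a normalised polygon record.

    Instances smaller than 3 px are skipped (logged); multi-part instances
    emit their largest connected part only, since the one-line-per-object
    format cannot express parts.  Vertices are simplified Douglas–Peucker
    style with ``simplify_tol`` pixels tolerance and normalised by the image
    width/height with pixel centres at (i + 0.5)/size.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    ann = PolygonAnnotationSet(image_id=image_id)
    for iid in np.unique(labels):
        if iid <= 0:
            continue
        mask = labels == iid
        area = int(mask.sum())
        if area < MIN_INSTANCE_AREA:
            log.info("instance %d has area %d px < %d, skipped", iid, area, MIN_INSTANCE_AREA)
            continue
        comp = measure.label(mask, connectivity=1)
        if comp.max() > 1:
            sizes = np.bincount(comp.ravel())[1:]
            keep = int(np.argmax(sizes)) + 1
            log.info("instance %d has %d parts; keeping the largest", iid, comp.max())
            mask = comp == keep
            if mask.sum() < MIN_INSTANCE_AREA:
                continue
        contour = _outer_contour(mask)
        if contour is None:
            continue
        contour = measure.approximate_polygon(contour, tolerance=simplify_tol)
        # drop the duplicated closing vertex
        if len(contour) > 1 and np.allclose(contour[0], contour[-1]):
            contour = contour[:-1]
        if len(contour) < 3:
            continue
        # contour rows are (row, col); convert to (x, y) at pixel centres
        xy = np.stack([(contour[:, 1] + 0.5) / w, (contour[:, 0] + 0.5) / h], axis=1)
        xy = np.clip(xy, 0.0, 1.0)
        ann.records.append(PolygonRecord(0, xy))
    return ann


def _outer_contour(mask: np.ndarray) -> np.ndarray | None:
    """Longest closed iso-contour of a binary mask, in (row, col) pixel units."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    return contour - 1.0  # undo padding offset


def polygons_to_mask(ann: PolygonAnnotationSet, height: int, width: int) -> np.ndarray:
    """Rasterise polygon records back into an instance label map.

    Records are painted in order; later records overwrite earlier ones on
    overlap; record ``k`` receives id ``k + 1``.  Degenerate polygons
    covering fewer than 3 pixels are skipped with a warning.
    """
    out = np.zeros((height, width), dtype=np.int32)
    for k, rec in enumerate(ann.records):
        v = np.asarray(rec.vertices, dtype=float)
        if len(v) < 3:
            log.warning("record %d has %d vertices, skipped", k, len(v))
            continue
        cols = v[:, 0] * width - 0.5
        rows = v[:, 1] * height - 0.5
        rr, cc = draw_polygon(rows, cols, shape=(height, width))
        if rr.size < MIN_INSTANCE_AREA:
            log.debug("record %d rasterises to %d px, skipped", k, rr.size)
            continue
        out[rr, cc] = k + 1
    return out


# ---------------------------------------------------------------------------
# Plain-text polygon annotations


def write_annotation_txt(ann: PolygonAnnotationSet, path) -> None:
    """One line per record: class id then alternating x y, 6-decimal fixed point."""
    with open(path, "w") as fh:
        for rec in ann.records:
            coords = " ".join(f"{c:.6f}" for c in np.asarray(rec.vertices).ravel())
            fh.write(f"{rec.class_id} {coords}\n")


def read_annotation_txt(path, image_id: str = "") -> PolygonAnnotationSet:
    """Inverse of :func:`write_annotation_txt`; strict about malformed lines."""
    ann = PolygonAnnotationSet(image_id=image_id or Path(path).stem)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) % 2 == 0 or len(tokens) < 7:
                raise ValueError(
                    f"{path}:{lineno}: expected a class id plus >=3 x,y pairs, got {len(tokens)} tokens"
                )
            try:
                class_id = int(tokens[0])
                coords = np.array([float(t) for t in tokens[1:]], dtype=float)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric token ({exc})") from None
            ann.records.append(PolygonRecord(class_id, coords.reshape(-1, 2)))
    return ann


# ---------------------------------------------------------------------------
# Split and resize


def split_file_list(files: Sequence[str], presorted: bool = False) -> DatasetSplit:
    """Deterministic 3:1 split: every fourth file of the sorted list → val.

    Positions 4, 8, 12, … (1-based) of the lexicographically sorted list go
    to validation; the rest to training.
    """
    files = list(files) if presorted else sorted(files)
    val = [f for i, f in enumerate(files, start=1) if i % 4 == 0]
    train = [f for i, f in enumerate(files, start=1) if i % 4 != 0]
    return DatasetSplit(train=train, val=val)


def resize_pair(image, labels, size) -> tuple[np.ndarray, np.ndarray]:
    """Resize an image (bilinear) and its label map (nearest-neighbour) together.

    ``size`` is ``(height, width)`` or a single square edge.  Nearest-
    neighbour label resampling never introduces ids absent from the source.
    """
    if np.isscalar(size):
        size = (int(size), int(size))
    h, w = int(size[0]), int(size[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"target size must be positive, got {(h, w)}")
    image = np.asarray(image)
    labels = np.asarray(labels)
    if image.shape[:2] == (h, w):
        out_img = image.copy()
    else:
        out_img = _sk_resize(
            image.astype(float), (h, w) + image.shape[2:], order=1,
            preserve_range=True, anti_aliasing=False,
        )
        if np.issubdtype(image.dtype, np.integer):
            out_img = np.clip(np.rint(out_img), np.iinfo(image.dtype).min, np.iinfo(image.dtype).max).astype(image.dtype)
    if labels.shape == (h, w):
        out_lab = labels.copy()
    else:
        # nearest-neighbour via index mapping (order=0 with exact centres)
        src_h, src_w = labels.shape
        rows = np.minimum((np.arange(h) + 0.5) * src_h / h, src_h - 1).astype(int)
        cols = np.minimum((np.arange(w) + 0.5) * src_w / w, src_w - 1).astype(int)
        out_lab = labels[np.ix_(rows, cols)]
    return out_img, out_lab
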