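"""CVPPP Leaf Segmentation Challenge evaluation measures.

Implements the five measures used to score leaf instance segmentation:

* ``dice`` — binary Dice overlap of two masks.
* ``best_dice`` — for every instance of the first label map, the best Dice
  against any instance of the second, averaged over the first map's instances.
* ``symmetric_best_dice`` — the minimum of Best Dice taken in both directions;
  the challenge's primary segmentation score.
* ``fgbg_dice`` — Dice of the binarised foreground masks (instance identity
  ignored).
* ``diff_fg`` / ``abs_diff_fg`` — signed and absolute difference in instance
  (leaf) count.

Conventions: two empty masks have Dice 1.0 (perfect agreement on absence);
one empty and one non-empty mask have Dice 0.0.  Best Dice of a map with no
instances is 0.0 so that batch evaluation never aborts on an empty
prediction.  Dataset aggregation is the unweighted arithmetic mean of the
per-image values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MetricReport",
    "dice",
    "best_dice",
    "symmetric_best_dice",
    "fgbg_dice",
    "diff_fg",
    "abs_diff_fg",
    "evaluate_dataset",
    "instance_ids",
]

METRIC_NAMES = ("BD", "SBD", "FGBGDice", "DiffFG", "AbsDiffFG")


def _as_labels(a) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2:
        raise ValueError(f"label map must be 2-D, got shape {a.shape}")
    if not np.issubdtype(a.dtype, np.integer) and not np.issubdtype(a.dtype, np.bool_):
        if not np.all(a == np.round(a)):
            raise ValueError("label map must contain integers")
        a = a.astype(np.int64)
    return a


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def instance_ids(labels) -> np.ndarray:
    """Distinct positive ids present in a label map, sorted ascending."""
    ids = np.unique(np.asarray(labels))
    return ids[ids > 0]


def dice(a, b) -> float:
    """Dice overlap of two boolean masks: ``2|a∩b| / (|a| + |b|)``.

    Both masks empty scores 1.0; exactly one empty scores 0.0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    _check_shapes(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def _pairwise_dice_matrix(ar: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dice between every (ar instance, gt instance) pair via a joint histogram."""
    ar_ids = instance_ids(ar)
    gt_ids = instance_ids(gt)
    if ar_ids.size == 0 or gt_ids.size == 0:
        return np.zeros((ar_ids.size, gt_ids.size)), ar_ids, gt_ids
    # map ids to contiguous indices; 0 stays background
    ar_idx = np.searchsorted(ar_ids, ar.ravel())
    ar_fg = np.isin(ar.ravel(), ar_ids)
    gt_idx = np.searchsorted(gt_ids, gt.ravel())
    gt_fg = np.isin(gt.ravel(), gt_ids)
    both = ar_fg & gt_fg
    inter = np.zeros((ar_ids.size, gt_ids.size), dtype=np.int64)
    np.add.at(inter, (ar_idx[both], gt_idx[both]), 1)
    area_ar = np.bincount(ar_idx[ar_fg], minlength=ar_ids.size).astype(np.int64)
    area_gt = np.bincount(gt_idx[gt_fg], minlength=gt_ids.size).astype(np.int64)
    denom = area_ar[:, None] + area_gt[None, :]
    return 2.0 * inter / denom, ar_ids, gt_ids


def best_dice(ar, gt) -> float:
    """Mean over the first map's instances of the best Dice against any
    instance of the second map.  Returns 0.0 when the first map has no
    instances."""
    ar = _as_labels(ar)
    gt = _as_labels(gt)
    _check_shapes(ar, gt)
    mat, ar_ids, gt_ids = _pairwise_dice_matrix(ar, gt)
    if ar_ids.size == 0:
        return 0.0
    if gt_ids.size == 0:
        return 0.0
    return float(mat.max(axis=1).mean())


def symmetric_best_dice(ar, gt) -> float:
    """min(best_dice(ar, gt), best_dice(gt, ar))."""
    return min(best_dice(ar, gt), best_dice(gt, ar))


def fgbg_dice(ar, gt) -> float:
    """Dice of the binarised foregrounds (labels > 0)."""
    ar = _as_labels(ar)
    gt = _as_labels(gt)
    _check_shapes(ar, gt)
    return dice(ar > 0, gt > 0)


def diff_fg(ar, gt) -> int:
    """Signed difference in instance count: #ar − #gt."""
    return int(instance_ids(_as_labels(ar)).size) - int(instance_ids(_as_labels(gt)).size)


def abs_diff_fg(ar, gt) -> int:
    """Absolute difference in instance count."""
    return abs(diff_fg(ar, gt))


@dataclass
class MetricReport:
    """Per-image and aggregated evaluation results.

    ``per_image`` holds one ``(image_id, BD, SBD, FGBGDice, DiffFG,
    AbsDiffFG)`` row per evaluated pair; ``aggregate`` the column-wise
    arithmetic means.  ``scale`` is ``"fraction"`` ([0, 1] Dice values) or
    ``"percent"``.
    """

    per_image: list[tuple] = field(default_factory=list)
    aggregate: dict[str, float] = field(default_factory=dict)
    scale: str = "fraction"

    def to_percent(self) -> "MetricReport":
        if self.scale == "percent":
            return self
        rows = [
            (i, bd * 100.0, sbd * 100.0, fg * 100.0, d, ad)
            for (i, bd, sbd, fg, d, ad) in self.per_image
        ]
        agg = dict(self.aggregate)
        for k in ("BD", "SBD", "FGBGDice"):
            agg[k] *= 100.0
        return MetricReport(rows, agg, "percent")

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(("image",) + METRIC_NAMES)
            for row in self.per_image:
                w.writerow(row)
            w.writerow(["mean"] + [self.aggregate[k] for k in METRIC_NAMES])

    def format_table(self) -> str:
        """Human-readable table, Dice columns in percent with 2 decimals."""
        rep = self.to_percent()
        lines = [f"{'image':<16}{'BD':>9}{'SBD':>9}{'FGBGDice':>10}{'DiffFG':>8}{'AbsDiffFG':>10}"]
        for i, bd, sbd, fg, d, ad in rep.per_image:
            lines.append(f"{str(i):<16}{bd:>9.2f}{sbd:>9.2f}{fg:>10.2f}{d:>8.2f}{ad:>10.2f}")
        a = rep.aggregate
        lines.append(
            f"{'ALL':<16}{a['BD']:>9.2f}{a['SBD']:>9.2f}{a['FGBGDice']:>10.2f}"
            f"{a['DiffFG']:>8.2f}{a['AbsDiffFG']:>10.2f}"
        )
        return "\n".join(lines)


def evaluate_dataset(
    pairs: Iterable[tuple],
    ids: Sequence | None = None,
    percent: bool = False,
) -> MetricReport:
    """Evaluate (prediction, ground-truth) label-map pairs.

    Parameters
    ----------
    pairs
        Iterable of ``(ar, gt)`` label-map pairs, shape-matched per pair.
    ids
        Optional per-pair identifiers; defaults to the running index.
    percent
        Report Dice columns on the 0–100 scale.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_dataset needs at least one (prediction, truth) pair")
    rows = []
    for k, (ar, gt) in enumerate(pairs):
        image_id = ids[k] if ids is not None else k
        rows.append(
            (
                image_id,
                best_dice(ar, gt),
                symmetric_best_dice(ar, gt),
                fgbg_dice(ar, gt),
                diff_fg(ar, gt),
                abs_diff_fg(ar, gt),
            )
        )
    cols = np.array([r[1:] for r in rows], dtype=float)
    agg = {name: float(cols[:, j].mean()) for j, name in enumerate(METRIC_NAMES)}
    report = MetricReport(rows, agg, "fraction")
    return report.to_percent() if percent else report
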