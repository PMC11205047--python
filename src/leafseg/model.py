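"""Assembly, training and inference of the leaf segmentation networks.

Three variants share one anchor-free, decoupled-head, prototype-mask
architecture:

* ``standard`` — C2f backbone with P3/P4/P5 taps, path-aggregation neck,
  decoupled head with box-distribution (DFL), class, and mask-coefficient
  branches plus a shared prototype stack.
* ``bifpn`` — the neck's concatenation nodes replaced by fast normalised
  weighted fusion with same-level skip connections.
* ``ghost`` — the P4 backbone downsampling convolution replaced by a Ghost
  module.

Training uses task-aligned assignment (alignment metric
``t = score^α · IoU^β`` restricted to anchor points inside the box, top-k
per instance), CIoU + distribution-focal box losses, binary cross-entropy
classification, and per-instance prototype-mask BCE cropped to the box.
"""

from __future__ import annotations

import copy
import importlib.resources as resources
import json
import logging
import time
from dataclasses import dataclass, field, asdict


import numpy as np
import yaml

from . import autograd as ag
from . import masks_io, metrics, nn
from .augment import AugmentConfig, apply_stack
from .autograd import Tensor, no_grad
from .masks_io import PolygonAnnotationSet, polygons_to_mask, resize_pair
from .net_blocks import C2f, GhostConfig, GhostConv, SPPF, WeightedFusion
from .nn import Conv, Module, SGD, Upsample

log = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "Prediction",
    "build_model",
    "assign_targets",
    "compute_loss",
    "train",
    "predict_instances",
    "save_checkpoint",
    "load_checkpoint",
]

SCALES = {
    "n": (0.33, 0.25),
    "s": (0.33, 0.50),
    "m": (0.67, 0.75),
    "l": (1.00, 1.00),
    "x": (1.33, 1.25),
}

STRIDES = (8, 16, 32)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``scale`` selects the depth/width multipliers (n/s/m/l/x); the deeper
    study-scale models use ``l``, while desk-scale experiments run ``n``.
    """

    variant: str = "standard"
    scale: str = "n"
    num_classes: int = 1
    image_size: int = 512
    num_prototypes: int = 32
    dfl_bins: int = 16
    fusion_eps: float = 1e-4
    conf_threshold: float = 0.25
    nms_iou: float = 0.7
    max_detections: int = 300

    def __post_init__(self):
        if self.variant not in ("standard", "bifpn", "ghost"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.image_size % 32 != 0:
            raise ValueError("image size must be divisible by 32")


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (study-scale defaults)."""

    epochs: int = 250
    batch_size: int = 16
    close_mosaic: int = 10
    lr0: float = 0.01
    lrf: float = 0.01  # final lr = lr0 * lrf (linear decay)
    momentum: float = 0.937
    weight_decay: float = 5e-4
    warmup_epochs: float = 3.0
    grad_clip: float = 10.0  # global gradient-norm ceiling; 0 disables
    tal_topk: int = 10
    tal_alpha: float = 0.5
    tal_beta: float = 6.0
    lambda_box: float = 7.5
    lambda_cls: float = 0.5
    lambda_dfl: float = 1.5
    lambda_mask: float = 1.0
    val_interval: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.close_mosaic > self.epochs:
            raise ValueError("close_mosaic must not exceed epochs")


@dataclass
class Prediction:
    """Per-image inference result, instances sorted by descending score."""

    boxes: np.ndarray  # (n, 4) xyxy pixels
    scores: np.ndarray  # (n,)
    coefficients: np.ndarray  # (n, num_prototypes)
    prototypes: np.ndarray  # (num_prototypes, H/4, W/4)
    labels: np.ndarray  # (H, W) instance label map


# ---------------------------------------------------------------------------
# graph assembly


def _make_divisible(x: float, div: int = 8) -> int:
    return max(div, int(np.ceil(x / div) * div))


class Proto(Module):
    """Prototype-mask branch: runs on P3 and upsamples to stride 4."""

    def __init__(self, c_in, c_mid, nm):
        super().__init__()
        self.cv1 = Conv(c_in, c_mid, 3, 1)
        self.up = Upsample()
        self.cv2 = Conv(c_mid, c_mid, 3, 1)
        self.cv3 = Conv(c_mid, nm, 1, 1)

    def forward(self, x):
        return self.cv3(self.cv2(self.up(self.cv1(x))))


class Segment(Module):
    """Decoupled anchor-free head with mask coefficients and prototypes.

    Per level: a box branch emitting ``4 · dfl_bins`` logits (each box edge
    a discrete distribution over distance bins), a class branch, and a
    mask-coefficient branch; a shared prototype stack runs off P3.
    """

    def __init__(self, ch: list[int], nc: int, reg_max: int, nm: int, proto_ch: int):
        super().__init__()
        self.nc, self.reg_max, self.nm = nc, reg_max, nm
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        c4 = max(ch[0] // 4, nm)
        self.box_branch = [
            nn.Sequential(Conv(c, c2, 3), Conv(c2, c2, 3), Conv(c2, 4 * reg_max, 1, act=False, bn=False))
            for c in ch
        ]
        self.cls_branch = [
            nn.Sequential(Conv(c, c3, 3), Conv(c3, c3, 3), Conv(c3, nc, 1, act=False, bn=False))
            for c in ch
        ]
        self.coef_branch = [
            nn.Sequential(Conv(c, c4, 3), Conv(c4, c4, 3), Conv(c4, nm, 1, act=False, bn=False))
            for c in ch
        ]
        self.proto = Proto(ch[0], proto_ch, nm)
        # bias the class logits towards a low positive prior for stable warmup
        for seq in self.cls_branch:
            seq.layers[-1].bias.data[...] = -4.0

    def forward(self, feats: list[Tensor]):
        out = []
        for i, f in enumerate(feats):
            out.append(
                {
                    "box": self.box_branch[i](f),
                    "cls": self.cls_branch[i](f),
                    "coef": self.coef_branch[i](f),
                }
            )
        return out, self.proto(feats[0])


_BLOCKS = {"Conv", "C2f", "SPPF", "GhostConv", "Upsample", "Concat", "WeightedFusion", "Segment"}


class SegModel(Module):
    """Network built from a declarative (from, repeats, block, args) graph."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        depth, width = SCALES[cfg.scale]
        rows = _load_graph(cfg.variant)
        self.rows = rows
        self.layers: list[Module] = []
        self.froms: list = []
        self.save: set[int] = set()
        ch: list[int] = []
        head_ch = None
        for idx, (frm, repeats, name, args) in enumerate(rows):
            if name not in _BLOCKS:
                raise ValueError(f"unknown block {name!r} in graph row {idx}")
            src = frm if isinstance(frm, list) else [frm]
            src = [s if s >= 0 else idx + s for s in src]
            in_ch = [ch[s] if s < len(ch) else 3 for s in src] if idx > 0 else [3]
            n = max(round(repeats * depth), 1) if repeats > 1 else repeats
            if name == "Conv":
                c2 = _make_divisible(args[0] * width)
                layer = Conv(in_ch[0], c2, args[1], args[2])
            elif name == "C2f":
                c2 = _make_divisible(args[0] * width)
                layer = C2f(in_ch[0], c2, n=n, shortcut=bool(args[1]))
            elif name == "SPPF":
                c2 = _make_divisible(args[0] * width)
                layer = SPPF(in_ch[0], c2, args[1])
            elif name == "GhostConv":
                c2 = _make_divisible(args[0] * width)
                gcfg = GhostConfig(in_ch[0], c2, ratio=args[1], primary_kernel=args[2],
                                   cheap_kernel=args[3], stride=args[4])
                layer = GhostConv(gcfg)
            elif name == "Upsample":
                c2 = in_ch[0]
                layer = Upsample()
            elif name == "Concat":
                c2 = sum(in_ch)
                layer = _ConcatNode()
            elif name == "WeightedFusion":
                c2 = _make_divisible(args[0] * width)
                layer = WeightedFusion(in_ch, c2, eps=cfg.fusion_eps)
            elif name == "Segment":
                head_ch = in_ch
                proto_ch = _make_divisible(256 * width)
                layer = Segment(in_ch, cfg.num_classes, cfg.dfl_bins, cfg.num_prototypes, proto_ch)
                c2 = 0
            self.layers.append(layer)
            self.froms.append(src)
            for s in src:
                if s != idx - 1:
                    self.save.add(s)
            ch.append(c2)
        if head_ch is None:
            raise ValueError("graph has no Segment head")
        self.head: Segment = self.layers[-1]

    def forward(self, x: Tensor):
        saved: dict[int, Tensor] = {}
        prev = x
        for idx, (layer, src) in enumerate(zip(self.layers, self.froms)):
            inputs = [prev if s == idx - 1 else saved[s] for s in src]
            if isinstance(layer, Segment):
                return layer(inputs)
            if isinstance(layer, (_ConcatNode, WeightedFusion)):
                prev = layer(inputs)
            else:
                prev = layer(inputs[0])
            if idx in self.save:
                saved[idx] = prev
        raise RuntimeError("graph ended without a Segment head")


class _ConcatNode(Module):
    def forward(self, inputs: list[Tensor]) -> Tensor:
        return ag.concat(inputs, axis=1)


def _load_graph(variant: str) -> list:
    text = resources.files("leafseg.configs").joinpath(f"{variant}.yaml").read_text()
    spec = yaml.safe_load(text)
    return list(spec["backbone"]) + list(spec["neck"]) + list(spec["head"])


def build_model(cfg: ModelConfig, seed: int | None = None) -> SegModel:
    """Instantiate a variant; ``seed`` reseeds weight initialisation."""
    if seed is not None:
        nn.set_init_seed(seed)
    return SegModel(cfg)


# ---------------------------------------------------------------------------
# anchors, decoding, IoU


def make_anchors(image_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Anchor-point centres (pixels) and per-anchor strides for all levels."""
    points, strides = [], []
    for st in STRIDES:
        g = image_size // st
        xs = (np.arange(g) + 0.5) * st
        xx, yy = np.meshgrid(xs, xs)
        points.append(np.stack([xx.ravel(), yy.ravel()], axis=1))
        strides.append(np.full(g * g, st, dtype=np.float64))
    return np.concatenate(points).astype(np.float64), np.concatenate(strides)


def bbox_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (n,4) and (m,4) xyxy boxes."""
    if a.size == 0 or b.size == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.prod(np.clip(a[:, 2:] - a[:, :2], 0, None), axis=1)
    area_b = np.prod(np.clip(b[:, 2:] - b[:, :2], 0, None), axis=1)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-9), 0.0)


def _flatten_levels(level_outs: list[dict], key: str) -> Tensor:
    """(B, C, h, w) per level → (B, ΣA, C)."""
    parts = []
    for lv in level_outs:
        t = lv[key]
        B, C, H, W = t.shape
        parts.append(ag.transpose(ag.reshape(t, (B, C, H * W)), (0, 2, 1)))
    return ag.concat(parts, axis=1)


def decode_boxes(box_logits: Tensor, anchors: np.ndarray, strides: np.ndarray,
                 reg_max: int) -> tuple[Tensor, Tensor]:
    """DFL expectation decode: logits (A, 4·reg_max) → boxes (A, 4) xyxy px.

    Returns (boxes, distances-in-grid-units); gradients flow through the
    softmax expectation.
    """
    A = box_logits.shape[0]
    probs = ag.softmax(ag.reshape(box_logits, (A, 4, reg_max)), axis=-1)
    proj = Tensor(np.arange(reg_max, dtype=np.float32).reshape(reg_max, 1))
    dist = ag.reshape(ag.matmul(probs, proj), (A, 4))  # ltrb, grid units
    st = Tensor(strides[:, None].astype(np.float32))
    dist_px = ag.mul(dist, st)
    anc = Tensor(anchors.astype(np.float32))
    lt = ag.narrow(dist_px, 1, 0, 2)
    rb = ag.narrow(dist_px, 1, 2, 2)
    x1y1 = ag.sub(anc, lt)
    x2y2 = ag.add(anc, rb)
    return ag.concat([x1y1, x2y2], axis=1), dist


# ---------------------------------------------------------------------------
# task-aligned assignment


@dataclass
class Assignment:
    fg_mask: np.ndarray  # (A,) bool
    gt_index: np.ndarray  # (A,) int, -1 for background
    target_scores: np.ndarray  # (A,) alignment-normalised target class scores


def assign_targets(
    scores: np.ndarray,
    pred_boxes: np.ndarray,
    anchors: np.ndarray,
    gt_boxes: np.ndarray,
    topk: int = 10,
    alpha: float = 0.5,
    beta: float = 6.0,
) -> Assignment:
    """Task-aligned positive-sample assignment for one image.

    Each ground-truth box receives the top-k anchor points (restricted to
    points inside the box) ranked by ``t = score^α · IoU^β``; an anchor
    claimed by several instances goes to the one with the highest ``t``.
    Target scores are ``t`` rescaled per instance so its maximum equals the
    instance's best IoU.
    """
    A = anchors.shape[0]
    n = gt_boxes.shape[0]
    if n == 0:
        return Assignment(np.zeros(A, bool), np.full(A, -1), np.zeros(A))
    inside = (
        (anchors[:, 0, None] > gt_boxes[None, :, 0])
        & (anchors[:, 0, None] < gt_boxes[None, :, 2])
        & (anchors[:, 1, None] > gt_boxes[None, :, 1])
        & (anchors[:, 1, None] < gt_boxes[None, :, 3])
    )
    iou = bbox_iou_matrix(pred_boxes, gt_boxes)  # (A, n)
    t = (np.clip(scores[:, None], 1e-9, 1) ** alpha) * (iou**beta)
    t = np.where(inside, t, 0.0)

    candidate = np.zeros((A, n), dtype=bool)
    for j in range(n):
        order = np.argsort(-t[:, j])
        picked = 0
        for i in order:
            if t[i, j] <= 0:
                break
            candidate[i, j] = True
            picked += 1
            if picked >= topk:
                break
    # resolve anchors claimed by several instances: highest t wins
    claimed = candidate.sum(axis=1)
    multi = claimed > 1
    if multi.any():
        best = t.argmax(axis=1)
        fix = np.zeros_like(candidate)
        fix[np.arange(A), best] = True
        candidate[multi] = fix[multi] & candidate[multi]
    fg = candidate.any(axis=1)
    gt_index = np.where(fg, candidate.argmax(axis=1), -1)

    target_scores = np.zeros(A)
    for j in range(n):
        pos = candidate[:, j]
        if not pos.any():
            continue
        tmax = t[pos, j].max()
        imax = iou[pos, j].max()
        if tmax > 0:
            target_scores[pos] = t[pos, j] / tmax * imax
    return Assignment(fg, gt_index, target_scores)


# ---------------------------------------------------------------------------
# losses


def _ciou(pred: Tensor, target: np.ndarray) -> Tensor:
    """Complete IoU between predicted boxes (with grad) and constant targets."""
    tx1, ty1, tx2, ty2 = (Tensor(target[:, i : i + 1]) for i in range(4))
    px1 = ag.narrow(pred, 1, 0, 1)
    py1 = ag.narrow(pred, 1, 1, 1)
    px2 = ag.narrow(pred, 1, 2, 1)
    py2 = ag.narrow(pred, 1, 3, 1)
    iw = ag.clamp(ag.sub(ag.minimum(px2, tx2), ag.maximum(px1, tx1)), 0.0)
    ih = ag.clamp(ag.sub(ag.minimum(py2, ty2), ag.maximum(py1, ty1)), 0.0)
    inter = ag.mul(iw, ih)
    pw = ag.clamp(ag.sub(px2, px1), 1e-6)
    ph = ag.clamp(ag.sub(py2, py1), 1e-6)
    tw = np.clip(target[:, 2:3] - target[:, 0:1], 1e-6, None)
    th = np.clip(target[:, 3:4] - target[:, 1:2], 1e-6, None)
    union = ag.add(ag.sub(ag.add(ag.mul(pw, ph), tw * th), inter), 1e-7)
    iou = ag.div(inter, union)
    # enclosing-box diagonal
    cw = ag.sub(ag.maximum(px2, tx2), ag.minimum(px1, tx1))
    chh = ag.sub(ag.maximum(py2, ty2), ag.minimum(py1, ty1))
    c2 = ag.add(ag.add(ag.mul(cw, cw), ag.mul(chh, chh)), 1e-7)
    pcx = ag.mul(ag.add(px1, px2), 0.5)
    pcy = ag.mul(ag.add(py1, py2), 0.5)
    tcx = (target[:, 0:1] + target[:, 2:3]) * 0.5
    tcy = (target[:, 1:2] + target[:, 3:4]) * 0.5
    dx = ag.sub(pcx, Tensor(tcx))
    dy = ag.sub(pcy, Tensor(tcy))
    rho2 = ag.add(ag.mul(dx, dx), ag.mul(dy, dy))
    # aspect-ratio term with detached trade-off coefficient
    v = ag.mul(ag.power(ag.sub(ag.arctan(Tensor(tw / th)), ag.arctan(ag.div(pw, ph))), 2.0), 4.0 / np.pi**2)
    with no_grad():
        alpha_np = v.data / np.clip(1.0 - iou.data + v.data, 1e-7, None)
    return ag.sub(ag.sub(iou, ag.div(rho2, c2)), ag.mul(v, Tensor(alpha_np)))


def dfl_target_weights(tdist: np.ndarray, reg_max: int) -> np.ndarray:
    """Two-bin interpolation targets for the distribution focal loss.

    A true distance ``t`` puts mass ``ceil(t) − t`` on bin ``⌊t⌋`` and the
    remainder on the next bin; a distance exactly on an integer bin edge is
    a delta (its cross-entropy against a matching delta prediction is 0).
    Input shape (..., ) maps to output shape (..., reg_max).
    """
    tdist = np.clip(tdist, 0, reg_max - 1 - 0.01)
    tl = np.floor(tdist).astype(int)
    wr = (tdist - tl).astype(np.float32)
    out = np.zeros(tdist.shape + (reg_max,), dtype=np.float32)
    np.put_along_axis(out, tl[..., None], (1.0 - wr)[..., None], axis=-1)
    idx_hi = np.minimum(tl + 1, reg_max - 1)
    hi = np.take_along_axis(out, idx_hi[..., None], axis=-1) + wr[..., None]
    np.put_along_axis(out, idx_hi[..., None], hi, axis=-1)
    return out


def compute_loss(
    level_outs: list[dict],
    proto: Tensor,
    batch_targets: list[dict],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> tuple[Tensor, dict[str, float]]:
    """Total training loss for one batch plus per-component values.

    ``batch_targets[b]`` holds ``boxes`` (n,4 xyxy px) and ``masks``
    (n, Hp, Wp) binary instance masks at prototype resolution.
    """
    reg_max = model_cfg.dfl_bins
    anchors, strides = make_anchors(model_cfg.image_size)
    A = anchors.shape[0]
    box_all = _flatten_levels(level_outs, "box")  # (B, A, 4*reg_max)
    cls_all = _flatten_levels(level_outs, "cls")  # (B, A, nc)
    coef_all = _flatten_levels(level_outs, "coef")  # (B, A, nm)
    B = box_all.shape[0]
    hp, wp = proto.shape[2], proto.shape[3]
    proto_stride = model_cfg.image_size // hp

    total = None
    comps = {"box": 0.0, "cls": 0.0, "dfl": 0.0, "mask": 0.0}
    for b in range(B):
        tgt = batch_targets[b]
        gt_boxes = np.asarray(tgt["boxes"], dtype=np.float64).reshape(-1, 4)
        box_b = ag.reshape(ag.narrow(box_all, 0, b, 1), (A, 4 * reg_max))
        cls_b = ag.reshape(ag.narrow(cls_all, 0, b, 1), (A, model_cfg.num_classes))
        coef_b = ag.reshape(ag.narrow(coef_all, 0, b, 1), (A, model_cfg.num_prototypes))
        proto_b = ag.reshape(ag.narrow(proto, 0, b, 1), (model_cfg.num_prototypes, hp * wp))

        pred_boxes, pred_dist = decode_boxes(box_b, anchors, strides, reg_max)

        with no_grad():
            scores_np = ag.sigmoid_np(cls_b.data[:, 0].astype(np.float64))
            assign = assign_targets(
                scores_np, pred_boxes.data.astype(np.float64), anchors, gt_boxes,
                train_cfg.tal_topk, train_cfg.tal_alpha, train_cfg.tal_beta,
            )
        ts = assign.target_scores
        norm = max(float(ts.sum()), 1.0)

        # classification: BCE against alignment-normalised scores, all anchors
        cls_loss = ag.div(ag.sum_(ag.bce_with_logits(cls_b, ts[:, None].astype(np.float32))), norm)

        if assign.fg_mask.any():
            w_anchor = (ts * assign.fg_mask).astype(np.float32)[:, None]
            gt_for_anchor = gt_boxes[np.maximum(assign.gt_index, 0)]
            ciou = _ciou(pred_boxes, gt_for_anchor)
            box_loss = ag.div(ag.sum_(ag.mul(ag.sub(1.0, ciou), Tensor(w_anchor))), norm)

            # DFL: two-bin interpolation of the true ltrb distance in grid units
            tdist = np.stack(
                [
                    (anchors[:, 0] - gt_for_anchor[:, 0]),
                    (anchors[:, 1] - gt_for_anchor[:, 1]),
                    (gt_for_anchor[:, 2] - anchors[:, 0]),
                    (gt_for_anchor[:, 3] - anchors[:, 1]),
                ],
                axis=1,
            ) / strides[:, None]
            dist_w = dfl_target_weights(tdist, reg_max)
            logp = ag.log_softmax(ag.reshape(box_b, (A, 4, reg_max)), axis=-1)
            dfl_per = ag.mul(ag.sum_(ag.mul(logp, Tensor(dist_w)), axis=-1), -1.0)
            dfl_loss = ag.div(ag.sum_(ag.mul(dfl_per, Tensor(np.repeat(w_anchor, 4, axis=1) / 4.0))), norm)

            # prototype-mask BCE cropped to the assigned box
            gt_masks = np.asarray(tgt["masks"], dtype=np.float32).reshape(-1, hp, wp)
            fg_idx = np.flatnonzero(assign.fg_mask)
            target_mask = np.zeros((A, hp * wp), dtype=np.float32)
            crop_w = np.zeros((A, hp * wp), dtype=np.float32)
            ys = (np.arange(hp) + 0.5) * proto_stride
            xs = (np.arange(wp) + 0.5) * proto_stride
            for i in fg_idx:
                j = assign.gt_index[i]
                target_mask[i] = gt_masks[j].ravel()
                bx = gt_boxes[j]
                inside = ((ys[:, None] >= bx[1]) & (ys[:, None] <= bx[3])
                          & (xs[None, :] >= bx[0]) & (xs[None, :] <= bx[2]))
                area = max(float(inside.sum()), 1.0)
                crop_w[i] = inside.ravel() / area
            mlogits = ag.matmul(coef_b, proto_b)  # (A, hp*wp)
            mask_bce = ag.bce_with_logits(mlogits, target_mask)
            mask_loss = ag.div(ag.sum_(ag.mul(mask_bce, Tensor(crop_w))), float(len(fg_idx)))
        else:
            zero = Tensor(np.zeros(()))
            box_loss = dfl_loss = mask_loss = zero

        img_loss = ag.add(
            ag.add(
                ag.mul(box_loss, train_cfg.lambda_box),
                ag.mul(cls_loss, train_cfg.lambda_cls),
            ),
            ag.add(
                ag.mul(dfl_loss, train_cfg.lambda_dfl),
                ag.mul(mask_loss, train_cfg.lambda_mask),
            ),
        )
        total = img_loss if total is None else ag.add(total, img_loss)
        comps["box"] += float(box_loss.data)
        comps["cls"] += float(cls_loss.data)
        comps["dfl"] += float(dfl_loss.data)
        comps["mask"] += float(mask_loss.data)

    total = ag.mul(total, 1.0 / B)
    for k in comps:
        comps[k] /= B
        if not np.isfinite(comps[k]):
            raise FloatingPointError(f"non-finite {k} loss component: {comps[k]}")
    return total, comps


# ---------------------------------------------------------------------------
# inference


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Class-agnostic non-maximum suppression; returns kept indices by score."""
    order = np.argsort(-scores)
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        iou = bbox_iou_matrix(boxes[i : i + 1], boxes[rest])[0]
        order = rest[iou <= iou_threshold]
    return np.array(keep, dtype=int)


def predict_instances(model: SegModel, image: np.ndarray) -> Prediction:
    """Segment one RGB image (H, W, 3) uint8 or float in [0, 1].

    Decodes anchor-free boxes, filters by score, applies class-agnostic NMS,
    assembles prototype masks, binarises at 0.5, and paints instances in
    ascending score order so the highest-score instance owns contested
    pixels.
    """
    cfg = model.cfg
    H = W = cfg.image_size
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 255.0
    if img.shape[:2] != (H, W):
        raise ValueError(f"expected {(H, W)} input, got {img.shape[:2]}")
    x = Tensor(img.transpose(2, 0, 1)[None])
    model.eval()
    with no_grad():
        level_outs, proto = model(x)
        box_all = _flatten_levels(level_outs, "box")
        cls_all = _flatten_levels(level_outs, "cls")
        coef_all = _flatten_levels(level_outs, "coef")
    anchors, strides = make_anchors(cfg.image_size)
    A = anchors.shape[0]
    with no_grad():
        boxes_t, _ = decode_boxes(ag.reshape(box_all, (A, 4 * cfg.dfl_bins)), anchors, strides, cfg.dfl_bins)
    boxes = boxes_t.data.astype(np.float64)
    scores = ag.sigmoid_np(cls_all.data[0, :, 0].astype(np.float64))
    coefs = coef_all.data[0]
    keep = scores >= cfg.conf_threshold
    boxes, scores, coefs = boxes[keep], scores[keep], coefs[keep]
    if boxes.shape[0]:
        kept = nms(boxes, scores, cfg.nms_iou)[: cfg.max_detections]
        boxes, scores, coefs = boxes[kept], scores[kept], coefs[kept]

    proto_np = proto.data[0]  # (nm, hp, wp)
    hp, wp = proto_np.shape[1:]
    up = H // hp
    labels = np.zeros((H, W), dtype=np.int32)
    n = boxes.shape[0]
    final_boxes, final_scores, final_coefs = [], [], []
    if n:
        mask_logits = coefs @ proto_np.reshape(cfg.num_prototypes, -1)
        masks = ag.sigmoid_np(mask_logits).reshape(n, hp, wp)
        masks_full = masks.repeat(up, axis=1).repeat(up, axis=2)
        order = np.argsort(-scores)  # descending for reporting
        # paint ascending so the highest score is painted last and wins
        next_id = 0
        id_of = {}
        for i in order[::-1]:
            m = masks_full[i] > 0.5
            x1, y1, x2, y2 = boxes[i]
            crop = np.zeros_like(m)
            xs1, ys1 = max(int(np.floor(x1)), 0), max(int(np.floor(y1)), 0)
            xs2, ys2 = min(int(np.ceil(x2)), W), min(int(np.ceil(y2)), H)
            if xs2 > xs1 and ys2 > ys1:
                crop[ys1:ys2, xs1:xs2] = m[ys1:ys2, xs1:xs2]
            if crop.any():
                if i not in id_of:
                    next_id += 1
                    id_of[i] = next_id
                labels[crop] = id_of[i]
        survivors = [i for i in order if i in id_of and np.any(labels == id_of[i])]
        # relabel so ids follow descending score and drop fully overpainted ones
        relabel = np.zeros(next_id + 1, dtype=np.int32)
        for new_id, i in enumerate(survivors, start=1):
            relabel[id_of[i]] = new_id
            final_boxes.append(boxes[i])
            final_scores.append(scores[i])
            final_coefs.append(coefs[i])
        labels = relabel[labels]
    return Prediction(
        boxes=np.array(final_boxes).reshape(-1, 4),
        scores=np.array(final_scores),
        coefficients=np.array(final_coefs).reshape(-1, cfg.num_prototypes),
        prototypes=proto_np,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# training


def _clip_grad_norm(params, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad.astype(np.float64) ** 2))
    norm = float(np.sqrt(total))
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


@dataclass
class TrainLog:
    epochs: list[dict] = field(default_factory=list)
    best_sbd: float = -1.0
    best_epoch: int = -1


def _targets_from_labels(labels: np.ndarray, proto_hw: tuple[int, int]) -> dict:
    """Ground-truth boxes and prototype-resolution masks from a label map."""
    ids = metrics.instance_ids(labels)
    H, W = labels.shape
    hp, wp = proto_hw
    _, small = resize_pair(labels, labels, (hp, wp))
    boxes, masks = [], []
    for iid in ids:
        ys, xs = np.nonzero(labels == iid)
        boxes.append([xs.min(), ys.min(), xs.max() + 1, ys.max() + 1])
        masks.append((small == iid).astype(np.float32))
    if boxes:
        return {"boxes": np.array(boxes, dtype=np.float64), "masks": np.stack(masks)}
    return {"boxes": np.zeros((0, 4)), "masks": np.zeros((0, hp, wp), dtype=np.float32)}


def _prepare_batch(
    samples: list[tuple[np.ndarray, PolygonAnnotationSet]],
    idxs: np.ndarray,
    pool: list,
    aug_cfg: AugmentConfig,
    use_mosaic: bool,
    rng: np.random.Generator,
    model_cfg: ModelConfig,
) -> tuple[np.ndarray, list[dict]]:
    S = model_cfg.image_size
    hp = wp = S // 4
    imgs, targets = [], []
    for i in idxs:
        img, ann = apply_stack(samples[i], pool, aug_cfg, rng, use_mosaic=use_mosaic)
        if img.shape[0] != S:
            img, _ = resize_pair(img, np.zeros(img.shape[:2], np.int32), S)
        labels = polygons_to_mask(ann, S, S)
        imgs.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
        targets.append(_targets_from_labels(labels, (hp, wp)))
    return np.stack(imgs), targets


def evaluate_model(model: SegModel, samples: list) -> metrics.MetricReport:
    """Run inference over (image, annotation) samples and score against the
    rasterised ground truth."""
    S = model.cfg.image_size
    pairs = []
    for img, ann in samples:
        gt = polygons_to_mask(ann, S, S)
        pred = predict_instances(model, img)
        pairs.append((pred.labels, gt))
    return metrics.evaluate_dataset(pairs)


def train(
    model: SegModel,
    train_samples: list[tuple[np.ndarray, PolygonAnnotationSet]],
    val_samples: list[tuple[np.ndarray, PolygonAnnotationSet]],
    cfg: TrainConfig,
    aug_cfg: AugmentConfig | None = None,
    checkpoint_path=None,
) -> TrainLog:
    """Seeded training loop with mosaic shutdown and best-SBD checkpointing.

    Mosaic augmentation is disabled for the final ``close_mosaic`` epochs.
    Validation runs every ``val_interval`` epochs; the parameters achieving
    the best validation SBD are restored into ``model`` on return.
    """
    if not train_samples:
        raise ValueError("empty training set")
    aug_cfg = aug_cfg or AugmentConfig()
    rng = np.random.default_rng(cfg.seed)
    params = list(model.parameters())
    opt = SGD(params, lr=cfg.lr0, momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    n = len(train_samples)
    steps_per_epoch = max(n // cfg.batch_size, 1)
    total_steps = cfg.epochs * steps_per_epoch
    warmup_steps = max(int(cfg.warmup_epochs * steps_per_epoch), 1)
    logbook = TrainLog()
    best_state = None
    step = 0
    t0 = time.time()
    for epoch in range(cfg.epochs):
        model.train()
        use_mosaic = epoch < cfg.epochs - cfg.close_mosaic
        order = rng.permutation(n)
        epoch_losses = []
        for s in range(steps_per_epoch):
            idxs = order[s * cfg.batch_size : (s + 1) * cfg.batch_size]
            if idxs.size == 0:
                continue
            # linear warmup then linear decay to lr0 * lrf
            if step < warmup_steps:
                lr = cfg.lr0 * (step + 1) / warmup_steps
            else:
                frac = (step - warmup_steps) / max(total_steps - warmup_steps, 1)
                lr = cfg.lr0 * (1.0 - frac * (1.0 - cfg.lrf))
            opt.lr = lr
            imgs, targets = _prepare_batch(
                train_samples, idxs, train_samples, aug_cfg, use_mosaic, rng, model.cfg
            )
            level_outs, proto = model(Tensor(imgs))
            loss, comps = compute_loss(level_outs, proto, targets, model.cfg, cfg)
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip > 0:
                _clip_grad_norm(params, cfg.grad_clip)
            opt.step()
            epoch_losses.append(float(loss.data))
            step += 1
        entry = {
            "epoch": epoch,
            "loss": float(np.mean(epoch_losses)) if epoch_losses else float("nan"),
            "lr": opt.lr,
            "mosaic": bool(use_mosaic),
            "time": time.time() - t0,
        }
        if val_samples and (epoch + 1) % cfg.val_interval == 0:
            report = evaluate_model(model, val_samples)
            entry["val"] = dict(report.aggregate)
            sbd = report.aggregate["SBD"]
            if sbd > logbook.best_sbd:
                logbook.best_sbd = sbd
                logbook.best_epoch = epoch
                best_state = copy.deepcopy(model.state_dict())
                if checkpoint_path is not None:
                    save_checkpoint(model, checkpoint_path)
        logbook.epochs.append(entry)
        log.info("epoch %d: loss %.4f lr %.4g%s", epoch, entry["loss"], entry["lr"],
                 f" val SBD {entry['val']['SBD']*100:.2f}" if "val" in entry else "")
    if best_state is not None:
        model.load_state_dict(best_state)
    return logbook


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: SegModel, path) -> None:
    """Self-describing checkpoint: config JSON + every array, one npz."""
    state = model.state_dict()
    np.savez(path, __config__=np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> SegModel:
    data = np.load(path)
    cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
    model = build_model(cfg)
    state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model
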