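"""Building blocks of the segmentation networks.

* :class:`C2f` — split/concatenate bottleneck block: the input is projected
  and split into two halves, ``n`` bottlenecks run sequentially on one half
  with every intermediate retained, and all retained maps are concatenated
  and projected, giving a richer gradient flow than the older C3 design.
* :class:`GhostConv` — efficient convolution producing a few *intrinsic*
  feature maps by a dense primary convolution and the remaining *ghost*
  maps by a cheap per-channel (depthwise) transform, here a 5×5 kernel.
* Fast normalised weighted fusion — the BiFPN combination rule
  ``Conv((Σ wᵢ·xᵢ) / (Σ wᵢ + ε))`` with learnable non-negative scalar
  weights, used for the top-down transition nodes (two inputs) and the
  bottom-up output nodes (three inputs, including the same-level skip).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor
from .nn import Conv, Identity, MaxPool, Module

__all__ = [
    "Bottleneck",
    "C2f",
    "SPPF",
    "GhostConfig",
    "GhostConv",
    "ghost_param_count",
    "dense_param_count",
    "FusionWeights",
    "fuse_weighted",
    "bifpn_fuse_td",
    "bifpn_fuse_out",
    "WeightedFusion",
]


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, e=0.5, k=(3, 3)):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, k[0], 1)
        self.cv2 = Conv(c_, c2, k[1], 1)
        self.add = shortcut and c1 == c2

    def forward(self, x: Tensor) -> Tensor:
        out = self.cv2(self.cv1(x))
        return ag.add(x, out) if self.add else out


class C2f(Module):
    """Split + sequential bottlenecks with all intermediates concatenated.

    The 1×1 input projection emits ``2·c`` channels split into two halves;
    ``n`` bottlenecks transform one half in sequence, every output is kept,
    and the ``(2 + n)·c``-channel concatenation is projected to ``c2``.
    """

    def __init__(self, c1, c2, n=1, shortcut=False, e=0.5):
        super().__init__()
        self.c = int(c2 * e)
        if self.c < 1:
            raise ValueError("C2f hidden width must be >= 1")
        self.cv1 = Conv(c1, 2 * self.c, 1, 1)
        self.cv2 = Conv((2 + n) * self.c, c2, 1, 1)
        self.m = [Bottleneck(self.c, self.c, shortcut, e=1.0) for _ in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        parts = [ag.narrow(y, 1, 0, self.c), ag.narrow(y, 1, self.c, self.c)]
        for block in self.m:
            parts.append(block(parts[-1]))
        return self.cv2(ag.concat(parts, axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5×5 max pools."""

    def __init__(self, c1, c2, k=5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv(c_ * 4, c2, 1, 1)
        self.pool = MaxPool(k, 1, k // 2)

    def forward(self, x: Tensor) -> Tensor:
        y0 = self.cv1(x)
        y1 = self.pool(y0)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        return self.cv2(ag.concat([y0, y1, y2, y3], axis=1))


# ---------------------------------------------------------------------------
# Ghost module


@dataclass
class GhostConfig:
    """Ghost-module geometry.

    ``ratio`` (s) controls how many output channels come from the dense
    primary convolution: ``intrinsic = ceil(out / s)``; the remaining ghost
    maps are produced by a cheap depthwise convolution of ``cheap_kernel``
    size (5 by default) applied to the intrinsic maps.
    """

    in_channels: int
    out_channels: int
    ratio: int = 2
    primary_kernel: int = 1
    cheap_kernel: int = 5
    stride: int = 1

    def __post_init__(self):
        if self.ratio < 1:
            raise ValueError(f"ghost ratio must be >= 1, got {self.ratio}")
        if self.cheap_kernel % 2 == 0:
            raise ValueError("cheap kernel must be odd")

    @property
    def intrinsic(self) -> int:
        return math.ceil(self.out_channels / self.ratio)


class GhostConv(Module):
    """Ghost convolution: dense primary maps + cheap depthwise ghost maps.

    Output = concat(intrinsic, ghost) truncated to ``out_channels``.  With
    ``ratio == 1`` the layer degenerates to the primary convolution alone.
    Both convolutions carry batch norm + SiLU.
    """

    def __init__(self, cfg: GhostConfig):
        super().__init__()
        self.cfg = cfg
        c_ = cfg.intrinsic
        self.primary = Conv(cfg.in_channels, c_, cfg.primary_kernel, cfg.stride)
        if cfg.ratio > 1:
            mult = cfg.ratio - 1  # ghost maps per intrinsic map
            self.cheap = Conv(c_, c_ * mult, cfg.cheap_kernel, 1, g=c_)
        else:
            self.cheap = None

    def forward(self, x: Tensor) -> Tensor:
        intrinsic = self.primary(x)
        if self.cheap is None:
            return intrinsic
        ghost = self.cheap(intrinsic)
        out = ag.concat([intrinsic, ghost], axis=1)
        return ag.narrow(out, 1, 0, self.cfg.out_channels)

    def conv_weight_count(self) -> int:
        """Trainable convolution-kernel parameters (batch-norm affine excluded)."""
        n = int(self.primary.weight.data.size)
        if self.cheap is not None:
            n += int(self.cheap.weight.data.size)
        return n


def ghost_param_count(cfg: GhostConfig) -> int:
    """Closed-form convolution-kernel parameter count of a Ghost module:
    ``k_p²·c_in·⌈c_out/s⌉  +  (s−1)·⌈c_out/s⌉·k_cheap²``.

    Strictly below :func:`dense_param_count` whenever ``s ≥ 2`` and
    ``c_in · k_p² > k_cheap²`` — i.e. for every substitution site in these
    networks, where input widths far exceed the 5×5 cheap kernel's 25
    weights."""
    c_ = cfg.intrinsic
    n = cfg.primary_kernel**2 * cfg.in_channels * c_
    if cfg.ratio > 1:
        n += (cfg.ratio - 1) * c_ * cfg.cheap_kernel**2
    return n


def dense_param_count(cfg: GhostConfig) -> int:
    """Kernel parameters of the dense convolution the Ghost module replaces."""
    return cfg.primary_kernel**2 * cfg.in_channels * cfg.out_channels


# ---------------------------------------------------------------------------
# BiFPN fast normalised fusion


class FusionWeights(Module):
    """Learnable per-input scalars for fast normalised fusion.

    Effective weights are ``max(raw, 0)``; the normaliser adds a small
    ``eps`` so the coefficients sum to ``Σw / (Σw + ε) < 1`` and gradients
    never vanish at the origin.
    """

    def __init__(self, n_inputs: int, eps: float = 1e-4, init: float = 1.0):
        super().__init__()
        if n_inputs < 2:
            raise ValueError("fusion needs at least two inputs")
        self.raw = Parameter(np.full(n_inputs, init, dtype=np.float32))
        self.eps = float(eps)

    def normalized(self) -> list[Tensor]:
        w = ag.relu(self.raw)
        denom = ag.add(ag.sum_(w), self.eps)
        return [ag.div(ag.narrow(w, 0, i, 1), denom) for i in range(self.raw.data.size)]


def fuse_weighted(inputs: list[Tensor], weights: FusionWeights, conv: Module | None = None) -> Tensor:
    """``Conv((Σ wᵢ·xᵢ) / (Σ wᵢ + ε))`` — the BiFPN combination rule.

    ``conv`` defaults to the identity so the arithmetic can be checked in
    isolation; inputs must already share resolution and channel count.
    """
    if len(inputs) != weights.raw.data.size:
        raise ValueError(f"{len(inputs)} inputs but {weights.raw.data.size} weights")
    shapes = {tuple(x.shape) for x in inputs}
    if len(shapes) != 1:
        raise ValueError(f"fusion inputs must share a shape, got {sorted(shapes)}")
    coeffs = weights.normalized()
    acc = ag.mul(inputs[0], ag.reshape(coeffs[0], ()))
    for x, c in zip(inputs[1:], coeffs[1:]):
        acc = ag.add(acc, ag.mul(x, ag.reshape(c, ())))
    return acc if conv is None else conv(acc)


def bifpn_fuse_td(p_in_i: Tensor, p_in_next: Tensor, weights: FusionWeights,
                  conv: Module | None = None) -> Tensor:
    """Top-down transition node: fuses the level input with the (already
    upsampled) next-deeper level input."""
    return fuse_weighted([p_in_i, p_in_next], weights, conv)


def bifpn_fuse_out(p_in_i: Tensor, p_td_i: Tensor, p_out_prev: Tensor,
                   weights: FusionWeights, conv: Module | None = None) -> Tensor:
    """Bottom-up output node: fuses the same-level input (skip connection),
    the same-level transition feature, and the (already downsampled)
    previous-level output."""
    return fuse_weighted([p_in_i, p_td_i, p_out_prev], weights, conv)


class WeightedFusion(Module):
    """Graph node: harmonise channels (1×1 convs), fuse, then 3×3 conv.

    Used by the BiFPN-neck variant wherever the standard neck concatenates.
    """

    def __init__(self, in_channels: list[int], out_channels: int, eps: float = 1e-4):
        super().__init__()
        self.laterals = [
            Identity() if c == out_channels else Conv(c, out_channels, 1, 1)
            for c in in_channels
        ]
        self.weights = FusionWeights(len(in_channels), eps=eps)
        self.conv = Conv(out_channels, out_channels, 3, 1)

    def forward(self, inputs: list[Tensor]) -> Tensor:
        xs = [lat(x) for lat, x in zip(self.laterals, inputs)]
        return fuse_weighted(xs, self.weights, self.conv)
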