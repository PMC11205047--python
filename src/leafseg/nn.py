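"""Neural-network layers and optimisation on top of :mod:`leafseg.autograd`.

Provides the conventions shared by every block in this package: a ``Conv``
is convolution + batch norm + SiLU unless configured otherwise, parameters
are float32, and initialisation is Kaiming-style scaled by fan-in.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor

__all__ = ["Module", "Conv", "Upsample", "MaxPool", "Identity", "Sequential", "SGD"]


class Module:
    """Base class: parameter discovery, train/eval mode, parameter counting."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        seen = set()
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    yield v

    def num_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        self._collect_state("", out)
        return out

    def _collect_state(self, prefix: str, out: dict):
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                v._collect_state(key + ".", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_state(f"{key}.{i}.", out)

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = {}
        self._collect_refs("", own)
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in checkpoint: {sorted(missing)[:5]} ...")
        for key, ref in own.items():
            holder, attr_or_arr = ref
            arr = np.asarray(state[key])
            if isinstance(attr_or_arr, str):
                getattr(holder, attr_or_arr).data[...] = arr
            else:
                attr_or_arr[...] = arr

    def _collect_refs(self, prefix: str, out: dict):
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out[key] = (self, name)
            elif isinstance(v, np.ndarray):
                out[key] = (self, v)
            elif isinstance(v, Module):
                v._collect_refs(key + ".", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_refs(f"{key}.{i}.", out)


def _autopad(k: int, p: int | None) -> int:
    return k // 2 if p is None else p


_init_rng = np.random.default_rng(0)


def set_init_seed(seed: int) -> None:
    """Reseed weight initialisation (one seed drives all subsequent builds)."""
    global _init_rng
    _init_rng = np.random.default_rng(seed)


def kaiming(shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (_init_rng.standard_normal(shape) * std).astype(np.float32)


class Conv(Module):
    """Convolution + (optional) batch norm + (optional) SiLU activation."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, act=True, bn=True, bias=None):
        super().__init__()
        self.c1, self.c2, self.k, self.s, self.g = c1, c2, k, s, g
        self.p = _autopad(k, p)
        self.act = act
        self.use_bn = bn
        fan_in = (c1 // g) * k * k
        self.weight = Parameter(kaiming((c2, c1 // g, k, k), fan_in))
        use_bias = (not bn) if bias is None else bias
        self.bias = Parameter(np.zeros(c2, dtype=np.float32)) if use_bias else None
        if bn:
            self.gamma = Parameter(np.ones(c2, dtype=np.float32))
            self.beta = Parameter(np.zeros(c2, dtype=np.float32))
            self.running_mean = np.zeros(c2, dtype=np.float32)
            self.running_var = np.ones(c2, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        out = ag.conv2d(x, self.weight, self.bias, self.s, self.p, self.g)
        if self.use_bn:
            out = ag.batch_norm(
                out, self.gamma, self.beta, self.running_mean, self.running_var, self.training
            )
        if self.act:
            out = ag.silu(out)
        return out


class Upsample(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.upsample_nearest2x(x)


class MaxPool(Module):
    def __init__(self, k=5, s=1, p=2):
        super().__init__()
        self.k, self.s, self.p = k, s, p

    def forward(self, x: Tensor) -> Tensor:
        return ag.max_pool2d(x, self.k, self.s, self.p)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class SGD:
    """SGD with momentum and optional weight decay on conv/linear weights."""

    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
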