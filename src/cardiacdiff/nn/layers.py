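"""Neural-network layers on top of the autograd engine.

Initialisation is driven by an explicit ``numpy.random.Generator`` so that two
builds from the same config and seed are bit-identical.  Zero-initialised
parameters (biases, modulation heads, final output convs) draw nothing from
the generator, which keeps parameter streams aligned between closely related
architectures (e.g. a conditional backbone and its unconditional twin).
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        self.requires_grad = True  # parameters require grad even under no_grad


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            params.extend(_collect(v, seen))
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, sd: dict):
        params = self.parameters()
        if len(sd) != len(params):
            raise ValueError(f"state dict has {len(sd)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = np.asarray(sd[str(i)], dtype=np.float32)
            if arr.shape != p.shape:
                raise ValueError(f"parameter {i} shape mismatch: {arr.shape} vs {p.shape}")
            p.data = arr.copy()

    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


def _collect(v, seen: set[int]) -> list[Parameter]:
    out: list[Parameter] = []
    if isinstance(v, Parameter):
        if id(v) not in seen:
            seen.add(id(v))
            out.append(v)
    elif isinstance(v, Module):
        for p in v.parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
    elif isinstance(v, (list, tuple)):
        for item in v:
            out.extend(_collect(item, seen))
    return out


class ModuleList(Module):
    def __init__(self, mods: Iterable[Module] = ()):  # noqa: D401
        self.mods = list(mods)

    def append(self, m: Module):
        self.mods.append(m)

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]

    def __len__(self):
        return len(self.mods)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 padding: Optional[int] = None, rng: Optional[np.random.Generator] = None,
                 zero_init: bool = False):
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        if zero_init:
            w = np.zeros((cout, cin, k, k), dtype=np.float32)
        else:
            w = he_init(rng, (cout, cin, k, k), cin * k * k)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: Optional[np.random.Generator] = None,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((cin, cout), dtype=np.float32)
        else:
            w = he_init(rng, (cin, cout), cin)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def forward(self, x):
        return ag.matmul(x, self.weight) + self.bias


def group_norm(x, groups: int, eps: float = 1e-5):
    """Parameter-free group normalisation over (B, C, H, W)."""
    B, C, H, W = x.shape
    if C % groups:
        raise ValueError(f"channels {C} not divisible by {groups} groups")
    xr = ag.reshape(x, (B, groups, C // groups * H * W))
    mu = ag.tmean(xr, axis=2, keepdims=True)
    xc = xr - mu
    var = ag.tmean(xc * xc, axis=2, keepdims=True)
    xn = xc / ag.sqrt(var + eps)
    return ag.reshape(xn, (B, C, H, W))


class GroupNorm(Module):
    """Group normalisation with learned per-channel scale and shift."""

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        self.groups = groups
        self.eps = eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, channels, 1, 1), dtype=np.float32))

    def forward(self, x):
        return group_norm(x, self.groups, self.eps) * self.gamma + self.beta


class SelfAttention2d(Module):
    """Single-head self-attention over spatial positions of a feature map."""

    def __init__(self, channels: int, norm_groups: int, rng: np.random.Generator):
        self.norm = GroupNorm(norm_groups, channels)
        self.q = Conv2d(channels, channels, k=1, rng=rng)
        self.k = Conv2d(channels, channels, k=1, rng=rng)
        self.v = Conv2d(channels, channels, k=1, rng=rng)
        self.proj = Conv2d(channels, channels, k=1, rng=rng)
        self.scale = channels ** -0.5

    def forward(self, x):
        B, C, H, W = x.shape
        h = self.norm(x)
        q = ag.reshape(self.q(h), (B, C, H * W))
        k = ag.reshape(self.k(h), (B, C, H * W))
        v = ag.reshape(self.v(h), (B, C, H * W))
        attn = ag.softmax(ag.matmul(ag.transpose(q, (0, 2, 1)), k) * self.scale, axis=-1)
        out = ag.matmul(v, ag.transpose(attn, (0, 2, 1)))  # (B,C,HW)
        out = ag.reshape(out, (B, C, H, W))
        return x + self.proj(out)


def timestep_embedding(t, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Sinusoidal timestep features: [sin(t/p^(2i/dim)), cos(...)], dim even."""
    if dim % 2:
        raise ValueError("embedding dim must be even")
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half, dtype=np.float64) / half)
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    return emb.astype(np.float32)
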