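"""Configurable U-Net noise predictor ε_θ(y_t, t[, mask]).

The encoder is a stack of residual blocks (with self-attention at the deeper
levels); the decoder mirrors it with skip connections.  In the conditional
variant the decoder's residual blocks replace their learned group-norm affine
with SPADE modulation: per-pixel scale and shift maps predicted from the
(resized) one-hot conditioning mask.  SPADE γ/β output convolutions are
zero-initialised, so at initialisation the conditional network computes
exactly the same function as its unconditional twin — conditioning is learned,
never imposed.

Architecture parameters are deliberately explicit: the production-scale mask
model uses 6 levels with widths (64, 128, 256, 512, 1024, 1024), two residual
blocks per level and attention on the last three levels; tests use narrow
3-level toys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import (Conv2d, GroupNorm, Linear, Module, ModuleList,
                        SelfAttention2d, group_norm, timestep_embedding)


@dataclass(frozen=True)
class BackboneConfig:
    n_levels: int = 6
    channels: tuple = (64, 128, 256, 512, 1024, 1024)
    resblocks_per_level: int = 2
    attention_levels: tuple = (4, 5, 6)  # 1-based level indices
    norm_groups: int = 32
    conditional: bool = False
    in_channels: int = 4
    out_channels: int = 4
    cond_channels: int = 4

    def __post_init__(self):
        if len(self.channels) != self.n_levels:
            raise ValueError("channels must list one width per level")
        if any(not 1 <= a <= self.n_levels for a in self.attention_levels):
            raise ValueError("attention_levels must be within 1..n_levels")
        for c in self.channels:
            if c % self.norm_groups:
                raise ValueError(f"norm_groups={self.norm_groups} does not divide width {c}")

    def to_dict(self) -> dict:
        return {"n_levels": self.n_levels, "channels": list(self.channels),
                "resblocks_per_level": self.resblocks_per_level,
                "attention_levels": list(self.attention_levels),
                "norm_groups": self.norm_groups, "conditional": self.conditional,
                "in_channels": self.in_channels, "out_channels": self.out_channels,
                "cond_channels": self.cond_channels}

    @staticmethod
    def from_dict(d: dict) -> "BackboneConfig":
        d = dict(d)
        for key in ("channels", "attention_levels"):
            if key in d:
                d[key] = tuple(d[key])
        return BackboneConfig(**d)


def toy_config(channels=(8, 16, 32), attention_levels=(3,), conditional=False,
               in_channels=4, out_channels=4, norm_groups=4, cond_channels=4) -> BackboneConfig:
    """Small 3-level config for CPU-scale experiments and tests."""
    return BackboneConfig(n_levels=len(channels), channels=tuple(channels),
                          resblocks_per_level=2, attention_levels=tuple(attention_levels),
                          norm_groups=norm_groups, conditional=conditional,
                          in_channels=in_channels, out_channels=out_channels,
                          cond_channels=cond_channels)


class SpadeHead(Module):
    """Two-convolution head mapping a one-hot mask to per-pixel γ and β maps."""

    def __init__(self, cond_channels: int, out_ch: int, norm_groups: int,
                 rng: np.random.Generator, hidden: int = 32):
        hidden = max(norm_groups, hidden - hidden % norm_groups)
        self.shared = Conv2d(cond_channels, hidden, k=3, rng=rng)
        self.to_gamma = Conv2d(hidden, out_ch, k=3, zero_init=True)
        self.to_beta = Conv2d(hidden, out_ch, k=3, zero_init=True)
        self.norm_groups = norm_groups

    def forward(self, mask_resized):
        h = ag.silu(self.shared(mask_resized))
        return self.to_gamma(h), self.to_beta(h)


def resize_mask_to(mask_onehot: np.ndarray, target_hw: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize of a (..., H, W) one-hot mask by a power of 2.

    Downscaling takes the top-left source pixel of each block; upscaling
    replicates pixels.  One-hotness is preserved exactly.
    """
    H, W = mask_onehot.shape[-2:]
    th, tw = target_hw
    for src, dst in ((H, th), (W, tw)):
        ratio = max(src, dst) / min(src, dst)
        if ratio != int(ratio) or (int(ratio) & (int(ratio) - 1)):
            if ratio != 1:
                raise ValueError(f"resize ratio {src}->{dst} is not a power of 2")
    if th >= H:
        out = mask_onehot.repeat(th // H, axis=-2).repeat(tw // W, axis=-1)
    else:
        out = mask_onehot[..., :: H // th, :: W // tw]
    return out


def spade_modulate(features, mask_onehot: np.ndarray, head: SpadeHead):
    """out = GN(h)·(1 + γ(m)) + β(m) with parameter-free group normalisation."""
    feats = features if isinstance(features, Tensor) else Tensor(np.asarray(features, dtype=np.float32))
    if mask_onehot.shape[-2:] != feats.shape[-2:]:
        raise ValueError(f"mask resolution {mask_onehot.shape[-2:]} != features {feats.shape[-2:]}")
    m = Tensor(np.asarray(mask_onehot, dtype=np.float32))
    gamma, beta = head(m)
    normed = group_norm(feats, head.norm_groups)
    return normed * (gamma + 1.0) + beta


class ResBlock(Module):
    """Pre-activation residual block with timestep injection.

    With ``spade=True`` both normalisations are SPADE-modulated (decoder
    blocks of the conditional model); otherwise they are learned-affine
    group norms.
    """

    def __init__(self, cin: int, cout: int, t_dim: int, groups: int,
                 rng: np.random.Generator, spade: bool = False,
                 cond_channels: int = 4, rng_cond: Optional[np.random.Generator] = None):
        self.spade = spade
        if spade:
            self.head1 = SpadeHead(cond_channels, cin, groups, rng_cond)
            self.head2 = SpadeHead(cond_channels, cout, groups, rng_cond)
        else:
            self.norm1 = GroupNorm(groups, cin)
            self.norm2 = GroupNorm(groups, cout)
        self.conv1 = Conv2d(cin, cout, k=3, rng=rng)
        self.temb = Linear(t_dim, cout, rng=rng)
        self.conv2 = Conv2d(cout, cout, k=3, rng=rng)
        self.skip = Conv2d(cin, cout, k=1, rng=rng) if cin != cout else None
        self.groups = groups

    def forward(self, x, temb, cond=None):
        if self.spade:
            h = spade_modulate(x, cond, self.head1)
        else:
            h = self.norm1(x)
        h = self.conv1(ag.silu(h))
        tproj = self.temb(ag.silu(temb))
        B, C = tproj.shape
        h = h + ag.reshape(tproj, (B, C, 1, 1))
        if self.spade:
            h = spade_modulate(h, cond, self.head2)
        else:
            h = self.norm2(h)
        h = self.conv2(ag.silu(h))
        skip = x if self.skip is None else self.skip(x)
        return skip + h


class UNetDenoiser(Module):
    """The ε_θ network: (B,C,H,W), timesteps, optional one-hot mask → (B,C,H,W)."""

    def __init__(self, cfg: BackboneConfig, seed: int = 0):
        self.cfg = cfg
        root = np.random.default_rng(seed)
        rng, rng_cond = root.spawn(2)
        ch = cfg.channels
        g = cfg.norm_groups
        self.emb_base = max(32, ch[0])  # sinusoid features; >=16 frequencies
        tdim = 4 * self.emb_base
        self.tdim = tdim
        self.t_in = Linear(self.emb_base, tdim, rng=rng)
        self.t_out = Linear(tdim, tdim, rng=rng)
        self.conv_in = Conv2d(cfg.in_channels, ch[0], k=3, rng=rng)

        self.enc_blocks = ModuleList()
        self.enc_attn = ModuleList()
        self.downs = ModuleList()
        for i in range(cfg.n_levels):
            level = ModuleList()
            attns = ModuleList()
            cin = ch[i - 1] if i > 0 else ch[0]
            for r in range(cfg.resblocks_per_level):
                level.append(ResBlock(cin if r == 0 else ch[i], ch[i], tdim, g, rng))
                attns.append(SelfAttention2d(ch[i], g, rng)
                             if (i + 1) in cfg.attention_levels else None)
            self.enc_blocks.append(level)
            self.enc_attn.append(attns)
            if i < cfg.n_levels - 1:
                self.downs.append(Conv2d(ch[i], ch[i], k=3, stride=2, rng=rng))

        self.mid1 = ResBlock(ch[-1], ch[-1], tdim, g, rng)
        self.mid_attn = SelfAttention2d(ch[-1], g, rng)
        self.mid2 = ResBlock(ch[-1], ch[-1], tdim, g, rng)

        spade = cfg.conditional
        self.dec_blocks = ModuleList()
        self.dec_attn = ModuleList()
        self.ups = ModuleList()
        for i in reversed(range(cfg.n_levels)):
            level = ModuleList()
            attns = ModuleList()
            for r in range(cfg.resblocks_per_level):
                cin = ch[i] * 2 if r == 0 else ch[i]  # skip concat on first block
                level.append(ResBlock(cin, ch[i], tdim, g, rng, spade=spade,
                                      cond_channels=cfg.cond_channels, rng_cond=rng_cond))
                attns.append(SelfAttention2d(ch[i], g, rng)
                             if (i + 1) in cfg.attention_levels else None)
            self.dec_blocks.append(level)
            self.dec_attn.append(attns)
            if i > 0:
                self.ups.append(Conv2d(ch[i], ch[i - 1], k=3, rng=rng))

        self.norm_out = GroupNorm(g, ch[0])
        self.conv_out = Conv2d(ch[0], cfg.out_channels, k=3, rng=rng)
        # damp the initial output so training starts near eps_hat ~ 0 while
        # every parameter still receives gradient from the first step
        self.conv_out.weight.data *= 0.1

    # -- forward ------------------------------------------------------------
    def forward(self, x, t, cond: Optional[np.ndarray] = None):
        cfg = self.cfg
        if cfg.conditional and cond is None:
            raise ValueError("conditional backbone requires a conditioning mask")
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        B, C, H, W = x.shape
        if H % (1 << (cfg.n_levels - 1)) or W % (1 << (cfg.n_levels - 1)):
            raise ValueError(f"spatial size {H}x{W} not divisible by 2^{cfg.n_levels - 1}")
        temb = Tensor(timestep_embedding(t, self.emb_base))
        temb = self.t_out(ag.silu(self.t_in(temb)))

        h = self.conv_in(x)
        skips = []
        for i in range(cfg.n_levels):
            for r, block in enumerate(self.enc_blocks[i]):
                h = block(h, temb)
                if self.enc_attn[i][r] is not None:
                    h = self.enc_attn[i][r](h)
            skips.append(h)
            if i < cfg.n_levels - 1:
                h = self.downs[i](h)

        h = self.mid1(h, temb)
        h = self.mid_attn(h)
        h = self.mid2(h, temb)

        for j, i in enumerate(reversed(range(cfg.n_levels))):
            cond_i = None
            if cfg.conditional:
                cond_i = resize_mask_to(np.asarray(cond, dtype=np.float32), h.shape[-2:])
            h = ag.concat([h, skips[i]], axis=1)
            for r, block in enumerate(self.dec_blocks[j]):
                h = block(h, temb, cond=cond_i)
                if self.dec_attn[j][r] is not None:
                    h = self.dec_attn[j][r](h)
            if i > 0:
                h = self.ups[j](ag.upsample_nearest2x(h))

        h = ag.silu(self.norm_out(h))
        return self.conv_out(h)


def build_denoiser(cfg: BackboneConfig, seed: int = 0) -> UNetDenoiser:
    """Construct a seeded U-Net noise predictor from a config."""
    return UNetDenoiser(cfg, seed=seed)
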