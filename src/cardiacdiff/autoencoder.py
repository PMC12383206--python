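"""Perceptual-compression autoencoder for the latent diffusion stage.

A convolutional encoder E maps an image x (values in [−1, 1]) to a Gaussian
latent z = E(x) downsampled by a factor f (a power of 2); the decoder D maps
latents back to image space through a final tanh, so reconstructions are
bounded in (−1, 1).  Training minimises L1 reconstruction error plus a small
KL regulariser toward N(0, I) — a deliberately lightweight reading of
"perceptually equivalent": no adversarial or feature-space losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .nn import Adam, Tensor, no_grad
from .nn import autograd as ag
from .nn.layers import Conv2d, GroupNorm, Module, ModuleList


@dataclass(frozen=True)
class AutoencoderConfig:
    n_levels: int = 5
    channels: tuple = (64, 128, 256, 512, 1024)
    n_downsample: int = 3           # f = 2 ** n_downsample
    latent_channels: int = 4
    norm_groups: int = 64
    in_channels: int = 1
    kl_weight: float = 1e-6

    def __post_init__(self):
        if len(self.channels) != self.n_levels:
            raise ValueError("channels must list one width per level")
        if self.n_downsample >= self.n_levels:
            raise ValueError("need fewer downsamples than levels")
        for c in self.channels:
            if c % self.norm_groups:
                raise ValueError(f"norm_groups must divide width {c}")

    @property
    def factor(self) -> int:
        return 2 ** self.n_downsample

    def to_dict(self) -> dict:
        return {"n_levels": self.n_levels, "channels": list(self.channels),
                "n_downsample": self.n_downsample,
                "latent_channels": self.latent_channels,
                "norm_groups": self.norm_groups, "in_channels": self.in_channels,
                "kl_weight": self.kl_weight}

    @staticmethod
    def from_dict(d: dict) -> "AutoencoderConfig":
        d = dict(d)
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return AutoencoderConfig(**d)


def toy_ae_config(channels=(8, 16, 32), n_downsample=2, latent_channels=4,
                  norm_groups=4) -> AutoencoderConfig:
    return AutoencoderConfig(n_levels=len(channels), channels=tuple(channels),
                             n_downsample=n_downsample,
                             latent_channels=latent_channels,
                             norm_groups=norm_groups)


@dataclass(frozen=True)
class LatentCode:
    """A single latent z = E(x) with its spatial compression factor."""
    tensor: np.ndarray  # (c, h, w)
    factor: int


class _Block(Module):
    """Residual block without timestep conditioning (autoencoder variant)."""

    def __init__(self, cin, cout, groups, rng):
        self.norm1 = GroupNorm(groups, cin)
        self.conv1 = Conv2d(cin, cout, k=3, rng=rng)
        self.norm2 = GroupNorm(groups, cout)
        self.conv2 = Conv2d(cout, cout, k=3, rng=rng)
        self.skip = Conv2d(cin, cout, k=1, rng=rng) if cin != cout else None

    def forward(self, x):
        h = self.conv1(ag.silu(self.norm1(x)))
        h = self.conv2(ag.silu(self.norm2(h)))
        return (x if self.skip is None else self.skip(x)) + h


class Encoder(Module):
    def __init__(self, cfg: AutoencoderConfig, rng):
        ch = cfg.channels
        self.conv_in = Conv2d(cfg.in_channels, ch[0], k=3, rng=rng)
        self.blocks = ModuleList()
        self.downs = ModuleList()
        for i in range(cfg.n_levels):
            cin = ch[i - 1] if i > 0 else ch[0]
            self.blocks.append(ModuleList([_Block(cin if r == 0 else ch[i], ch[i],
                                                  cfg.norm_groups, rng)
                                           for r in range(2)]))
            if i < cfg.n_downsample:
                self.downs.append(Conv2d(ch[i], ch[i], k=3, stride=2, rng=rng))
            else:
                self.downs.append(None)
        self.norm_out = GroupNorm(cfg.norm_groups, ch[-1])
        self.conv_out = Conv2d(ch[-1], 2 * cfg.latent_channels, k=3, rng=rng)

    def forward(self, x):
        h = self.conv_in(x)
        for level, down in zip(self.blocks, self.downs):
            for b in level:
                h = b(h)
            if down is not None:
                h = down(h)
        return self.conv_out(ag.silu(self.norm_out(h)))  # (B, 2c, h, w)


class Decoder(Module):
    def __init__(self, cfg: AutoencoderConfig, rng):
        ch = cfg.channels
        self.conv_in = Conv2d(cfg.latent_channels, ch[-1], k=3, rng=rng)
        self.blocks = ModuleList()
        self.ups = ModuleList()
        for j, i in enumerate(reversed(range(cfg.n_levels))):
            cin = ch[i + 1] if i < cfg.n_levels - 1 else ch[-1]
            self.blocks.append(ModuleList([_Block(cin if r == 0 else ch[i], ch[i],
                                                  cfg.norm_groups, rng)
                                           for r in range(2)]))
            # mirror the encoder: upsample on the last n_downsample transitions
            if i > 0 and i <= cfg.n_downsample:
                self.ups.append(Conv2d(ch[i], ch[i], k=3, rng=rng))
            else:
                self.ups.append(None)
        self.norm_out = GroupNorm(cfg.norm_groups, ch[0])
        self.conv_out = Conv2d(ch[0], cfg.in_channels, k=3, rng=rng)

    def forward(self, z):
        h = self.conv_in(z)
        for level, up in zip(self.blocks, self.ups):
            for b in level:
                h = b(h)
            if up is not None:
                h = up(ag.upsample_nearest2x(h))
        return ag.tanh(self.conv_out(ag.silu(self.norm_out(h))))


class AutoencoderPair(Module):
    """Encoder/decoder pair; ``encode`` returns the latent mean."""

    def __init__(self, cfg: AutoencoderConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(cfg, rng)
        self.decoder = Decoder(cfg, rng)
        self.trained = False

    def encode_moments(self, x):
        """Full posterior parameters (mean, logvar), keeping the graph."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        out = self.encoder(x)
        c = self.cfg.latent_channels
        return out[:, :c], out[:, c:]

    def encode(self, x: np.ndarray) -> np.ndarray:
        """(B, 1, H, W) images -> (B, c, h, w) latent means, no gradients."""
        x = np.asarray(x, dtype=np.float32)
        if x.shape[-1] % self.cfg.factor or x.shape[-2] % self.cfg.factor:
            raise ValueError(f"image size {x.shape[-2:]} not divisible by f={self.cfg.factor}")
        with no_grad():
            mean, _ = self.encode_moments(x)
        return mean.numpy()

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float32)
        if z.shape[1] != self.cfg.latent_channels:
            raise ValueError(f"latent has {z.shape[1]} channels, expected {self.cfg.latent_channels}")
        with no_grad():
            out = self.decoder(z)
        return out.numpy()

    def encode_image(self, image: np.ndarray) -> LatentCode:
        """Single (H, W) image -> LatentCode."""
        z = self.encode(image[None, None])
        return LatentCode(tensor=z[0], factor=self.cfg.factor)

    def decode_latent(self, code: LatentCode) -> np.ndarray:
        return self.decode(code.tensor[None])[0, 0]


def build_autoencoder(cfg: AutoencoderConfig | None = None, seed: int = 0) -> AutoencoderPair:
    return AutoencoderPair(cfg or AutoencoderConfig(), seed=seed)


@dataclass
class AETrainConfig:
    steps: int = 2000
    batch_size: int = 8
    lr: float = 1e-4
    log_every: int = 50


def train_autoencoder(images: Sequence[np.ndarray], cfg: AutoencoderConfig | None = None,
                      opt_cfg: AETrainConfig | None = None, seed: int = 0):
    """Fit the autoencoder on (H, W) images; returns (model, loss history)."""
    images = list(images)
    if not images:
        raise ValueError("need at least one training image")
    if len({im.shape for im in images}) != 1:
        raise ValueError("all images must share one shape")
    cfg = cfg or AutoencoderConfig()
    opt_cfg = opt_cfg or AETrainConfig()
    data = np.stack(images).astype(np.float32)[:, None]  # (N,1,H,W)
    model = AutoencoderPair(cfg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    opt = Adam(model.parameters(), lr=opt_cfg.lr)
    history = []
    n = data.shape[0]
    for step in range(opt_cfg.steps):
        idx = rng.integers(0, n, size=min(opt_cfg.batch_size, n))
        x = Tensor(data[idx])
        mean, logvar = model.encode_moments(x)
        eps = rng.standard_normal(mean.shape).astype(np.float32)
        z = mean + ag.exp(logvar * 0.5) * Tensor(eps)
        recon = model.decoder(z)
        diff = recon - x
        l1 = ag.tmean(ag.sqrt(diff * diff + 1e-12))
        kl = ag.tmean(ag.exp(logvar) + mean * mean - 1.0 - logvar) * 0.5
        loss = l1 + cfg.kl_weight * kl
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(float(loss.data))
    model.trained = True
    return model, history


def reconstruction_mse(model: AutoencoderPair, images: Sequence[np.ndarray]) -> float:
    data = np.stack(list(images)).astype(np.float32)[:, None]
    recon = model.decode(model.encode(data))
    return float(np.mean((recon - data) ** 2))
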