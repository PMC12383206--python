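"""Stage 1: unconditional diffusion over multi-class cardiac masks.

Masks are lifted to a one-hot ±1 encoding (one channel per class, +1 where
the class is present) so that Gaussian diffusion never imposes a false
ordinal metric between class indices; samples are projected back to integer
label maps by a per-pixel argmax with ties broken toward the lowest class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import diffusion
from .backbone import BackboneConfig, build_denoiser
from .diffusion import NoiseSchedule, diffuse_batch, simple_loss
from .nn import Adam, Tensor, no_grad
from .phantoms import N_CLASSES


@dataclass
class TrainConfig:
    """Optimisation settings (Adam, lr 1e-4, batch 16 at production scale).

    ``lr_final`` enables cosine decay from ``lr`` to ``lr_final`` over the
    run, useful for short toy budgets where a high initial rate is needed.
    """
    steps: int = 2000
    batch_size: int = 16
    lr: float = 1e-4
    lr_final: Optional[float] = None
    weight_decay: float = 0.0
    ema_decay: Optional[float] = None  # e.g. 0.998; sampling uses the average
    log_every: int = 50


@dataclass
class PseudoLabelSet:
    masks: list[np.ndarray]
    model_id: str = ""
    sampler: str = "ddim"
    n_steps: int = 50
    eta: float = 0.0
    seed: int = 0

    def __len__(self):
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)


def encode_mask(mask: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """Integer label map -> (K, H, W) one-hot in {−1, +1}."""
    mask = np.asarray(mask)
    if mask.min(initial=0) < 0 or mask.max(initial=0) >= n_classes:
        raise ValueError(f"mask values must lie in 0..{n_classes - 1}")
    onehot = np.full((n_classes,) + mask.shape, -1.0, dtype=np.float32)
    for k in range(n_classes):
        onehot[k][mask == k] = 1.0
    return onehot


def decode_mask(tensor: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """(K, H, W) channel scores -> label map by argmax (ties -> lowest class)."""
    tensor = np.asarray(tensor)
    if tensor.ndim != 3 or tensor.shape[0] != n_classes:
        raise ValueError(f"expected ({n_classes}, H, W) tensor, got {tensor.shape}")
    return np.argmax(tensor, axis=0).astype(np.uint8)  # argmax returns first max


def _training_loop(model, data: np.ndarray, sched: NoiseSchedule, opt_cfg: TrainConfig,
                   seed: int, cond: Optional[np.ndarray] = None,
                   p_uncond: float = 0.0, null_cond: Optional[np.ndarray] = None):
    """Shared ε-matching loop used by the mask DDPM and the latent model."""
    rng = np.random.default_rng(seed)
    params = model.parameters()
    opt = Adam(params, lr=opt_cfg.lr, weight_decay=opt_cfg.weight_decay)
    ema = [p.data.copy() for p in params] if opt_cfg.ema_decay else None
    n = data.shape[0]
    history = []
    for step in range(opt_cfg.steps):
        if opt_cfg.lr_final is not None:
            frac = step / max(1, opt_cfg.steps - 1)
            opt.lr = opt_cfg.lr_final + 0.5 * (opt_cfg.lr - opt_cfg.lr_final) * (
                1.0 + np.cos(np.pi * frac))
        idx = rng.integers(0, n, size=min(opt_cfg.batch_size, n))
        x0 = data[idx]
        t = rng.integers(1, sched.T + 1, size=len(idx))
        eps = rng.standard_normal(x0.shape).astype(np.float32)
        xt = diffuse_batch(x0, t, eps, sched)
        if cond is not None:
            c = cond[idx].copy()
            drop = rng.random(len(idx)) < p_uncond
            if drop.any():
                c[drop] = null_cond
            pred = model(xt, t, c)
        else:
            pred = model(xt, t)
        loss = simple_loss(Tensor(eps), pred)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if ema is not None:
            d = opt_cfg.ema_decay
            for e, p in zip(ema, params):
                e *= d
                e += (1.0 - d) * p.data
        history.append(float(loss.data))
    if ema is not None:  # sampling quality: use the averaged weights
        for e, p in zip(ema, params):
            p.data = e.astype(np.float32)
    return history


def train_mask_ddpm(masks: Sequence[np.ndarray], backbone_cfg: BackboneConfig,
                    sched: NoiseSchedule, opt_cfg: TrainConfig | None = None,
                    seed: int = 0):
    """Train the unconditional mask DDPM with the simplified ε-matching loss.

    Returns (model, loss_history).  Timesteps are drawn uniformly on 1..T per
    example; the loop is bit-reproducible given data, configs and seed.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one training mask")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError("all masks must share one shape")
    data = np.stack([encode_mask(m) for m in masks])
    opt_cfg = opt_cfg or TrainConfig()
    model = build_denoiser(backbone_cfg, seed=seed)
    history = _training_loop(model, data, sched, opt_cfg, seed=seed + 1)
    return model, history


def sample_masks(model, sched: NoiseSchedule, n: int, grid_size: int,
                 sampler: str = "ddim", n_steps: int = 50, eta: float = 0.0,
                 seed: int = 0, batch: int = 16) -> PseudoLabelSet:
    """Draw n pseudo-label masks from a trained model and decode them."""
    if sampler not in ("ddpm", "ddim"):
        raise ValueError(f"unknown sampler {sampler!r}")
    K = model.cfg.in_channels
    out: list[np.ndarray] = []
    done = 0
    while done < n:
        b = min(batch, n - done)
        shape = (b, K, grid_size, grid_size)
        sub_seed = seed + 7919 * (done + 1)
        if sampler == "ddim":
            # clip intermediate x0 estimates to the ±1 one-hot range
            x = diffusion.ddim_sample(model, sched, n_steps=n_steps, eta=eta,
                                      shape=shape, seed=sub_seed, clip_x0=1.0)
        else:
            x = diffusion.ddpm_sample(model, sched, shape=shape, seed=sub_seed,
                                      clip_x0=1.0)
        out.extend(decode_mask(x[i], K) for i in range(b))
        done += b
    return PseudoLabelSet(masks=out, sampler=sampler, n_steps=n_steps,
                          eta=eta, seed=seed)
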