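"""Stage 2: mask-conditioned latent diffusion for paired image synthesis.

A diffusion model is trained on frozen-autoencoder latents z = E(x); the
conditioning mask enters only through SPADE blocks in the denoiser decoder,
resized (nearest-neighbour) to each feature resolution so hard class
boundaries survive.  Classifier-free guidance is supported by dropping the
condition to an all-background mask with probability ``p_uncond`` during
training and mixing conditional/unconditional predictions at sampling time.

Latents are standardised by a scalar scale factor (1/std over the training
latents) before diffusion, the usual practice for KL-regularised latent
spaces whose variance is not exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import diffusion
from .autoencoder import AutoencoderPair
from .backbone import BackboneConfig, build_denoiser, resize_mask_to, spade_modulate  # noqa: F401
from .diffusion import NoiseSchedule
from .mask_ddpm import PseudoLabelSet, TrainConfig, _training_loop, encode_mask
from .phantoms import N_CLASSES


def null_condition(grid_size: int, n_classes: int = N_CLASSES) -> np.ndarray:
    """All-background one-hot mask used as the classifier-free null input."""
    return encode_mask(np.zeros((grid_size, grid_size), dtype=np.uint8), n_classes)


@dataclass
class LatentDiffusionModel:
    """Denoiser plus the per-channel latent standardisation (z − μ)/σ that
    aligns the training latents with the N(0, I) sampling prior."""
    denoiser: object
    sched: NoiseSchedule
    latent_shift: np.ndarray  # (c,) per-channel mean of training latents
    latent_scale: np.ndarray  # (c,) per-channel std
    grid_size: int
    n_classes: int = N_CLASSES

    def standardize(self, z: np.ndarray) -> np.ndarray:
        return ((z - self.latent_shift[:, None, None]) /
                self.latent_scale[:, None, None]).astype(np.float32)

    def destandardize(self, z: np.ndarray) -> np.ndarray:
        return (z * self.latent_scale[:, None, None] +
                self.latent_shift[:, None, None]).astype(np.float32)

    def __call__(self, z, t, cond=None):
        if cond is None:
            cond = np.broadcast_to(null_condition(self.grid_size, self.n_classes),
                                   (np.asarray(z).shape[0], self.n_classes,
                                    self.grid_size, self.grid_size))
        return self.denoiser(z, t, cond)


def train_conditional_ldm(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                          autoencoder: AutoencoderPair,
                          backbone_cfg: BackboneConfig,
                          sched: NoiseSchedule,
                          opt_cfg: TrainConfig | None = None,
                          p_uncond: float = 0.1,
                          seed: int = 0):
    """Train ε_θ(z_t, t, mask) on frozen-encoder latents.

    ``pairs`` is a sequence of (image (H,W), mask (H,W)) tuples.  Returns
    (LatentDiffusionModel, loss history).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one (image, mask) pair")
    if not getattr(autoencoder, "trained", False):
        raise ValueError("autoencoder must be trained before LDM training")
    if not backbone_cfg.conditional:
        raise ValueError("backbone config must be conditional for the LDM")
    opt_cfg = opt_cfg or TrainConfig()
    images = np.stack([p[0] for p in pairs]).astype(np.float32)[:, None]
    grid_size = images.shape[-1]
    latents = autoencoder.encode(images)
    shift = latents.mean(axis=(0, 2, 3))
    scale = np.maximum(latents.std(axis=(0, 2, 3)), 1e-8)
    latents = ((latents - shift[:, None, None]) / scale[:, None, None]).astype(np.float32)
    conds = np.stack([encode_mask(p[1]) for p in pairs])
    null = null_condition(grid_size)
    model = build_denoiser(backbone_cfg, seed=seed)
    history = _training_loop(model, latents, sched, opt_cfg, seed=seed + 1,
                             cond=conds, p_uncond=p_uncond, null_cond=null)
    return LatentDiffusionModel(denoiser=model, sched=sched, latent_shift=shift,
                                latent_scale=scale, grid_size=grid_size), history


def synthesize_images(ldm: LatentDiffusionModel, autoencoder: AutoencoderPair,
                      masks: PseudoLabelSet | Sequence[np.ndarray],
                      guidance_w: float = 1.5, n_steps: int = 50,
                      eta: float = 0.0, seed: int = 0,
                      batch: int = 16) -> list[np.ndarray]:
    """Generate one image per mask: sample a latent with classifier-free
    guidance along the mask condition, then decode with D."""
    if guidance_w < 0:
        raise ValueError("guidance weight must be >= 0")
    mask_list = list(masks.masks if isinstance(masks, PseudoLabelSet) else masks)
    if not mask_list:
        return []
    grid = mask_list[0].shape[-1]
    f = autoencoder.cfg.factor
    c = autoencoder.cfg.latent_channels
    null = null_condition(grid)
    out: list[np.ndarray] = []
    done = 0
    while done < len(mask_list):
        chunk = mask_list[done:done + batch]
        cond = np.stack([encode_mask(m) for m in chunk])
        shape = (len(chunk), c, grid // f, grid // f)
        z = diffusion.ddim_sample(
            ldm.denoiser, ldm.sched, n_steps=n_steps, eta=eta, shape=shape,
            seed=seed + 104729 * (done + 1), condition=cond,
            guidance_w=guidance_w,
            null_condition=np.broadcast_to(null, cond.shape))
        imgs = autoencoder.decode(np.stack([ldm.destandardize(zi) for zi in z]))
        out.extend(imgs[i, 0] for i in range(len(chunk)))
        done += len(chunk)
    return out
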