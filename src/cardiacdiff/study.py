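"""End-to-end toy-scale study: generate, screen, synthesise, evaluate.

Bundles the full pipeline at CPU-friendly sizes so the reproduction script,
the acceptance tests and the examples share one code path.  Sizes here are
the package's standard toy operating point (32×32 grids, 3-level backbones,
T = 200 shortened schedule); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .autoencoder import AETrainConfig, toy_ae_config, train_autoencoder
from .backbone import toy_config
from .conditional import synthesize_images, train_conditional_ldm
from .diffusion import NoiseSchedule, scaled_schedule
from .filtering import FilterConfig, filter_labels
from .mask_ddpm import TrainConfig, sample_masks, train_mask_ddpm
from .phantoms import DatasetBundle, PhantomSpec, generate_dataset
from .segmentation import (AugmentedPair, ExperimentConfig, SegMetrics,
                           run_experiment, toy_seg_config)


@dataclass
class StudyConfig:
    """Problem sizes for the toy augmentation study."""
    n_phantoms: int = 200
    grid_size: int = 32
    T: int = 200
    mask_steps: int = 3000
    mask_batch: int = 12
    mask_lr: float = 1e-3
    mask_lr_final: float = 1e-4
    mask_ema: float = 0.998
    n_sample: int = 64
    ddim_steps: int = 50
    sample_eta: float = 1.0  # stochastic DDIM heals isolated pixel defects
    ae_steps: int = 800
    ldm_steps: int = 3500
    ldm_ema: float = 0.999
    synth_per_mask: int = 6
    gen_lr: float = 1e-3
    guidance_w: float = 1.5
    seg_epochs: int = 2
    seg_batch: int = 4


@dataclass
class StudyArtifacts:
    dataset: DatasetBundle
    sched: NoiseSchedule
    mask_model: object
    sampled_masks: list
    accepted_masks: list
    autoencoder: object
    ldm: object
    diffusion_pairs: list[AugmentedPair]


def train_stage1(dataset: DatasetBundle, cfg: StudyConfig, seed: int):
    """Train the unconditional mask DDPM on the train-split masks."""
    sched = scaled_schedule(cfg.T)
    masks = [p.mask for p in dataset.train]
    model, hist = train_mask_ddpm(
        masks, toy_config(), sched,
        TrainConfig(steps=cfg.mask_steps, batch_size=cfg.mask_batch,
                    lr=cfg.mask_lr, lr_final=cfg.mask_lr_final,
                    ema_decay=cfg.mask_ema),
        seed=seed)
    return model, sched, hist


def generate_screened_masks(mask_model, sched, cfg: StudyConfig, seed: int):
    pls = sample_masks(mask_model, sched, n=cfg.n_sample, grid_size=cfg.grid_size,
                       sampler="ddim", n_steps=cfg.ddim_steps, eta=cfg.sample_eta,
                       seed=seed)
    accepted, reports = filter_labels(pls.masks, FilterConfig())
    return list(pls.masks), accepted, reports


def train_stage2(dataset: DatasetBundle, cfg: StudyConfig, seed: int):
    """Train the compression autoencoder and the SPADE-conditioned LDM."""
    imgs = [p.image for p in dataset.train]
    pairs = [(p.image, p.mask) for p in dataset.train]
    ae, _ = train_autoencoder(imgs, toy_ae_config(),
                              AETrainConfig(steps=cfg.ae_steps, batch_size=8,
                                            lr=cfg.gen_lr), seed=seed)
    sched = scaled_schedule(cfg.T)
    bcfg = toy_config(conditional=True, in_channels=ae.cfg.latent_channels,
                      out_channels=ae.cfg.latent_channels)
    ldm, _ = train_conditional_ldm(pairs, ae, bcfg, sched,
                                   TrainConfig(steps=cfg.ldm_steps, batch_size=8,
                                               lr=cfg.gen_lr, lr_final=cfg.gen_lr / 10,
                                               ema_decay=cfg.ldm_ema),
                                   p_uncond=0.1, seed=seed)
    return ae, ldm


def build_diffusion_pairs(ae, ldm, masks, cfg: StudyConfig, seed: int) -> list[AugmentedPair]:
    """Synthesise ``synth_per_mask`` images per accepted pseudo-label (distinct
    sampling seeds), pairing each image with its conditioning mask."""
    out: list[AugmentedPair] = []
    for rep in range(cfg.synth_per_mask):
        images = synthesize_images(ldm, ae, masks, guidance_w=cfg.guidance_w,
                                   n_steps=cfg.ddim_steps, eta=cfg.sample_eta,
                                   seed=seed + 1009 * rep)
        out.extend(AugmentedPair(img, mask, "diffusion", seed + 1009 * rep)
                   for img, mask in zip(images, masks))
    return out


def run_study(cfg: StudyConfig | None = None, seed: int = 0) -> StudyArtifacts:
    """Run phantom generation through paired synthesis (no segmentation)."""
    cfg = cfg or StudyConfig()
    dataset = generate_dataset(cfg.n_phantoms, PhantomSpec(grid_size=cfg.grid_size),
                               seed=seed)
    mask_model, sched, _ = train_stage1(dataset, cfg, seed=seed + 1)
    sampled, accepted, _ = generate_screened_masks(mask_model, sched, cfg, seed=seed + 2)
    ae, ldm = train_stage2(dataset, cfg, seed=seed + 3)
    # only screened pseudo-labels are synthesised into pairs
    pairs = (build_diffusion_pairs(ae, ldm, accepted, cfg, seed=seed + 4)
             if accepted else [])
    return StudyArtifacts(dataset=dataset, sched=sched, mask_model=mask_model,
                          sampled_masks=sampled, accepted_masks=accepted,
                          autoencoder=ae, ldm=ldm, diffusion_pairs=pairs)


def compare_regimes(dataset: DatasetBundle, diffusion_pairs, cfg: StudyConfig,
                    regimes=("none", "diffusion"), seeds=(0, 1, 2)) -> dict[str, float]:
    """Mean test DSC per regime averaged over segmentation seeds."""
    sums = {r: 0.0 for r in regimes}
    for s in seeds:
        ecfg = ExperimentConfig(regimes=tuple(regimes),
                                seg_cfg=toy_seg_config(epochs=cfg.seg_epochs,
                                                       batch_size=cfg.seg_batch),
                                seed=int(s))
        for m in run_experiment(dataset, ecfg, diffusion_pairs=diffusion_pairs):
            sums[m.regime] += m.mean_dice
    return {r: v / len(seeds) for r, v in sums.items()}
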