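"""Readers/writers and run plumbing.

Conventions used everywhere: 0-based (row, column) pixel indexing with the
origin at the top-left; images stored as 16-bit grayscale PNG mapping
[−1, 1] → [0, 65535]; masks stored as palette-indexed 8-bit PNG with labels
0–3; every derived dataset directory carries a JSON manifest naming split
membership and generator seeds.  NIfTI is accepted only at ingestion.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from PIL import Image

from .phantoms import DatasetBundle, PhantomPair, PhantomSpec

_MASK_PALETTE = [0, 0, 0, 220, 40, 40, 240, 220, 60, 60, 90, 220] + [0] * (756)


def write_image_png(path, image: np.ndarray):
    """[−1, 1] float image -> 16-bit grayscale PNG."""
    arr = np.clip((np.asarray(image, dtype=np.float64) + 1.0) / 2.0, 0, 1)
    Image.fromarray((arr * 65535).round().astype(np.uint16)).save(path)


def read_image_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path), dtype=np.float64)
    return (arr / 65535 * 2.0 - 1.0).astype(np.float32)


def write_mask_png(path, mask: np.ndarray):
    im = Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="P")
    im.putpalette(_MASK_PALETTE)
    im.save(path)


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.uint8)


def write_dataset(bundle: DatasetBundle, outdir, spec: Optional[PhantomSpec] = None,
                  seed: Optional[int] = None):
    """Persist a phantom dataset as paired PNGs plus a split manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"splits": {}, "seed": seed,
                "spec": None if spec is None else _spec_dict(spec)}
    idx = 0
    for split in ("train", "val", "test"):
        names = []
        for pair in getattr(bundle, split):
            stem = f"case_{idx:04d}"
            write_image_png(outdir / f"{stem}_img.png", pair.image)
            write_mask_png(outdir / f"{stem}_mask.png", pair.mask)
            names.append({"stem": stem, "seed": pair.spec_used.seed})
            idx += 1
        manifest["splits"][split] = names
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_dataset(indir) -> DatasetBundle:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    spec_d = manifest.get("spec")
    splits = {}
    for split, names in manifest["splits"].items():
        pairs = []
        for rec in names:
            img = read_image_png(indir / f"{rec['stem']}_img.png")
            mask = read_mask_png(indir / f"{rec['stem']}_mask.png")
            spec = PhantomSpec(**spec_d) if spec_d else PhantomSpec(grid_size=mask.shape[0])
            pairs.append(PhantomPair(image=img, mask=mask,
                                     spec_used=replace(spec, seed=rec["seed"])))
        splits[split] = pairs
    return DatasetBundle(**splits)


def _spec_dict(spec: PhantomSpec) -> dict:
    return {"grid_size": spec.grid_size,
            "lv_radius_range": list(spec.lv_radius_range),
            "myo_thickness_range": list(spec.myo_thickness_range),
            "rv_angle_span": spec.rv_angle_span,
            "intensity_means": list(spec.intensity_means),
            "noise_sd": spec.noise_sd, "bias_amplitude": spec.bias_amplitude,
            "seed": spec.seed}


def write_mask_set(masks: Sequence[np.ndarray], outdir, meta: Optional[dict] = None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, m in enumerate(masks):
        stem = f"mask_{i:04d}"
        write_mask_png(outdir / f"{stem}.png", m)
        names.append(stem)
    manifest = {"masks": names, "meta": meta or {}}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_mask_set(indir) -> list[np.ndarray]:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    return [read_mask_png(indir / f"{stem}.png") for stem in manifest["masks"]]


# -- NIfTI ingestion ---------------------------------------------------------

def read_cardiac_volume(image_path, label_path, target_size: int = 128):
    """Load a NIfTI image + label volume and return per-slice 2-D pairs.

    Slices are taken along the smallest axis (the short-axis stack), centre
    cropped to a square and resized to ``target_size`` (bilinear for the
    image, nearest for the mask).  Intensities are rescaled to [−1, 1] using
    the per-volume robust 1st/99th-percentile range; a constant volume maps
    to all-zero images.
    """
    import nibabel as nib
    from skimage.transform import resize

    image_path, label_path = Path(image_path), Path(label_path)
    if not label_path.exists():
        raise FileNotFoundError(f"label volume not found: {label_path}")
    img = np.asarray(nib.load(str(image_path)).get_fdata(), dtype=np.float64)
    lab = np.asarray(nib.load(str(label_path)).get_fdata())
    if img.shape != lab.shape:
        raise ValueError(f"image shape {img.shape} != label shape {lab.shape}")
    if img.ndim != 3:
        raise ValueError("expected 3-D volumes")
    axis = int(np.argmin(img.shape))
    img = np.moveaxis(img, axis, 0)
    lab = np.moveaxis(lab, axis, 0)
    lo, hi = np.percentile(img, [1, 99])
    if hi > lo:
        img = np.clip((img - lo) / (hi - lo) * 2.0 - 1.0, -1.0, 1.0)
    else:
        img = np.zeros_like(img)
    pairs = []
    for sl_img, sl_lab in zip(img, lab):
        h, w = sl_img.shape
        side = min(h, w)
        y0, x0 = (h - side) // 2, (w - side) // 2
        ci = sl_img[y0:y0 + side, x0:x0 + side]
        cl = sl_lab[y0:y0 + side, x0:x0 + side]
        ri = resize(ci, (target_size, target_size), order=1, mode="edge",
                    anti_aliasing=side > target_size, preserve_range=True)
        rl = resize(cl, (target_size, target_size), order=0, mode="edge",
                    anti_aliasing=False, preserve_range=True)
        pairs.append((ri.astype(np.float32), rl.round().astype(np.uint8)))
    return pairs


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(path, kind: str, cfg: dict, state: dict[str, np.ndarray],
                    extra: Optional[dict] = None):
    meta = {"kind": kind, "cfg": cfg, "extra": extra or {}}
    np.savez(path, __meta__=json.dumps(meta, sort_keys=True),
             **{f"p_{k}": v for k, v in state.items()})


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k[2:]: data[k] for k in data.files if k.startswith("p_")}
    return meta, state


# -- run configuration -------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "runs",
    "phantoms": {"n": 50, "grid_size": 32, "noise_sd": 0.05, "bias_amplitude": 0.1},
    "schedule": {"T": 200, "beta_start": 5e-4, "beta_end": 0.1},
    "mask_ddpm": {"steps": 2000, "batch_size": 16, "lr": 1e-4, "ema_decay": None,
                  "channels": [8, 16, 32], "norm_groups": 4, "attention_levels": [3]},
    "autoencoder": {"steps": 1500, "batch_size": 8, "lr": 1e-4,
                    "channels": [8, 16, 32], "n_downsample": 2, "latent_channels": 4,
                    "norm_groups": 4},
    "ldm": {"steps": 2000, "batch_size": 16, "lr": 1e-4, "p_uncond": 0.1,
            "guidance_w": 1.5, "channels": [8, 16, 32], "norm_groups": 4,
            "attention_levels": [3]},
    "filter": {"connectivity": 8, "min_foreground_fraction": 0.01,
               "max_background_components": 5, "enclosure_tolerance": 0},
    "segmentation": {"epochs": 12, "batch_size": 8, "lr": 1e-4,
                     "weight_decay": 1e-5, "channels": [8, 16, 32], "norm_groups": 4},
    "experiment": {"regimes": ["none", "affine", "elastic", "intensity",
                               "cutmix", "diffusion"], "n_aug_per_real": 1.0},
    "sampling": {"sampler": "ddim", "n_steps": 50, "eta": 1.0},
}


class ConfigError(ValueError):
    pass


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> dict:
    """Merge a YAML config over the defaults, rejecting unknown keys."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for source in (None if path is None else yaml.safe_load(Path(path).read_text()),
                   overrides):
        if not source:
            continue
        _merge(cfg, source, [])
    return cfg


def _merge(base: dict, update: dict, trail: list[str]):
    for key, val in update.items():
        here = ".".join(trail + [str(key)])
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config key {here} must be a mapping")
            _merge(base[key], val, trail + [str(key)])
        else:
            base[key] = val


def write_resolved_config(cfg: dict, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
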