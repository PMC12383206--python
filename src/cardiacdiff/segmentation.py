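"""Downstream segmentation and the augmentation comparison harness.

A standard encoder–decoder U-Net is trained with cross-entropy plus soft-Dice
loss under one of six augmentation regimes — none, affine, elastic, intensity,
CutMix, or diffusion-generated pairs — and scored on a shared held-out test
split with per-class Dice (DSC) and Jaccard (IoU).  All regimes receive the
same number of gradient steps; generated pairs are added to (not substituted
for) the real training pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .nn import Adam, Tensor, no_grad
from .nn import autograd as ag
from .nn.layers import Conv2d, GroupNorm, Module, ModuleList
from .phantoms import N_CLASSES, PhantomPair

FOREGROUND_CLASSES = {"LV": 1, "MYO": 2, "RV": 3}
REGIMES = ("none", "affine", "elastic", "intensity", "cutmix", "diffusion")


# -- metrics -----------------------------------------------------------------

def dice_iou(pred: np.ndarray, gt: np.ndarray, class_id: int) -> tuple[float, float]:
    """Per-class Dice and IoU from pixel counts.

    Both metrics are defined as 1.0 when the class is absent from prediction
    and ground truth alike (and 0.0 when absent from exactly one), so empty
    apex-like slices neither break the mean nor reward hallucination.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    p = pred == class_id
    g = gt == class_id
    np_, ng = int(p.sum()), int(g.sum())
    if np_ == 0 and ng == 0:
        return 1.0, 1.0
    inter = int((p & g).sum())
    dsc = 2.0 * inter / (np_ + ng)
    iou = inter / (np_ + ng - inter)
    return dsc, iou


@dataclass
class SegMetrics:
    regime: str
    dice: dict[str, float]   # per foreground class
    iou: dict[str, float]

    @property
    def mean_dice(self) -> float:
        return float(np.mean(list(self.dice.values())))

    @property
    def mean_iou(self) -> float:
        return float(np.mean(list(self.iou.values())))

    def row(self) -> dict:
        return {"method": self.regime, "mean_dice": self.mean_dice,
                "dice_LV": self.dice["LV"], "dice_MYO": self.dice["MYO"],
                "dice_RV": self.dice["RV"], "mean_iou": self.mean_iou,
                "iou_LV": self.iou["LV"], "iou_MYO": self.iou["MYO"],
                "iou_RV": self.iou["RV"]}


def evaluate_masks(preds: Sequence[np.ndarray], gts: Sequence[np.ndarray],
                   regime: str = "") -> SegMetrics:
    """Aggregate per-class metrics from pooled confusion counts over a set."""
    dice, iou = {}, {}
    for name, cid in FOREGROUND_CLASSES.items():
        inter = sp = sg = 0
        for p, g in zip(preds, gts):
            pm = p == cid
            gm = g == cid
            inter += int((pm & gm).sum())
            sp += int(pm.sum())
            sg += int(gm.sum())
        if sp == 0 and sg == 0:
            dice[name], iou[name] = 1.0, 1.0
        else:
            dice[name] = 2.0 * inter / (sp + sg)
            iou[name] = inter / (sp + sg - inter)
    return SegMetrics(regime=regime, dice=dice, iou=iou)


# -- classic augmentations ---------------------------------------------------

@dataclass(frozen=True)
class AugmentedPair:
    image: np.ndarray
    mask: np.ndarray
    provenance: str
    seed: int = 0


def _spatial_transform(image, mask, matrix, offset):
    img_out = ndimage.affine_transform(image, matrix, offset=offset, order=1,
                                       mode="constant", cval=float(image.min()))
    mask_out = ndimage.affine_transform(mask, matrix, offset=offset, order=0,
                                        mode="constant", cval=0)
    return img_out.astype(np.float32), mask_out.astype(np.uint8)


def affine_augment(pair, seed: int = 0, max_rotate: float = 20.0,
                   scale_range: tuple[float, float] = (0.9, 1.1),
                   max_shift: float = 0.05) -> AugmentedPair:
    """Random rotation/scale/translation, bilinear image + nearest mask."""
    rng = np.random.default_rng(seed)
    theta = np.deg2rad(rng.uniform(-max_rotate, max_rotate))
    s = rng.uniform(*scale_range)
    if s == 0:
        raise ValueError("degenerate zero-scale transform")
    H, W = pair.mask.shape
    shift = rng.uniform(-max_shift, max_shift, size=2) * H
    c, si = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -si], [si, c]]) / s
    center = np.array([(H - 1) / 2, (W - 1) / 2])
    offset = center - rot @ (center + shift)
    img, mask = _spatial_transform(pair.image, pair.mask, rot, offset)
    return AugmentedPair(img, mask, "affine", seed)


def elastic_augment(pair, seed: int = 0, alpha: float = 8.0,
                    sigma: float = 4.0) -> AugmentedPair:
    """Gaussian-smoothed random displacement field, applied to both rasters."""
    rng = np.random.default_rng(seed)
    H, W = pair.mask.shape
    dy = ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma) * alpha
    dx = ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma) * alpha
    yy, xx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    coords = np.stack([yy + dy, xx + dx])
    img = ndimage.map_coordinates(pair.image, coords, order=1, mode="reflect")
    mask = ndimage.map_coordinates(pair.mask, coords, order=0, mode="reflect")
    return AugmentedPair(img.astype(np.float32), mask.astype(np.uint8), "elastic", seed)


def intensity_augment(pair, seed: int = 0, max_shift: float = 0.2,
                      contrast_range: tuple[float, float] = (0.7, 1.3)) -> AugmentedPair:
    """Brightness/contrast jitter on the image only; the mask is untouched."""
    rng = np.random.default_rng(seed)
    gain = rng.uniform(*contrast_range)
    shift = rng.uniform(-max_shift, max_shift)
    img = np.clip(pair.image * gain + shift, -1.0, 1.0).astype(np.float32)
    return AugmentedPair(img, pair.mask.copy(), "intensity", seed)


def cutmix_augment(pairA, pairB, box: Optional[tuple[int, int, int, int]] = None,
                   seed: int = 0) -> AugmentedPair:
    """Paste a rectangular region of B into A (image and mask alike)."""
    if pairA.mask.shape != pairB.mask.shape:
        raise ValueError("pairs must share shape")
    H, W = pairA.mask.shape
    if box is None:
        rng = np.random.default_rng(seed)
        bh = int(rng.integers(H // 4, H // 2 + 1))
        bw = int(rng.integers(W // 4, W // 2 + 1))
        y0 = int(rng.integers(0, H - bh + 1))
        x0 = int(rng.integers(0, W - bw + 1))
        box = (y0, x0, y0 + bh, x0 + bw)
    y0, x0, y1, x1 = box
    if y1 <= y0 or x1 <= x0:
        raise ValueError("empty CutMix box")
    img = pairA.image.copy()
    mask = pairA.mask.copy()
    img[y0:y1, x0:x1] = pairB.image[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] = pairB.mask[y0:y1, x0:x1]
    return AugmentedPair(img, mask, "cutmix", seed)


# -- segmentation U-Net ------------------------------------------------------

@dataclass(frozen=True)
class SegConfig:
    n_levels: int = 4
    channels: tuple = (32, 64, 128, 256)
    norm_groups: int = 8
    n_classes: int = N_CLASSES
    epochs: int = 30
    batch_size: int = 8
    lr: float = 1e-4
    weight_decay: float = 1e-5

    def __post_init__(self):
        if len(self.channels) != self.n_levels:
            raise ValueError("channels must list one width per level")


def toy_seg_config(channels=(8, 16, 32), norm_groups=4, epochs=30,
                   batch_size=4, lr=1e-3) -> SegConfig:
    """CPU-scale config; the higher learning rate compensates for the small
    step budget of toy runs."""
    return SegConfig(n_levels=len(channels), channels=tuple(channels),
                     norm_groups=norm_groups, epochs=epochs, batch_size=batch_size,
                     lr=lr)


class _ConvBlock(Module):
    def __init__(self, cin, cout, groups, rng):
        self.conv1 = Conv2d(cin, cout, k=3, rng=rng)
        self.norm1 = GroupNorm(groups, cout)
        self.conv2 = Conv2d(cout, cout, k=3, rng=rng)
        self.norm2 = GroupNorm(groups, cout)

    def forward(self, x):
        h = ag.silu(self.norm1(self.conv1(x)))
        return ag.silu(self.norm2(self.conv2(h)))


class SegUNet(Module):
    """Plain U-Net: strided-conv downsampling, nearest-up + conv, skip concat."""

    def __init__(self, cfg: SegConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = cfg.channels
        g = cfg.norm_groups
        self.enc = ModuleList()
        self.downs = ModuleList()
        for i in range(cfg.n_levels):
            cin = 1 if i == 0 else ch[i - 1]
            self.enc.append(_ConvBlock(cin, ch[i], g, rng))
            if i < cfg.n_levels - 1:
                self.downs.append(Conv2d(ch[i], ch[i], k=3, stride=2, rng=rng))
        self.dec = ModuleList()
        self.ups = ModuleList()
        for i in reversed(range(cfg.n_levels - 1)):
            self.ups.append(Conv2d(ch[i + 1], ch[i], k=3, rng=rng))
            self.dec.append(_ConvBlock(ch[i] * 2, ch[i], g, rng))
        self.head = Conv2d(ch[0], cfg.n_classes, k=1, rng=rng)

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block(h)
            if i < self.cfg.n_levels - 1:
                skips.append(h)
                h = self.downs[i](h)
        for j, (up, block) in enumerate(zip(self.ups, self.dec)):
            h = up(ag.upsample_nearest2x(h))
            h = block(ag.concat([h, skips[-(j + 1)]], axis=1))
        return self.head(h)  # (B, K, H, W) logits

    def predict(self, images: np.ndarray, batch: int = 16) -> np.ndarray:
        """(N, H, W) images -> (N, H, W) label maps."""
        images = np.asarray(images, dtype=np.float32)
        out = []
        with no_grad():
            for i in range(0, len(images), batch):
                logits = self(images[i:i + batch, None]).numpy()
                out.append(np.argmax(logits, axis=1).astype(np.uint8))
        return np.concatenate(out)


def _seg_loss(logits, target_onehot: np.ndarray):
    """Cross-entropy + soft Dice over foreground classes."""
    tgt = Tensor(target_onehot)
    logp = ag.log(ag.softmax(logits, axis=1) + 1e-8)
    ce = -ag.tmean(ag.tsum(tgt * logp, axis=1))
    probs = ag.softmax(logits, axis=1)
    inter = ag.tsum(probs * tgt, axis=(0, 2, 3))
    denom = ag.tsum(probs, axis=(0, 2, 3)) + ag.tsum(tgt, axis=(0, 2, 3))
    dice = (inter * 2.0 + 1.0) / (denom + 1.0)
    dice_fg = ag.tmean(dice[1:])  # ignore background channel
    return ce + (1.0 - dice_fg)


def train_unet_seg(train_pairs: Sequence, val_pairs: Sequence,
                   cfg: SegConfig | None = None, seed: int = 0):
    """Train the segmenter; keeps the best-on-validation parameters.

    Returns (model, history) where history has per-epoch loss and val dice.
    """
    train_pairs = list(train_pairs)
    if not train_pairs:
        raise ValueError("empty training set")
    cfg = cfg or SegConfig()
    images = np.stack([p.image for p in train_pairs]).astype(np.float32)[:, None]
    onehots = np.stack([np.eye(cfg.n_classes, dtype=np.float32)[p.mask].transpose(2, 0, 1)
                        for p in train_pairs])
    val_imgs = np.stack([p.image for p in val_pairs]) if val_pairs else None
    val_masks = [p.mask for p in val_pairs] if val_pairs else None
    model = SegUNet(cfg, seed=seed)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(seed + 1)
    n = len(train_pairs)
    history = {"loss": [], "val_dice": []}
    best = (-1.0, model.state_dict())
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model(images[idx])
            loss = _seg_loss(logits, onehots[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["loss"].append(float(np.mean(losses)))
        if val_imgs is not None:
            preds = model.predict(val_imgs)
            m = evaluate_masks(preds, val_masks)
            history["val_dice"].append(m.mean_dice)
            if m.mean_dice > best[0]:
                best = (m.mean_dice, model.state_dict())
    if val_imgs is not None and best[0] >= 0:
        model.load_state_dict(best[1])
    return model, history


# -- experiment harness ------------------------------------------------------

@dataclass
class ExperimentConfig:
    regimes: tuple = REGIMES
    seg_cfg: SegConfig = field(default_factory=SegConfig)
    n_aug_per_real: float = 1.0   # M = ratio * N extra pairs for classic regimes
    seed: int = 0


def _build_augmented(regime: str, real: list, rng: np.random.Generator,
                     n_aug: int, diffusion_pairs=None) -> list:
    if regime == "none":
        return []
    if regime == "diffusion":
        if diffusion_pairs is None:
            raise ValueError("diffusion regime requires generated pairs")
        return list(diffusion_pairs)[:n_aug] if n_aug else list(diffusion_pairs)
    out = []
    for k in range(n_aug):
        src = real[int(rng.integers(len(real)))]
        s = int(rng.integers(2 ** 31 - 1))
        if regime == "affine":
            out.append(affine_augment(src, seed=s))
        elif regime == "elastic":
            out.append(elastic_augment(src, seed=s))
        elif regime == "intensity":
            out.append(intensity_augment(src, seed=s))
        elif regime == "cutmix":
            other = real[int(rng.integers(len(real)))]
            out.append(cutmix_augment(src, other, seed=s))
        else:
            raise ValueError(f"unknown regime {regime!r}")
    return out


def run_experiment(dataset, cfg: ExperimentConfig,
                   diffusion_pairs: Optional[list] = None) -> list[SegMetrics]:
    """Train one segmenter per requested regime and score the shared test split.

    ``dataset`` is a DatasetBundle; ``diffusion_pairs`` supplies the
    generated (pseudo-image, pseudo-label) pairs for the diffusion regime.
    Equal budgets: every regime trains for the same number of epochs on
    real + M augmented pairs (M = round(n_aug_per_real · N), except the
    diffusion regime which contributes its own pair count).  Duplicate
    regimes reuse the cached run.
    """
    test_imgs = np.stack([p.image for p in dataset.test])
    test_masks = [p.mask for p in dataset.test]
    n_aug = int(round(cfg.n_aug_per_real * len(dataset.train)))
    cache: dict[str, SegMetrics] = {}
    results = []
    for regime in cfg.regimes:
        if regime in cache:
            results.append(cache[regime])
            continue
        rng = np.random.default_rng((cfg.seed, REGIMES.index(regime)))
        aug = _build_augmented(regime, list(dataset.train), rng, n_aug, diffusion_pairs)
        train = list(dataset.train) + aug
        # equal budgets: keep the number of gradient steps constant across
        # regimes by scaling epochs down when augmentation enlarges the set
        scale = len(dataset.train) / len(train)
        seg_cfg = replace(cfg.seg_cfg,
                          epochs=max(1, round(cfg.seg_cfg.epochs * scale)))
        model, _ = train_unet_seg(train, list(dataset.val), seg_cfg, seed=cfg.seed)
        preds = model.predict(test_imgs)
        metrics = evaluate_masks(preds, test_masks, regime=regime)
        cache[regime] = metrics
        results.append(metrics)
    return results


def metrics_table(results: Sequence[SegMetrics]) -> str:
    """CSV in the standard comparison layout (method, Dice, IoU columns)."""
    cols = ["method", "mean_dice", "dice_LV", "dice_MYO", "dice_RV",
            "mean_iou", "iou_LV", "iou_MYO", "iou_RV"]
    lines = [",".join(cols)]
    for m in results:
        row = m.row()
        lines.append(",".join(row["method"] if c == "method" else f"{row[c]:.4f}"
                              for c in cols))
    return "\n".join(lines) + "\n"
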