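"""Seedable cardiac phantom generator.

Produces short-axis-like image/mask pairs on a square grid: the left
ventricular cavity (LV, label 1) is a bright disk enclosed by the myocardial
ring (MYO, label 2), with the right ventricular cavity (RV, label 3) rendered
as a crescent hugging the ring on a randomised lateral angle.  Images carry
class-dependent intensities in [−1, 1], additive Gaussian noise and a smooth
low-order polynomial bias field emulating coil inhomogeneity.

The module also constructs deliberately malformed masks, one per screening
rule (fragmented structure, broken topology, undersized heart, background
speckle), each violating exactly its target rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

LABELS = {"background": 0, "LV": 1, "MYO": 2, "RV": 3}
N_CLASSES = 4


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance parameters for one phantom draw.

    Radii and thicknesses are fractions of the grid side; intensity means are
    per-class values in [−1, 1] ordered (background, LV, MYO, RV) — blood
    pools bright, myocardium dark, as in balanced SSFP cardiac MR.
    """

    grid_size: int = 128
    lv_radius_range: tuple[float, float] = (0.10, 0.16)
    myo_thickness_range: tuple[float, float] = (0.05, 0.09)
    rv_angle_span: float = 120.0
    intensity_means: tuple[float, ...] = (-0.8, 0.7, -0.1, 0.4)
    noise_sd: float = 0.05
    bias_amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if len(self.intensity_means) != N_CLASSES:
            raise ValueError(f"intensity_means must have {N_CLASSES} entries")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lv_radius_range[1] + self.myo_thickness_range[1] >= 0.5:
            raise ValueError("LV radius + MYO thickness must fit inside the grid "
                             "(fractional sum must stay below 0.5)")
        if self.grid_size < 16:
            raise ValueError("grid too small for a resolvable phantom")


@dataclass(frozen=True)
class PhantomPair:
    image: np.ndarray  # float32 (H, W) in [-1, 1]
    mask: np.ndarray   # uint8 (H, W) in {0..3}
    spec_used: PhantomSpec


@dataclass
class DatasetBundle:
    train: list[PhantomPair]
    val: list[PhantomPair]
    test: list[PhantomPair]

    def __iter__(self):
        return iter(self.train + self.val + self.test)

    def __len__(self):
        return len(self.train) + len(self.val) + len(self.test)


def _grid_coords(G: int):
    return np.meshgrid(np.arange(G), np.arange(G), indexing="ij")


def _draw_geometry(spec: PhantomSpec, rng: np.random.Generator):
    G = spec.grid_size
    cy = G / 2 + rng.uniform(-0.05, 0.05) * G
    cx = G / 2 + rng.uniform(-0.05, 0.05) * G
    r = rng.uniform(*spec.lv_radius_range) * G
    th = max(rng.uniform(*spec.myo_thickness_range) * G, 1.5)  # >=1.5 px ensures 8-enclosure
    phi = rng.uniform(0, 2 * np.pi)
    return cy, cx, r, th, phi


def _render_mask(spec: PhantomSpec, cy, cx, r, th, phi, rv_gap: float = 0.0) -> np.ndarray:
    """Rasterise LV disk, MYO annulus and RV crescent.

    ``rv_gap`` > 0 displaces the RV crescent radially outward, detaching it
    from the ring (used by the malformed-mask constructors only).
    """
    G = spec.grid_size
    yy, xx = _grid_coords(G)
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    mask = np.zeros((G, G), dtype=np.uint8)
    mask[dist <= r] = LABELS["LV"]
    mask[(dist > r) & (dist <= r + th)] = LABELS["MYO"]
    # RV: disk centred beyond the ring along phi, clipped to outside the ring
    span = np.deg2rad(spec.rv_angle_span)
    rv_r = max((r + th) * np.sin(span / 2), 2.5)
    d_center = r + th + rv_gap + rv_r * 0.55
    ry = cy + d_center * np.sin(phi)
    rx = cx + d_center * np.cos(phi)
    rv_dist = np.sqrt((yy - ry) ** 2 + (xx - rx) ** 2)
    rv = (rv_dist <= rv_r) & (dist > r + th + rv_gap)
    mask[rv] = LABELS["RV"]
    if rv_gap == 0.0 and not rv.any():
        raise ValueError("RV crescent fell outside the grid; reduce radii or angle span")
    return mask


def _render_image(spec: PhantomSpec, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    G = spec.grid_size
    means = np.asarray(spec.intensity_means, dtype=np.float64)
    img = means[mask]
    if spec.bias_amplitude > 0:
        yy, xx = _grid_coords(G)
        X = 2 * xx / (G - 1) - 1
        Y = 2 * yy / (G - 1) - 1
        c = rng.uniform(-1, 1, size=5)
        poly = c[0] * X + c[1] * Y + c[2] * X * Y + c[3] * X * X + c[4] * Y * Y
        img = img * (1.0 + spec.bias_amplitude * poly)
    if spec.noise_sd > 0:
        img = img + rng.normal(0, spec.noise_sd, size=img.shape)
    return np.clip(img, -1.0, 1.0).astype(np.float32)


def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Draw one image/mask pair; same spec (incl. seed) reproduces it exactly."""
    rng = np.random.default_rng(spec.seed)
    cy, cx, r, th, phi = _draw_geometry(spec, rng)
    mask = _render_mask(spec, cy, cx, r, th, phi)
    image = _render_image(spec, mask, rng)
    return PhantomPair(image=image, mask=mask, spec_used=spec)


def generate_malformed_mask(rule_id: int, seed: int, grid_size: int = 32,
                            spec: PhantomSpec | None = None) -> np.ndarray:
    """Construct a mask violating exactly one screening rule.

    rule 1: LV fragmented into two components (a myocardial band splits it).
    rule 2: broken topology — either a slit in the MYO ring exposes LV to
            background (even seeds) or the RV is detached from the ring
            (odd seeds).
    rule 3: miniature heart occupying fewer pixels than the minimum fraction
            (requires grid_size >= 32).
    rule 4: canonical phantom plus many isolated single-pixel islands.
    """
    if rule_id not in (1, 2, 3, 4):
        raise ValueError(f"unknown rule_id {rule_id}; expected 1..4")
    if spec is None:
        spec = PhantomSpec(grid_size=grid_size, seed=seed)
    else:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng((seed, rule_id))
    G = spec.grid_size
    cy, cx, r, th, phi = _draw_geometry(spec, rng)

    if rule_id == 1:
        mask = _render_mask(spec, cy, cx, r, th, phi)
        yy, xx = _grid_coords(G)
        # band through the LV centre, 2 px wide, painted MYO: splits LV in two
        u = (yy - cy) * np.sin(phi) + (xx - cx) * np.cos(phi)
        band = (np.abs(u) <= 1.0) & (mask == LABELS["LV"])
        mask[band] = LABELS["MYO"]
        return mask

    if rule_id == 2:
        if seed % 2 == 0:
            mask = _render_mask(spec, cy, cx, r, th, phi)
            yy, xx = _grid_coords(G)
            # radial slit through the full ring thickness, opposite the RV
            ang = np.arctan2(yy - cy, xx - cx)
            slit_dir = phi + np.pi
            v = (yy - cy) * np.sin(slit_dir) + (xx - cx) * np.cos(slit_dir)
            perp = -(yy - cy) * np.cos(slit_dir) + (xx - cx) * np.sin(slit_dir)
            slit = (np.abs(perp) <= 1.0) & (v > 0) & (mask == LABELS["MYO"])
            mask[slit] = LABELS["background"]
            return mask
        return _render_mask(spec, cy, cx, r, th, phi, rv_gap=4.0)

    if rule_id == 3:
        if G < 32:
            raise ValueError("rule-3 miniature needs grid_size >= 32")
        mask = np.zeros((G, G), dtype=np.uint8)
        my = int(rng.integers(4, G - 4))
        mx = int(rng.integers(4, G - 5))
        mask[my - 1:my + 2, mx - 1:mx + 2] = LABELS["MYO"]
        mask[my, mx] = LABELS["LV"]
        mask[my, mx + 2] = LABELS["RV"]  # single pixel abutting the ring
        return mask

    # rule 4: canonical anatomy plus isolated foreground speckles
    mask = _render_mask(spec, cy, cx, r, th, phi)
    from scipy.ndimage import binary_dilation
    forbidden = binary_dilation(mask > 0, np.ones((5, 5), bool))
    n_islands, placed = 25, 0
    attempts = 0
    while placed < n_islands and attempts < 10000:
        attempts += 1
        y = int(rng.integers(1, G - 1))
        x = int(rng.integers(1, G - 1))
        if forbidden[y, x]:
            continue
        mask[y, x] = int(rng.integers(1, 4))
        forbidden[max(0, y - 2):y + 3, max(0, x - 2):x + 3] = True
        placed += 1
    if placed < n_islands:
        raise RuntimeError("could not place speckle islands; grid too crowded")
    return mask


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_sizes(n: int, split_ratio: Sequence[int] = (7, 1, 2)) -> tuple[int, int, int]:
    """Partition n cases by ratio: round train and val, remainder to test."""
    if n < 10:
        raise ValueError("need at least 10 cases to honour the split ratio")
    a, b, c = split_ratio
    s = a + b + c
    n_train = _round_half_up(n * a / s)
    n_val = _round_half_up(n * b / s)
    n_test = n - n_train - n_val
    if n_test < 0:
        raise ValueError("ratio rounding produced a negative test split")
    return n_train, n_val, n_test


def generate_dataset(n: int, spec: PhantomSpec | None = None,
                     split_ratio: Sequence[int] = (7, 1, 2), seed: int = 0) -> DatasetBundle:
    """Generate n phantoms and split them case-wise (shuffled, then ratio-cut)."""
    n_train, n_val, n_test = split_sizes(n, split_ratio)
    if spec is None:
        spec = PhantomSpec()
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    pairs = [generate_phantom(replace(spec, seed=int(s))) for s in case_seeds]
    order = rng.permutation(n)
    pairs = [pairs[i] for i in order]
    return DatasetBundle(train=pairs[:n_train],
                         val=pairs[n_train:n_train + n_val],
                         test=pairs[n_train + n_val:])
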