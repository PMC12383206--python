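"""Quality screening of generated cardiac masks.

Generated pseudo-labels are rejected when they exhibit one of four abnormal
conditions: (1) fragmented cardiac structures, (2) spatial configurations
inconsistent with short-axis anatomy, (3) an implausibly small heart, and
(4) many stray labels scattered over the background.

Operationalisation
------------------
Let the *main cluster* be the largest connected component (8-connectivity by
default) of the union of all foreground classes; every other union component
is a *stray*.  Rules are evaluated as:

1. connectivity — within the main cluster, each foreground class present must
   form a single connected component;
2. topology — LV, MYO and RV must all be present in the main cluster, every
   LV boundary pixel's neighbourhood outside LV must contain only MYO (up to
   ``enclosure_tolerance`` violating pixels), and the RV must share at least
   one adjacent pixel pair with the MYO;
3. minimum area — the total foreground fraction must reach
   ``min_foreground_fraction`` (at-threshold passes);
4. background speckle — the number of strays must not exceed
   ``max_background_components``.

Scoping rules 1 and 2 to the main cluster keeps the four verdicts orthogonal:
a speckled mask fails only rule 4, a fragmented one only rule 1, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .phantoms import LABELS, N_CLASSES

_FOREGROUND = ("LV", "MYO", "RV")


@dataclass(frozen=True)
class FilterConfig:
    connectivity: int = 8
    min_foreground_fraction: float = 0.01
    max_background_components: int = 5
    enclosure_tolerance: int = 0
    adjacency_required: bool = True

    def __post_init__(self):
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not 0 < self.min_foreground_fraction < 1:
            raise ValueError("min_foreground_fraction must be in (0, 1)")
        if self.max_background_components < 0:
            raise ValueError("max_background_components must be >= 0")

    @property
    def structure(self) -> np.ndarray:
        return np.ones((3, 3), bool) if self.connectivity == 8 else \
            ndimage.generate_binary_structure(2, 1)


@dataclass
class FilterReport:
    verdicts: dict[str, bool]          # rule name -> passed
    component_counts: dict[str, int]   # per-class counts within the main cluster
    foreground_fraction: float
    stray_count: int

    @property
    def accepted(self) -> bool:
        return all(self.verdicts.values())

    def failed_rules(self) -> list[int]:
        order = ("connectivity", "topology", "min_area", "background_speckle")
        return [i + 1 for i, name in enumerate(order) if not self.verdicts[name]]


def _main_cluster(mask: np.ndarray, cfg: FilterConfig):
    """Largest union-foreground component and the count of other components."""
    fg = mask > 0
    labeled, n = ndimage.label(fg, structure=cfg.structure)
    if n == 0:
        return np.zeros_like(fg), 0
    sizes = ndimage.sum_labels(fg, labeled, index=np.arange(1, n + 1))
    main_id = 1 + int(np.argmax(sizes))
    return labeled == main_id, n - 1


def rule1_connectivity(mask: np.ndarray, cfg: FilterConfig | None = None):
    """Fragmentation check: each class in the main cluster forms one piece."""
    cfg = cfg or FilterConfig()
    main, _ = _main_cluster(mask, cfg)
    counts = {}
    ok = True
    for name in _FOREGROUND:
        cls = (mask == LABELS[name]) & main
        _, n = ndimage.label(cls, structure=cfg.structure)
        counts[name] = int(n)
        if n > 1:
            ok = False
    return ok, counts


def rule2_topology(mask: np.ndarray, cfg: FilterConfig | None = None) -> bool:
    """Clinical-logic check: LV enclosed by MYO; RV attached to the ring."""
    cfg = cfg or FilterConfig()
    main, _ = _main_cluster(mask, cfg)
    lv = (mask == LABELS["LV"]) & main
    myo = (mask == LABELS["MYO"]) & main
    rv = (mask == LABELS["RV"]) & main
    if not (lv.any() and myo.any()):
        return False
    if cfg.adjacency_required and not rv.any():
        return False
    # LV enclosure: dilate LV; its halo must be LV or MYO
    halo = ndimage.binary_dilation(lv, cfg.structure) & ~lv
    violations = int(np.count_nonzero(halo & ~myo))
    if violations > cfg.enclosure_tolerance:
        return False
    if cfg.adjacency_required:
        rv_halo = ndimage.binary_dilation(rv, cfg.structure) & ~rv
        if not (rv_halo & myo).any():
            return False
    return True


def rule3_min_area(mask: np.ndarray, cfg: FilterConfig | None = None):
    """Minimum heart size: total foreground fraction of the grid."""
    cfg = cfg or FilterConfig()
    frac = float(np.count_nonzero(mask > 0)) / mask.size
    return frac >= cfg.min_foreground_fraction, frac


def rule4_background_speckle(mask: np.ndarray, cfg: FilterConfig | None = None):
    """Stray-component check: union components besides the main cluster."""
    cfg = cfg or FilterConfig()
    _, strays = _main_cluster(mask, cfg)
    return strays <= cfg.max_background_components, strays


def screen_mask(mask: np.ndarray, cfg: FilterConfig | None = None) -> FilterReport:
    """Evaluate all four rules on one mask."""
    cfg = cfg or FilterConfig()
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D label map")
    if mask.max(initial=0) >= N_CLASSES:
        raise ValueError("mask contains out-of-range class values")
    ok1, counts = rule1_connectivity(mask, cfg)
    ok2 = rule2_topology(mask, cfg)
    ok3, frac = rule3_min_area(mask, cfg)
    ok4, strays = rule4_background_speckle(mask, cfg)
    return FilterReport(
        verdicts={"connectivity": ok1, "topology": ok2,
                  "min_area": ok3, "background_speckle": ok4},
        component_counts=counts, foreground_fraction=frac, stray_count=strays)


def filter_labels(masks: Iterable[np.ndarray], cfg: FilterConfig | None = None):
    """Screen a set of masks; returns (accepted list, all reports), order kept."""
    cfg = cfg or FilterConfig()
    masks = list(masks)
    reports = [screen_mask(m, cfg) for m in masks]
    accepted = [m for m, r in zip(masks, reports) if r.accepted]
    return accepted, reports
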