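"""Fruit/background segmentation by hue thresholding plus blob-size filtering.

The background behind the fruit is a blue-ish surface whose hue falls in the
band [0.466, 0.842] (cyan through magenta on a 0-1 hue wheel). A pixel is
foreground iff its hue lies *outside* that band — tomato hues from green
(~0.33) through yellow, orange and red (~0 / ~1) all survive — and its
saturation and value lie inside their configured ranges. Connected
components smaller than ``min_area`` pixels (default 400) are then
discarded as debris.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .imaging import ImageHSV


@dataclass
class SegmentationConfig:
    """Thresholds for hue-band background removal and blob filtering.

    ``h_background_low``/``h_background_high`` delimit the *background* hue
    band; everything outside it is candidate fruit. ``s_range`` and
    ``v_range`` default to the full [0, 1] interval (no-ops) but can be
    narrowed, e.g. to drop near-black shadow pixels.
    """

    h_background_low: float = 0.466
    h_background_high: float = 0.842
    s_range: tuple[float, float] = (0.0, 1.0)
    v_range: tuple[float, float] = (0.0, 1.0)
    min_area: int = 400
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0.0 <= self.h_background_low < self.h_background_high <= 1.0:
            raise ValueError(
                "hue band must satisfy 0 <= low < high <= 1, got "
                f"[{self.h_background_low}, {self.h_background_high}]"
            )
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class FruitMask:
    """A boolean foreground mask together with its connected-component areas."""

    mask: np.ndarray
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def labels(self) -> np.ndarray:
        # skimage connectivity: 1 = 4-neighbourhood, 2 = 8-neighbourhood
        return measure.label(self.mask, connectivity=1 if self.connectivity == 4 else 2)

    @property
    def areas(self) -> list[int]:
        lab = self.labels
        n = lab.max()
        return [int((lab == i).sum()) for i in range(1, n + 1)]

    @property
    def n_components(self) -> int:
        return int(self.labels.max())

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def segment_fruit(img: ImageHSV, cfg: SegmentationConfig | None = None) -> FruitMask:
    """Threshold an HSV image into a fruit mask.

    A pixel is foreground iff H is outside [h_background_low,
    h_background_high] and S, V fall inside their ranges. An image with no
    fruit yields an empty mask, not an error.
    """
    cfg = cfg or SegmentationConfig()
    h, s, v = img.hue, img.saturation, img.value
    fg = ~((h >= cfg.h_background_low) & (h <= cfg.h_background_high))
    fg &= (s >= cfg.s_range[0]) & (s <= cfg.s_range[1])
    fg &= (v >= cfg.v_range[0]) & (v <= cfg.v_range[1])
    return FruitMask(fg, connectivity=cfg.connectivity)


def filter_small_regions(m: FruitMask, min_area: int = 400) -> FruitMask:
    """Remove every connected component whose area is smaller than ``min_area``.

    Components of exactly ``min_area`` pixels are kept (the rule is strictly
    "smaller than"). Idempotent and anti-extensive.
    """
    lab = m.labels
    keep = np.zeros_like(m.mask)
    for region in measure.regionprops(lab):
        if region.area >= min_area:
            keep[lab == region.label] = True
    return FruitMask(keep, connectivity=m.connectivity)


def mask_jaccard(a: FruitMask | np.ndarray, b: FruitMask | np.ndarray) -> float:
    """Jaccard overlap (intersection over union) between two masks."""
    ma = a.mask if isinstance(a, FruitMask) else np.asarray(a, dtype=bool)
    mb = b.mask if isinstance(b, FruitMask) else np.asarray(b, dtype=bool)
    union = (ma | mb).sum()
    if union == 0:
        return 1.0
    return float((ma & mb).sum() / union)
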