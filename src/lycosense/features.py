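"""Color-feature extraction from a segmented fruit.

Two families of features feed the regression models:

* **Pixel areas** — counts of fruit pixels whose dominant channel is red,
  green or blue (dominance by a configurable margin), realizing the
  "red, green and blue pixel regions" the image sensor measures.
* **Lab aggregates** — masked-pixel means of L*, a*, b*, mapped by an
  affine :class:`FeatureScaling` into the input domains the fuzzy engine's
  membership functions are defined on (L in (0, 2558.3], a in (0, 1736],
  b in (-210, 358]), plus the classic a/b ripeness ratio.

The fuzzy-domain units are not standard L*a*b* ranges and the mapping from
image statistics into them is not uniquely determined, so it is kept as one
explicit, configurable affine seam with a documented default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import ImageRGB, rgb_to_lab
from .segmentation import FruitMask


class EmptyMaskError(ValueError):
    """No fruit pixels were segmented; features are undefined."""


class PixelClass(enum.Enum):
    RED = "red"
    GREEN = "green"
    BLUE = "blue"
    NONE = "none"


# Fuzzy-engine input domains (lower open bound, upper closed bound).
L_DOMAIN = (0.0, 2558.3)
A_DOMAIN = (0.0, 1736.0)
B_DOMAIN = (-210.0, 358.0)


@dataclass
class FeatureScaling:
    """Affine map from L*a*b* aggregates into fuzzy-domain units.

    ``x_feat = gain * x_lab + offset`` per channel. The default maps
    L* in [0, 100] onto [0, 2558.3], a* in [-128, 127] onto [0, 1736] and
    b* in [-128, 127] onto [-210, 358].
    """

    l_gain: float = 2558.3 / 100.0
    l_offset: float = 0.0
    a_gain: float = 1736.0 / 255.0
    a_offset: float = 128.0 * 1736.0 / 255.0
    b_gain: float = (358.0 + 210.0) / 255.0
    b_offset: float = 128.0 * (358.0 + 210.0) / 255.0 - 210.0

    @classmethod
    def identity(cls) -> "FeatureScaling":
        return cls(1.0, 0.0, 1.0, 0.0, 1.0, 0.0)

    def apply(self, L: float, a: float, b: float) -> tuple[float, float, float]:
        return (
            self.l_gain * L + self.l_offset,
            self.a_gain * a + self.a_offset,
            self.b_gain * b + self.b_offset,
        )


@dataclass
class ColorFeatures:
    """The per-fruit color summary consumed by the regression models."""

    area_red: int
    area_green: int
    area_blue: int
    L_feat: float
    a_feat: float
    b_feat: float
    n_fruit_px: int

    def __post_init__(self) -> None:
        if min(self.area_red, self.area_green, self.area_blue) < 0:
            raise ValueError("pixel areas must be non-negative")
        if self.area_red + self.area_green + self.area_blue > self.n_fruit_px:
            raise ValueError("classified areas cannot exceed the fruit pixel count")

    @property
    def ratio_ab(self) -> float:
        if self.b_feat == 0:
            raise ZeroDivisionError("a/b ratio undefined: b feature is zero")
        return self.a_feat / self.b_feat

    @property
    def redness_fraction(self) -> float:
        """area_red / (area_red + area_green); 0 when neither class occurs."""
        denom = self.area_red + self.area_green
        return self.area_red / denom if denom else 0.0

    def as_vector(self, names: tuple[str, ...]) -> np.ndarray:
        """Assemble a model input vector from named components."""
        table = {
            "area_red": self.area_red,
            "area_green": self.area_green,
            "area_blue": self.area_blue,
            "L": self.L_feat,
            "a": self.a_feat,
            "b": self.b_feat,
            "ratio_ab": self.ratio_ab if self.b_feat != 0 else np.nan,
        }
        return np.array([table[n] for n in names], dtype=float)


def classify_pixel_color(rgb, margin: int = 10) -> PixelClass:
    """Dominant-channel pixel class: RED/GREEN/BLUE if one channel exceeds
    both others by ``margin``, else NONE."""
    r, g, b = (int(c) for c in rgb)
    if not all(0 <= c <= 255 for c in (r, g, b)):
        raise ValueError(f"channel values must be in [0, 255], got {(r, g, b)}")
    if r > g + margin and r > b + margin:
        return PixelClass.RED
    if g > r + margin and g > b + margin:
        return PixelClass.GREEN
    if b > r + margin and b > g + margin:
        return PixelClass.BLUE
    return PixelClass.NONE


def _classify_array(px: np.ndarray, margin: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    r = px[..., 0].astype(np.int16)
    g = px[..., 1].astype(np.int16)
    b = px[..., 2].astype(np.int16)
    red = (r > g + margin) & (r > b + margin)
    green = (g > r + margin) & (g > b + margin)
    blue = (b > r + margin) & (b > g + margin)
    return red, green, blue


def extract_features(
    img: ImageRGB,
    m: FruitMask,
    scaling: FeatureScaling | None = None,
    margin: int = 10,
) -> ColorFeatures:
    """Reduce a segmented fruit image to its color-feature vector.

    Areas are raw masked-pixel counts per dominant-channel class; the Lab
    features are masked means mapped through ``scaling``.

    Raises
    ------
    EmptyMaskError
        If the mask contains no fruit pixels.
    """
    scaling = scaling or FeatureScaling()
    if img.pixels.shape[:2] != m.mask.shape:
        raise ValueError("image and mask shapes differ")
    if m.n_pixels == 0:
        raise EmptyMaskError("no fruit segmented: mask is empty")

    red, green, blue = _classify_array(img.pixels, margin)
    mask = m.mask
    lab = rgb_to_lab(img).pixels
    L_mean = float(lab[..., 0][mask].mean())
    a_mean = float(lab[..., 1][mask].mean())
    b_mean = float(lab[..., 2][mask].mean())
    L_feat, a_feat, b_feat = scaling.apply(L_mean, a_mean, b_mean)

    return ColorFeatures(
        area_red=int((red & mask).sum()),
        area_green=int((green & mask).sum()),
        area_blue=int((blue & mask).sum()),
        L_feat=L_feat,
        a_feat=a_feat,
        b_feat=b_feat,
        n_fruit_px=m.n_pixels,
    )


FEATURE_COLUMNS = [
    "image_id",
    "area_red",
    "area_green",
    "area_blue",
    "L_feat",
    "a_feat",
    "b_feat",
    "ratio_ab",
    "n_fruit_px",
]


def features_to_frame(rows: dict[str, ColorFeatures], labels: dict[str, float] | None = None) -> pd.DataFrame:
    """Tabulate per-image features (plus optional lycopene labels) as a DataFrame."""
    records = []
    for image_id, f in rows.items():
        rec = {
            "image_id": image_id,
            "area_red": f.area_red,
            "area_green": f.area_green,
            "area_blue": f.area_blue,
            "L_feat": f.L_feat,
            "a_feat": f.a_feat,
            "b_feat": f.b_feat,
            "ratio_ab": f.ratio_ab if f.b_feat != 0 else np.nan,
            "n_fruit_px": f.n_fruit_px,
        }
        if labels is not None:
            rec["lycopene_ppm"] = labels.get(image_id)
        records.append(rec)
    return pd.DataFrame.from_records(records)
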