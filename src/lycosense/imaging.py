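"""Image loading and color-space conversion.

Conventions used throughout the package:

* RGB images are 8-bit, ``(H, W, 3)`` uint8 arrays.
* HSV components are all unit-scaled to ``[0, 1]`` (the hue thresholds used
  by the segmentation stage are stated on a 0-1 hue scale).
* CIE-L*a*b* is computed for sRGB primaries under the D65 illuminant,
  2-degree observer; L* in ``[0, 100]``, a*/b* roughly ``[-128, 127]``.

The camera's actual color profile is unknown, so sRGB is assumed; this is
the dominant convention for consumer RGB cameras.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import color as skcolor


class ImageLoadError(IOError):
    """Raised when an image file cannot be read or decoded."""


@dataclass
class ImageRGB:
    """An 8-bit RGB image of a single fruit on a background.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array.
    source_tag
        Optional free-text provenance tag, e.g. the name of the optical
        bandpass filter the frame was captured through.
    """

    pixels: np.ndarray
    source_tag: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"RGB image must be (H, W, 3), got {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise ValueError("RGB channel values must be integers in [0, 255]")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ImageHSV:
    """Unit-scaled HSV image; every component in ``[0, 1]``."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"HSV image must be (H, W, 3), got {px.shape}")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("HSV components must lie in [0, 1]")
        self.pixels = np.clip(px, 0.0, 1.0)

    @property
    def hue(self) -> np.ndarray:
        return self.pixels[..., 0]

    @property
    def saturation(self) -> np.ndarray:
        return self.pixels[..., 1]

    @property
    def value(self) -> np.ndarray:
        return self.pixels[..., 2]


@dataclass
class ImageLab:
    """CIE-L*a*b* image (D65, 2-degree observer); L* in ``[0, 100]``."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"Lab image must be (H, W, 3), got {px.shape}")
        if not np.isfinite(px).all():
            raise ValueError("Lab values must be finite")
        L = px[..., 0]
        if L.min() < -1e-6 or L.max() > 100 + 1e-6:
            raise ValueError("L* must lie in [0, 100]")
        self.pixels = px

    @property
    def L(self) -> np.ndarray:
        return self.pixels[..., 0]

    @property
    def a(self) -> np.ndarray:
        return self.pixels[..., 1]

    @property
    def b(self) -> np.ndarray:
        return self.pixels[..., 2]


def load_image(path, source_tag: str | None = None) -> ImageRGB:
    """Load a JPEG or PNG file as an 8-bit RGB image.

    Grayscale inputs are replicated to three channels; 16-bit inputs are
    rescaled to [0, 255]; an alpha channel, if present, is dropped.

    Raises
    ------
    ImageLoadError
        If the file is missing, truncated, or not a decodable image.
    ValueError
        If the decoded image has zero size.
    """
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise ImageLoadError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path!r}")
    if arr.dtype == np.uint16:
        arr = (arr.astype(np.float64) * (255.0 / 65535.0)).round().astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.shape[2] == 4:
        arr = arr[..., :3]
    return ImageRGB(arr.astype(np.uint8), source_tag=source_tag)


def rgb_to_hsv(img: ImageRGB) -> ImageHSV:
    """Standard hexcone RGB→HSV conversion, all components in [0, 1]."""
    return ImageHSV(skcolor.rgb2hsv(img.pixels))


def hsv_to_rgb(img: ImageHSV) -> ImageRGB:
    """Inverse hexcone conversion back to 8-bit RGB."""
    rgb = skcolor.hsv2rgb(img.pixels)
    return ImageRGB(np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8))


def rgb_to_lab(img: ImageRGB) -> ImageLab:
    """sRGB → XYZ (D65, 2°) → CIE-L*a*b*."""
    return ImageLab(skcolor.rgb2lab(img.pixels / 255.0))
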