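"""Seeded synthetic tomato images, features and lycopene ground truth.

The generator emulates the bench conditions the sensor's models assume: a
single fruit, photographed against a uniform blue backdrop (hue 0.65, well
inside the background hue band the segmentation stage removes), across the
five visual maturity classes G (green), T (turned), P (pink), LR (light
red) and R (red). A fruit is an ellipse whose pixels draw from a red and a
green base color with a class-specific red fraction plus Gaussian jitter —
so the red-pixel fraction, like a real epicarp, grades smoothly from green
to fully red. Small non-fruit speckles (< 400 px each, in fruit-like hues)
are scattered on the backdrop to exercise the blob-size filter.

Ground-truth lycopene follows a monotone law anchored to the HPLC scale of
the real assay (~0-90 ppm):

    lycopene_ppm = lambda_max * r ** gamma + N(0, noise_sd),  truncated at 0,

with ``r = area_red / (area_red + area_green)`` measured on the generated
image. Defaults: lambda_max = 90 ppm, gamma = 1.5, noise_sd = 2 ppm. This
law is a synthetic stand-in chosen to reproduce the qualitative behaviour
of the real data (lycopene rising with red and falling with green pixel
area), not a measured relationship.

Everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .features import (
    A_DOMAIN,
    B_DOMAIN,
    L_DOMAIN,
    ColorFeatures,
    FeatureScaling,
    extract_features,
)
from .imaging import ImageRGB
from .segmentation import FruitMask

MATURITY_CLASSES = ("G", "T", "P", "LR", "R")

# Red fraction of the epicarp mixture per maturity class (G -> R progression).
DEFAULT_RED_FRACTIONS = {"G": 0.02, "T": 0.30, "P": 0.55, "LR": 0.75, "R": 0.95}


@dataclass
class LycopeneLaw:
    """lambda_max * r**gamma + N(0, noise_sd), truncated at 0 ppm."""

    lambda_max: float = 90.0
    gamma: float = 1.5
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.lambda_max <= 0 or self.noise_sd < 0:
            raise ValueError("lambda_max must be > 0 and noise_sd >= 0")

    def __call__(self, r: float, rng: np.random.Generator) -> float:
        val = self.lambda_max * r**self.gamma
        if self.noise_sd > 0:
            val += rng.normal(0.0, self.noise_sd)
        return max(0.0, float(val))


@dataclass
class GeneratorConfig:
    """Study design of the synthetic dataset.

    The default class counts mirror the real study's 18-fruit design
    (5 G / 3 T / 3 P / 2 LR / 5 R); the default image shape matches the
    sensor camera's 768 x 1366 frames.
    """

    class_counts: dict = field(
        default_factory=lambda: {"G": 5, "T": 3, "P": 3, "LR": 2, "R": 5}
    )
    image_shape: tuple[int, int] = (768, 1366)
    background_hue: float = 0.65
    background_rgb: tuple[int, int, int] = (86, 97, 191)  # hue 0.65, s .55, v .75
    red_base: tuple[int, int, int] = (185, 40, 35)
    green_base: tuple[int, int, int] = (70, 150, 60)
    red_fractions: dict = field(default_factory=lambda: dict(DEFAULT_RED_FRACTIONS))
    jitter_sd: float = 8.0
    speckle_count: int = 6
    speckle_max_radius: int = 10  # area pi*r^2 < 400 px
    lycopene_law: LycopeneLaw = field(default_factory=LycopeneLaw)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if isinstance(self.lycopene_law, dict):
            self.lycopene_law = LycopeneLaw(**self.lycopene_law)

    @property
    def n_samples(self) -> int:
        return sum(self.class_counts.values())


@dataclass
class SyntheticSample:
    sample_id: str
    maturity_class: str
    image: ImageRGB
    true_mask: FruitMask
    features: ColorFeatures
    lycopene_ppm: float


@dataclass
class LabeledDataset:
    """Synthetic study: one labeled row per fruit."""

    samples: list[SyntheticSample]
    config: GeneratorConfig

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for s in self.samples:
            f = s.features
            recs.append(
                {
                    "image_id": s.sample_id,
                    "maturity_class": s.maturity_class,
                    "area_red": f.area_red,
                    "area_green": f.area_green,
                    "area_blue": f.area_blue,
                    "L_feat": f.L_feat,
                    "a_feat": f.a_feat,
                    "b_feat": f.b_feat,
                    "ratio_ab": f.ratio_ab if f.b_feat != 0 else np.nan,
                    "n_fruit_px": f.n_fruit_px,
                    "lycopene_ppm": s.lycopene_ppm,
                }
            )
        return pd.DataFrame.from_records(recs)

    def write(self, outdir) -> None:
        """Dump images as PNG, the feature table as CSV and a YAML sidecar
        recording config and seed."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for s in self.samples:
            Image.fromarray(s.image.pixels).save(out / f"{s.sample_id}.png")
            Image.fromarray(s.true_mask.mask.astype(np.uint8) * 255).save(
                out / f"{s.sample_id}_mask.png"
            )
        self.to_frame().to_csv(out / "features.csv", index=False)
        cfg = asdict(self.config)
        cfg["image_shape"] = list(self.config.image_shape)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)


def _ellipse_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    cy, cx = h / 2.0, w / 2.0
    ry = h * rng.uniform(0.28, 0.34)
    rx = w * rng.uniform(0.20, 0.26)
    yy, xx = np.ogrid[:h, :w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_tomato_image(
    maturity_class: str,
    cfg: GeneratorConfig | None = None,
    seed: int | None = None,
) -> tuple[ImageRGB, FruitMask]:
    """Render one synthetic fruit image and its true foreground mask.

    The mask covers the fruit ellipse only; injected speckles are not part
    of it (they are the debris the segmentation stage must discard).
    """
    cfg = cfg or GeneratorConfig()
    if maturity_class not in cfg.red_fractions:
        raise ValueError(f"unknown maturity class {maturity_class!r}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    h, w = cfg.image_shape

    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(cfg.background_rgb, dtype=float)

    fruit = _ellipse_mask((h, w), rng)
    p_red = cfg.red_fractions[maturity_class]
    is_red = rng.random((h, w)) < p_red
    base = np.where(
        is_red[..., None], np.asarray(cfg.red_base, float), np.asarray(cfg.green_base, float)
    )
    img[fruit] = base[fruit]

    # debris speckles on the backdrop, fruit-hued so only the area filter kills them
    cy, cx = h / 2.0, w / 2.0
    placed = []
    attempts = 0
    while len(placed) < cfg.speckle_count and attempts < 200:
        attempts += 1
        r = int(rng.integers(3, cfg.speckle_max_radius + 1))
        y = int(rng.integers(r + 1, h - r - 1))
        x = int(rng.integers(r + 1, w - r - 1))
        # keep clear of the fruit and of other speckles so blobs stay < 400 px
        if ((y - cy) / (h * 0.40)) ** 2 + ((x - cx) / (w * 0.32)) ** 2 <= 1.0:
            continue
        if any((y - py) ** 2 + (x - px) ** 2 < (r + pr + 4) ** 2 for py, px, pr in placed):
            continue
        yy, xx = np.ogrid[:h, :w]
        spot = (yy - y) ** 2 + (xx - x) ** 2 <= r**2
        img[spot] = np.asarray(cfg.red_base, dtype=float)
        placed.append((y, x, r))

    img += rng.normal(0.0, cfg.jitter_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ImageRGB(pixels), FruitMask(fruit)


def generate_dataset(cfg: GeneratorConfig | None = None) -> LabeledDataset:
    """Generate the full synthetic study.

    Features are extracted on the true mask; the lycopene label applies the
    configured law to the measured red-pixel fraction.
    """
    cfg = cfg or GeneratorConfig()
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = ss.generate_state(2 * cfg.n_samples)
    samples = []
    i = 0
    for cls in MATURITY_CLASSES:
        for k in range(cfg.class_counts.get(cls, 0)):
            img, mask = generate_tomato_image(cls, cfg, seed=int(child_seeds[2 * i]))
            feats = extract_features(img, mask)
            rng = np.random.default_rng(int(child_seeds[2 * i + 1]))
            ppm = cfg.lycopene_law(feats.redness_fraction, rng)
            samples.append(
                SyntheticSample(
                    sample_id=f"{cls}{k + 1:02d}",
                    maturity_class=cls,
                    image=img,
                    true_mask=mask,
                    features=feats,
                    lycopene_ppm=ppm,
                )
            )
            i += 1
    return LabeledDataset(samples=samples, config=cfg)


def default_feature_law(L: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smooth synthetic lycopene surface over the fuzzy feature domains:
    rises with the red-green coordinate a, modulated by b."""
    an = a / A_DOMAIN[1]
    bn = (b - B_DOMAIN[0]) / (B_DOMAIN[1] - B_DOMAIN[0])
    return 90.0 * an**1.5 * (0.6 + 0.4 * bn)


def generate_feature_table(
    n: int,
    cfg: GeneratorConfig | None = None,
    seed: int | None = None,
    law=None,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Sample (L, a, b) uniformly from the fuzzy input domains and label
    them with a smooth lycopene surface plus noise.

    Bypasses imaging entirely — this is the table used to exercise the
    fuzzy engine's fit/predict path on its own. ``law`` may be any
    callable ``(L, a, b) -> ppm``; a planted Takagi-Sugeno model's predict
    can be passed through it for recovery experiments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    eps = 1e-6
    L = rng.uniform(L_DOMAIN[0] + eps, L_DOMAIN[1], n)
    a = rng.uniform(A_DOMAIN[0] + eps, A_DOMAIN[1], n)
    b = rng.uniform(B_DOMAIN[0] + eps, B_DOMAIN[1], n)
    custom = law is not None
    law = law or default_feature_law
    y = np.asarray(law(L, a, b), dtype=float)
    sd = cfg.lycopene_law.noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        y = y + rng.normal(0.0, sd, n)
    if not custom:
        # the default surface is a concentration; a custom law is used as-is
        y = np.maximum(y, 0.0)
    return pd.DataFrame(
        {
            "image_id": [f"f{i:04d}" for i in range(n)],
            "L_feat": L,
            "a_feat": a,
            "b_feat": b,
            "ratio_ab": a / b,
            "lycopene_ppm": y,
        }
    )
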