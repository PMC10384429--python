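"""End-to-end orchestration: image → mask → features → model → ppm.

`predict_from_image` runs the four sensor stages (acquisition,
segmentation, region-of-interest feature extraction, model evaluation) on
one image file. `run_study` builds or loads a labeled dataset, trains the
configured model specs and writes the comparison report.

Negative raw model outputs are clamped to 0 ppm at this boundary — a
concentration cannot be negative — with the raw value kept in the record
and the log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import evaluation, fuzzy, regressors
from .evaluation import EvaluationReport, ModelSpec
from .features import EmptyMaskError, FeatureScaling, extract_features
from .imaging import load_image, rgb_to_hsv
from .segmentation import SegmentationConfig, filter_small_regions, segment_fruit
from .synthetic import GeneratorConfig, generate_dataset

logger = logging.getLogger(__name__)

MODEL_KINDS = ("MNFR", "MNNR", "LR")


class NoFruitError(ValueError):
    """Segmentation found no fruit in the image."""


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    scaling: FeatureScaling = field(default_factory=FeatureScaling)
    model_path: str | None = None
    model_kind: str = "MNFR"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        logging.getLogger("lycosense").setLevel(self.log_level)

    def hash(self) -> str:
        payload = json.dumps(
            {
                "segmentation": vars(self.segmentation),
                "scaling": vars(self.scaling),
                "model_path": self.model_path,
                "model_kind": self.model_kind,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PredictionRecord:
    image_id: str
    lycopene_ppm: float
    raw_ppm: float
    n_fruit_px: int
    model_name: str
    config_hash: str


def load_model(cfg: PipelineConfig):
    if cfg.model_path is None:
        raise ValueError("PipelineConfig.model_path is not set")
    if cfg.model_kind == "MNFR":
        return fuzzy.TakagiSugenoModel.from_json(cfg.model_path)
    if cfg.model_kind == "MNNR":
        return regressors.MLPModel.from_json(cfg.model_path)
    with open(cfg.model_path) as fh:
        d = json.load(fh)
    return regressors.LinearModel(slope=d["slope"], intercept=d["intercept"])


def _model_predict(cfg: PipelineConfig, model, feats) -> float:
    if cfg.model_kind == "MNFR":
        x = feats.as_vector(("L", "a", "b"))
        return float(fuzzy.predict(model, x))
    if cfg.model_kind == "MNNR":
        x = feats.as_vector(("L", "a", "b"))[None, :]
        return float(regressors.mlp_predict(model, x)[0])
    return float(model.predict([feats.ratio_ab])[0])


def predict_from_image(path, cfg: PipelineConfig, model=None) -> PredictionRecord:
    """Run the full sensor pipeline on one image file.

    Raises
    ------
    NoFruitError
        If nothing survives segmentation and blob filtering.
    fuzzy.RuleCoverageError
        If the fuzzy model's rule base does not cover the extracted features.
    """
    model = model if model is not None else load_model(cfg)
    img = load_image(path)
    mask = filter_small_regions(
        segment_fruit(rgb_to_hsv(img), cfg.segmentation), cfg.segmentation.min_area
    )
    if mask.n_pixels == 0:
        raise NoFruitError(f"no fruit found in {path!r} after segmentation")
    try:
        feats = extract_features(img, mask, cfg.scaling)
    except EmptyMaskError as exc:  # pragma: no cover - guarded above
        raise NoFruitError(str(exc)) from exc
    raw = _model_predict(cfg, model, feats)
    ppm = raw
    if raw < 0:
        logger.info("negative raw prediction %.4f ppm clamped to 0 for %s", raw, path)
        ppm = 0.0
    return PredictionRecord(
        image_id=pathlib.Path(path).stem,
        lycopene_ppm=ppm,
        raw_ppm=raw,
        n_fruit_px=mask.n_pixels,
        model_name=cfg.model_kind,
        config_hash=cfg.hash(),
    )


DEFAULT_SPECS = [
    ModelSpec(name="MNFR-Lab", technique="MNFR", inputs=("L", "a", "b")),
    ModelSpec(name="MNNR-Lab", technique="MNNR", inputs=("L", "a", "b")),
    ModelSpec(name="MNNR-areas", technique="MNNR", inputs=("area_red", "area_green", "area_blue")),
    ModelSpec(name="LR-ab", technique="LR", inputs=("ratio_ab",)),
]


@dataclass
class StudyConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    specs: list[ModelSpec] = field(default_factory=lambda: list(DEFAULT_SPECS))
    outdir: str | None = None
    loo: bool = False


def run_study(cfg: StudyConfig | None = None, frame: pd.DataFrame | None = None) -> EvaluationReport:
    """Train and compare all configured models on a labeled feature table.

    If ``frame`` is not given, the synthetic study is generated from
    ``cfg.generator`` (fully seeded, hence re-runnable to identical
    numbers). With ``outdir`` set, the report CSV and the fitted fuzzy /
    MLP / linear models are written there.
    """
    cfg = cfg or StudyConfig()
    if frame is None:
        logger.info("generating synthetic study: %d samples", cfg.generator.n_samples)
        dataset = generate_dataset(cfg.generator)
        frame = dataset.to_frame()
    colmap = {"L": "L_feat", "a": "a_feat", "b": "b_feat"}
    specs = []
    for spec in cfg.specs:
        missing = [c for c in spec.inputs if colmap.get(c, c) not in frame.columns]
        if missing:
            logger.warning("skipping model %s: dataset lacks column(s) %s", spec.name, missing)
        else:
            specs.append(spec)
    cfg = replace(cfg, specs=specs)
    report = evaluation.compare_models(frame, cfg.specs, seed=cfg.generator.seed, loo=cfg.loo)
    if cfg.outdir:
        out = pathlib.Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.csv")
        _write_models(out, frame, cfg)
    return report


def _write_models(out: pathlib.Path, frame: pd.DataFrame, cfg: StudyConfig) -> None:
    y = frame["lycopene_ppm"].to_numpy(dtype=float)
    colmap = {"L": "L_feat", "a": "a_feat", "b": "b_feat"}
    for spec in cfg.specs:
        cols = [colmap.get(c, c) for c in spec.inputs]
        X = frame[cols].to_numpy(dtype=float)
        path = out / f"{spec.name}.json"
        if spec.technique == "MNFR":
            model = fuzzy.fit_consequents(fuzzy.build_default_model(), X, y)
            model.to_json(path)
        elif spec.technique == "MNNR":
            tc = regressors.TrainingConfig(epochs=spec.epochs, seed=spec.seed)
            regressors.train_mlp(X, y, tc, hidden_units=spec.hidden_units).to_json(path)
        else:
            lm = regressors.fit_linear_ab(X[:, 0], y)
            with open(path, "w") as fh:
                json.dump({"slope": lm.slope, "intercept": lm.intercept}, fh)
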