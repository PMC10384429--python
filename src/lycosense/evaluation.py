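"""Model-comparison metrics and report generation.

The comparison harness fits each requested model (LR — linear regression on
the a/b ratio; MNNR — multiple nonlinear neural regression, the small MLP;
MNFR — multiple nonlinear fuzzy regression, the Takagi-Sugeno system) on a
labeled dataset and reports, per model, the squared Pearson correlation
between observed and predicted lycopene (the headline "R²"), the
coefficient of determination 1 - SSE/SST, and the signed mean residual.

By default metrics are computed on the training set itself (the
calibration protocol of a small-sample sensor study); leave-one-out
cross-validation can be reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fuzzy, regressors

TECHNIQUES = ("LR", "MNNR", "MNFR")


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (a constant vector)."""


def r_squared(obs, pred) -> float:
    """Squared Pearson correlation between observed and predicted values.

    Affine-invariant in either argument; raises if ``obs`` is constant.
    """
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.size != pred.size or obs.size < 2:
        raise ValueError("obs and pred must have equal length >= 2")
    if np.ptp(obs) == 0:
        raise UndefinedCorrelationError("observed values are constant")
    if np.ptp(pred) == 0:
        raise UndefinedCorrelationError("predicted values are constant")
    c = np.corrcoef(obs, pred)[0, 1]
    return float(c * c)


def determination(obs, pred) -> float:
    """Coefficient of determination 1 - SSE/SST (can be negative)."""
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        raise UndefinedCorrelationError("observed values are constant")
    sse = float(((obs - pred) ** 2).sum())
    return 1.0 - sse / sst


def mean_error(obs, pred) -> float:
    """Signed mean residual, mean(pred - obs)."""
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.size == 0 or obs.size != pred.size:
        raise ValueError("obs and pred must be non-empty and equal length")
    return float(np.mean(pred - obs))


@dataclass
class ModelSpec:
    """One row of the comparison: a technique, an input set, hyperparameters."""

    name: str
    technique: str  # LR | MNNR | MNFR
    inputs: tuple[str, ...]
    epochs: int = 10
    seed: int = 0
    hidden_units: int = 10
    t_norm: str = "product"
    order: str = "one"

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}; expected one of {TECHNIQUES}")


@dataclass
class EvaluationRow:
    name: str
    technique: str
    inputs: tuple[str, ...]
    r_squared: float
    determination: float
    error_mean: float
    loo_r_squared: float | None = None


@dataclass
class EvaluationReport:
    rows: list[EvaluationRow]
    seed: int
    split_policy: str = "training-set"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": r.name,
                    "technique": r.technique,
                    "inputs": "+".join(r.inputs),
                    "r_squared": r.r_squared,
                    "determination": r.determination,
                    "error_mean": r.error_mean,
                    "loo_r_squared": r.loo_r_squared,
                }
                for r in self.rows
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def pretty(self) -> str:
        return self.to_frame().to_string(index=False)


def _fit_predict(technique, Xtr, ytr, Xte, spec: ModelSpec):
    if technique == "LR":
        model = regressors.fit_linear_ab(Xtr[:, 0], ytr)
        return model, model.predict(Xte[:, 0])
    if technique == "MNNR":
        cfg = regressors.TrainingConfig(epochs=spec.epochs, seed=spec.seed)
        model = regressors.train_mlp(Xtr, ytr, cfg, hidden_units=spec.hidden_units)
        return model, regressors.mlp_predict(model, Xte)
    # MNFR: the three-input default system requires the (L, a, b) input set
    if tuple(spec.inputs) != ("L", "a", "b"):
        raise ValueError(
            "MNFR uses the default (L, a, b) membership functions; "
            f"got inputs {spec.inputs}. Supply membership breakpoints via a "
            "custom TakagiSugenoModel for other input sets."
        )
    base = fuzzy.build_default_model(t_norm=spec.t_norm, order=spec.order)
    model = fuzzy.fit_consequents(base, Xtr, ytr)
    return model, np.atleast_1d(fuzzy.predict(model, Xte))


def compare_models(
    frame: pd.DataFrame,
    specs: list[ModelSpec],
    *,
    seed: int = 0,
    loo: bool = False,
) -> EvaluationReport:
    """Fit every spec on the labeled feature table and report metrics.

    ``frame`` must carry the input columns each spec names (``L_feat``,
    ``a_feat``, ``b_feat`` map to ``L``/``a``/``b``) plus ``lycopene_ppm``.
    Metrics are training-set by default; ``loo=True`` adds leave-one-out
    Pearson-squared per model. Rows are sorted by descending R².
    """
    colmap = {"L": "L_feat", "a": "a_feat", "b": "b_feat"}
    y = frame["lycopene_ppm"].to_numpy(dtype=float)
    rows = []
    for spec in specs:
        cols = [colmap.get(c, c) for c in spec.inputs]
        X = frame[cols].to_numpy(dtype=float)
        _, pred = _fit_predict(spec.technique, X, y, X, spec)
        loo_r2 = None
        if loo:
            loo_pred = np.empty_like(y)
            for i in range(y.size):
                keep = np.arange(y.size) != i
                _, p = _fit_predict(spec.technique, X[keep], y[keep], X[i : i + 1], spec)
                loo_pred[i] = np.atleast_1d(p)[0]
            loo_r2 = r_squared(y, loo_pred)
        rows.append(
            EvaluationRow(
                name=spec.name,
                technique=spec.technique,
                inputs=tuple(spec.inputs),
                r_squared=r_squared(y, pred),
                determination=determination(y, pred),
                error_mean=mean_error(y, pred),
                loo_r_squared=loo_r2,
            )
        )
    rows.sort(key=lambda r: -r.r_squared)
    return EvaluationReport(rows=rows, seed=seed)
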