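"""Takagi-Sugeno fuzzy regression engine for lycopene estimation.

The estimator fuzzifies three color inputs (L, a, b, in the sensor's
feature units) through fixed triangular membership functions, fires a full
grid of inference rules with a product (or min) t-norm, and defuzzifies by
the firing-strength-weighted average of the rule output levels

    output = sum_i(w_i * Z_i) / sum_i(w_i),

where ``Z_i`` is the i-th rule's output level (a linear function of the
inputs for a first-order model, a constant for zero order) and ``w_i`` its
firing strength. Consequent coefficients are fitted by the ANFIS hybrid
step: with premises fixed, the output is linear in the consequent
parameters, so they are solved by (minimum-norm) linear least squares on
the normalized-firing-strength design matrix.

Membership layout of the default model
--------------------------------------
* ``L`` on (0, 2558.3]: Low (shoulder falling 0→1285), Medium (triangle
  10.7 / 1285 / 2558.3), High (shoulder rising 1285→2558.3).
* ``a`` on (0, 1736]: Low (shoulder falling 0→753), Medium (triangle
  0 / 753 / 1736), High (shoulder rising 753→1736).
* ``b`` on (-210, 358]: Low (shoulder falling 210→358, clipped to 1 below
  210), High (shoulder rising 210→358).

That is 8 membership functions; the full 3 x 3 x 2 antecedent grid gives
18 rules. Degrees are always clipped to [0, 1], and the a- and b-variable
neighbours form exact partitions of unity on their shared supports.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)


class RuleCoverageError(ValueError):
    """No rule fires for the given input (sum of firing strengths is zero)."""


# ---------------------------------------------------------------------------
# Membership functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriangularMF:
    """A (possibly shoulder-shaped) triangular membership function.

    ``feet_left == peak`` makes a left shoulder (no rising constraint, so
    the falling line is simply clipped at 1 below the peak); likewise
    ``peak == feet_right`` makes a right shoulder. Values outside
    ``domain`` (open lower bound, closed upper bound) get degree 0.
    """

    name: str
    feet_left: float
    peak: float
    feet_right: float
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.feet_left <= self.peak <= self.feet_right:
            raise ValueError(f"{self.name}: need feet_left <= peak <= feet_right")
        if self.feet_left == self.peak == self.feet_right:
            raise ValueError(f"{self.name}: singleton support not allowed")

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        lo, hi = self.domain
        rise = np.full_like(x, np.inf)
        if self.peak > self.feet_left:
            rise = (x - self.feet_left) / (self.peak - self.feet_left)
        fall = np.full_like(x, np.inf)
        if self.feet_right > self.peak:
            fall = (self.feet_right - x) / (self.feet_right - self.peak)
        deg = np.clip(np.minimum(rise, fall), 0.0, 1.0)
        deg = np.where((x > lo) & (x <= hi), deg, 0.0)
        return float(deg) if deg.ndim == 0 else deg


def membership(mf: TriangularMF, x) -> np.ndarray | float:
    """Degree of membership of ``x`` in ``mf``, clipped to [0, 1]."""
    return mf(x)


@dataclass(frozen=True)
class FuzzyVariable:
    """An input variable with an ordered list of membership functions."""

    name: str
    mfs: tuple[TriangularMF, ...]
    domain: tuple[float, float]

    def degrees(self, x) -> np.ndarray:
        return np.stack([mf(x) for mf in self.mfs], axis=-1)


# ---------------------------------------------------------------------------
# Rules and model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FuzzyRule:
    """One inference rule: an MF index per input variable plus a linear
    consequent ``Z(x) = coeffs . x + intercept``."""

    antecedent: tuple[int, ...]
    coeffs: tuple[float, ...]
    intercept: float = 0.0


@dataclass
class TakagiSugenoModel:
    """A Takagi-Sugeno fuzzy system: variables, a rule base, a t-norm and
    a consequent order ("zero" for constant rule outputs, "one" for linear)."""

    variables: tuple[FuzzyVariable, ...]
    rules: tuple[FuzzyRule, ...]
    t_norm: str = "product"
    order: str = "one"
    fit_report: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.t_norm not in ("product", "min"):
            raise ValueError("t_norm must be 'product' or 'min'")
        if self.order not in ("zero", "one"):
            raise ValueError("order must be 'zero' or 'one'")
        for r in self.rules:
            if len(r.antecedent) != len(self.variables):
                raise ValueError("rule antecedent length != number of variables")
            for idx, var in zip(r.antecedent, self.variables):
                if not 0 <= idx < len(var.mfs):
                    raise ValueError(f"antecedent index {idx} invalid for {var.name}")

    # -- structure ---------------------------------------------------------
    @property
    def n_inputs(self) -> int:
        return len(self.variables)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def n_membership_functions(self) -> int:
        return sum(len(v.mfs) for v in self.variables)

    @property
    def n_consequent_params(self) -> int:
        per_rule = self.n_inputs + 1 if self.order == "one" else 1
        return self.n_rules * per_rule

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "t_norm": self.t_norm,
            "order": self.order,
            "variables": [
                {
                    "name": v.name,
                    "domain": list(v.domain),
                    "mfs": [
                        {
                            "name": m.name,
                            "feet_left": m.feet_left,
                            "peak": m.peak,
                            "feet_right": m.feet_right,
                            "domain": list(m.domain),
                        }
                        for m in v.mfs
                    ],
                }
                for v in self.variables
            ],
            "rules": [
                {
                    "antecedent": list(r.antecedent),
                    "coeffs": list(r.coeffs),
                    "intercept": r.intercept,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TakagiSugenoModel":
        variables = tuple(
            FuzzyVariable(
                name=v["name"],
                domain=tuple(v["domain"]),
                mfs=tuple(
                    TriangularMF(
                        name=m["name"],
                        feet_left=m["feet_left"],
                        peak=m["peak"],
                        feet_right=m["feet_right"],
                        domain=tuple(m["domain"]),
                    )
                    for m in v["mfs"]
                ),
            )
            for v in d["variables"]
        )
        rules = tuple(
            FuzzyRule(
                antecedent=tuple(r["antecedent"]),
                coeffs=tuple(r["coeffs"]),
                intercept=r["intercept"],
            )
            for r in d["rules"]
        )
        return cls(variables=variables, rules=rules, t_norm=d["t_norm"], order=d["order"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TakagiSugenoModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Default model from the sensor's membership equations
# ---------------------------------------------------------------------------

L_DOMAIN = (0.0, 2558.3)
A_DOMAIN = (0.0, 1736.0)
B_DOMAIN = (-210.0, 358.0)


def build_default_variables() -> tuple[FuzzyVariable, FuzzyVariable, FuzzyVariable]:
    L = FuzzyVariable(
        name="L",
        domain=L_DOMAIN,
        mfs=(
            TriangularMF("Low_L", 0.0, 0.0, 1285.0, L_DOMAIN),
            TriangularMF("Medium_L", 10.7, 1285.0, 2558.3, L_DOMAIN),
            TriangularMF("High_L", 1285.0, 2558.3, 2558.3, L_DOMAIN),
        ),
    )
    a = FuzzyVariable(
        name="a",
        domain=A_DOMAIN,
        mfs=(
            TriangularMF("Low_a", 0.0, 0.0, 753.0, A_DOMAIN),
            TriangularMF("Medium_a", 0.0, 753.0, 1736.0, A_DOMAIN),
            TriangularMF("High_a", 753.0, 1736.0, 1736.0, A_DOMAIN),
        ),
    )
    b = FuzzyVariable(
        name="b",
        domain=B_DOMAIN,
        mfs=(
            TriangularMF("Low_b", 210.0, 210.0, 358.0, B_DOMAIN),
            TriangularMF("High_b", 210.0, 358.0, 358.0, B_DOMAIN),
        ),
    )
    return L, a, b


def build_default_model(t_norm: str = "product", order: str = "one") -> TakagiSugenoModel:
    """The default three-input lycopene estimator: 8 membership functions
    (3 for L, 3 for a, 2 for b) and the full 3x3x2 = 18-rule grid, with
    consequents initialized to zero."""
    variables = build_default_variables()
    n_in = len(variables)
    rules = tuple(
        FuzzyRule(antecedent=combo, coeffs=(0.0,) * n_in, intercept=0.0)
        for combo in itertools.product(*(range(len(v.mfs)) for v in variables))
    )
    return TakagiSugenoModel(variables=variables, rules=rules, t_norm=t_norm, order=order)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _degree_matrix(model: TakagiSugenoModel, X: np.ndarray) -> list[np.ndarray]:
    """Per-variable degree arrays, each (n_samples, n_mfs_of_variable)."""
    return [v.degrees(X[:, j]) for j, v in enumerate(model.variables)]


def rule_strengths(model: TakagiSugenoModel, x) -> np.ndarray:
    """Firing strength w_i of every rule at input ``x`` (or rows of X).

    w_i is the t-norm (product by default, min optionally) of the
    antecedent membership degrees; every w_i lies in [0, 1].
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} inputs, got {X.shape[1]}")
    degs = _degree_matrix(model, X)
    W = np.empty((X.shape[0], model.n_rules))
    for i, rule in enumerate(model.rules):
        cols = [degs[j][:, idx] for j, idx in enumerate(rule.antecedent)]
        stacked = np.stack(cols, axis=0)
        W[:, i] = stacked.prod(axis=0) if model.t_norm == "product" else stacked.min(axis=0)
    return W[0] if np.ndim(x) == 1 else W


def rule_outputs(model: TakagiSugenoModel, x) -> np.ndarray:
    """Output level Z_i of every rule at ``x`` (rows allowed)."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    P = np.array([r.coeffs for r in model.rules])        # (n_rules, n_in)
    r0 = np.array([r.intercept for r in model.rules])    # (n_rules,)
    Z = r0[None, :] if model.order == "zero" else X @ P.T + r0[None, :]
    if model.order == "zero":
        Z = np.broadcast_to(Z, (X.shape[0], model.n_rules)).copy()
    return Z[0] if np.ndim(x) == 1 else Z


def predict(model: TakagiSugenoModel, x) -> float | np.ndarray:
    """Defuzzified estimate: sum(w_i Z_i) / sum(w_i).

    Raises
    ------
    RuleCoverageError
        If no rule fires for some input row.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    W = np.atleast_2d(rule_strengths(model, X))
    wsum = W.sum(axis=1)
    if np.any(wsum <= 0):
        bad = np.flatnonzero(wsum <= 0)
        raise RuleCoverageError(
            f"input outside rule coverage (no rule fires) for row(s) {bad.tolist()}: "
            f"{X[bad[0]].tolist()}"
        )
    Z = np.atleast_2d(rule_outputs(model, X))
    out = (W * Z).sum(axis=1) / wsum
    return float(out[0]) if np.ndim(x) == 1 else out


# ---------------------------------------------------------------------------
# ANFIS hybrid fitting
# ---------------------------------------------------------------------------

def _design_matrix(model: TakagiSugenoModel, X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Normalized-firing-strength design matrix of the consequent LSE.

    Row j holds, for each rule i, ``wbar_ij * [x_j, 1]`` (first order) or
    ``wbar_ij`` (zero order), where wbar is w normalized over rules.
    """
    wbar = W / W.sum(axis=1, keepdims=True)
    if model.order == "zero":
        return wbar
    n, d = X.shape
    blocks = []
    for i in range(model.n_rules):
        blocks.append(wbar[:, i : i + 1] * X)
        blocks.append(wbar[:, i : i + 1])
    return np.concatenate(blocks, axis=1)


def fit_consequents(
    model: TakagiSugenoModel, X, y, *, rcond: float | None = None, warn_rejects: bool = True
) -> TakagiSugenoModel:
    """Fit rule consequents by the ANFIS least-squares step.

    Premise membership functions are held fixed; the consequent
    coefficients are the minimum-norm least-squares solution on the
    normalized-firing-strength design matrix. Samples that fire no rule
    are rejected with a warning; a rank-deficient design is solved
    minimum-norm with a logged warning. The returned model carries a
    ``fit_report`` with the residual norm and sample counts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_inputs) matching y")

    W = np.atleast_2d(rule_strengths(model, X))
    fires = W.sum(axis=1) > 0
    n_rejected = int((~fires).sum())
    if n_rejected:
        if warn_rejects:
            warnings.warn(
                f"{n_rejected} sample(s) fire no rule and were rejected from the fit",
                stacklevel=2,
            )
        X, y, W = X[fires], y[fires], W[fires]
    if X.shape[0] == 0:
        raise RuleCoverageError("no training sample fires any rule")

    A = _design_matrix(model, X, W)
    theta, residuals, rank, _ = np.linalg.lstsq(A, y, rcond=rcond)
    if rank < A.shape[1]:
        logger.warning(
            "consequent design is rank-deficient (rank %d < %d parameters); "
            "minimum-norm solution used",
            rank,
            A.shape[1],
        )

    per_rule = model.n_inputs + 1 if model.order == "one" else 1
    new_rules = []
    for i, rule in enumerate(model.rules):
        seg = theta[i * per_rule : (i + 1) * per_rule]
        if model.order == "one":
            new_rules.append(replace(rule, coeffs=tuple(seg[:-1]), intercept=float(seg[-1])))
        else:
            new_rules.append(replace(rule, coeffs=(0.0,) * model.n_inputs, intercept=float(seg[0])))

    fitted = replace(model, rules=tuple(new_rules))
    resid = A @ theta - y
    fitted.fit_report = {
        "n_samples": int(X.shape[0]),
        "n_rejected": n_rejected,
        "n_params": int(A.shape[1]),
        "design_rank": int(rank),
        "residual_norm": float(np.linalg.norm(resid)),
        "training_mse": float(np.mean(resid**2)),
    }
    return fitted


def fit_anfis(
    model: TakagiSugenoModel,
    X,
    y,
    *,
    epochs: int = 10,
    learn_premises: bool = False,
    step: float = 1.0,
) -> TakagiSugenoModel:
    """Hybrid ANFIS training.

    With ``learn_premises=False`` (the default, matching the fixed-formula
    premises of the sensor) this is a single consequent LSE pass. With
    ``learn_premises=True`` each epoch alternates a finite-difference
    descent step on the MF breakpoints (accepted only if training MSE
    decreases; the step is halved otherwise) with a consequent LSE.
    """
    fitted = fit_consequents(model, X, y)
    if not learn_premises:
        return fitted

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()

    base_rejected = fitted.fit_report["n_rejected"]

    def mse_of(m: TakagiSugenoModel):
        m2 = fit_consequents(m, X, y, warn_rejects=False)
        return m2.fit_report["training_mse"], m2

    best_mse, best = mse_of(fitted)
    h = step
    for _ in range(epochs):
        grad_model = _premise_gradient_step(best, X, y, best_mse, h, base_rejected)
        if grad_model is None:
            h *= 0.5
            continue
        cand_mse, cand = mse_of(grad_model)
        if cand_mse < best_mse and cand.fit_report["n_rejected"] <= base_rejected:
            best_mse, best = cand_mse, cand
        else:
            h *= 0.5
    return best


def _premise_gradient_step(model, X, y, base_mse, h, base_rejected=0):
    """One coordinate-wise finite-difference descent step over MF peaks and
    feet (domains fixed). Returns the perturbed model, or None if degenerate."""
    new_vars = []
    changed = False
    for v in model.variables:
        new_mfs = []
        for mf in v.mfs:
            params = {"feet_left": mf.feet_left, "peak": mf.peak, "feet_right": mf.feet_right}
            best_local = mf
            for key in params:
                for delta in (+h, -h):
                    trial = dict(params)
                    trial[key] = params[key] + delta
                    if not trial["feet_left"] <= trial["peak"] <= trial["feet_right"]:
                        continue
                    if trial["feet_left"] == trial["peak"] == trial["feet_right"]:
                        continue
                    cand_mf = TriangularMF(mf.name, trial["feet_left"], trial["peak"], trial["feet_right"], mf.domain)
                    cand_vars = tuple(
                        FuzzyVariable(vv.name, tuple(cand_mf if m is mf else m for m in vv.mfs), vv.domain)
                        if vv is v
                        else vv
                        for vv in model.variables
                    )
                    try:
                        cand_model = replace(model, variables=cand_vars)
                        cand_fit = fit_consequents(cand_model, X, y, warn_rejects=False)
                    except (RuleCoverageError, ValueError):
                        continue
                    # a candidate may not trade coverage for residual
                    if cand_fit.fit_report["n_rejected"] > base_rejected:
                        continue
                    if cand_fit.fit_report["training_mse"] < base_mse:
                        best_local = cand_mf
                        base_mse = cand_fit.fit_report["training_mse"]
            if best_local is not mf:
                changed = True
            new_mfs.append(best_local)
        new_vars.append(FuzzyVariable(v.name, tuple(new_mfs), v.domain))
    if not changed:
        return None
    return replace(model, variables=tuple(new_vars))
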