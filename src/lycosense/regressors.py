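"""Baseline lycopene estimators: a*/b* linear regression and a small MLP.

The linear model regresses lycopene (ppm) on the a/b chromaticity ratio by
ordinary least squares — the classic low-cost ripeness index.

The neural baseline is a single-hidden-layer feed-forward network
(default 10 sigmoid hidden units, one linear output) trained by
Levenberg-Marquardt: damped Gauss-Newton on the Jacobian of the residuals,
the standard trainer for small regression networks. Because the output
layer is linear in its parameters, each candidate LM step is followed by
an exact least-squares re-solve of the output weights (the separable /
variable-projection refinement), which makes convergence fast and robust
from random initializations. Inputs and target are z-scored internally
(the inverse transform is applied at predict time); weights are
initialized uniformly in [-0.5, 0.5] from a seeded generator, so training
is bit-reproducible. One "epoch" is one accepted LM step; the damping
factor lambda starts at 1e-3, is multiplied by 10 on a rejected step and
divided by 10 on an accepted one, and a step is accepted only if it lowers
the training MSE, so the accepted-step loss trace is non-increasing by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


class DegenerateDesignError(ValueError):
    """The regression design has no variation to fit."""


# ---------------------------------------------------------------------------
# Linear regression on the a/b ratio
# ---------------------------------------------------------------------------

@dataclass
class LinearModel:
    """y = slope * ratio + intercept, in ppm."""

    slope: float
    intercept: float

    def predict(self, ratios) -> np.ndarray:
        return self.slope * np.asarray(ratios, dtype=float) + self.intercept


def fit_linear_ab(ratios, y) -> LinearModel:
    """Ordinary least-squares fit of lycopene on the a/b ratio.

    Raises
    ------
    DegenerateDesignError
        If all ratio values are identical (slope undefined).
    """
    x = np.asarray(ratios, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two (ratio, y) pairs of equal length")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all ratio values identical; slope undefined")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    return LinearModel(slope=float(slope), intercept=float(intercept))


# ---------------------------------------------------------------------------
# Feed-forward network trained by Levenberg-Marquardt
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    epochs: int = 10
    seed: int = 0
    lam0: float = 1e-3
    lam_up: float = 10.0
    lam_down: float = 10.0
    max_rejects: int = 25


@dataclass
class MLPModel:
    """(n_inputs) -> sigmoid(hidden_units) -> linear(1) regression network.

    Weights live on standardized coordinates; ``x_mean``/``x_std`` and
    ``y_mean``/``y_std`` hold the z-score parameters applied around the
    forward pass.
    """

    n_inputs: int
    hidden_units: int
    W1: np.ndarray  # (hidden, n_inputs)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: float
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float = 0.0
    y_std: float = 1.0
    loss_trace: list[float] = field(default_factory=list, compare=False)

    def to_json(self, path) -> None:
        d = {
            "n_inputs": self.n_inputs,
            "hidden_units": self.hidden_units,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2,
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MLPModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            n_inputs=d["n_inputs"],
            hidden_units=d["hidden_units"],
            W1=np.array(d["W1"], dtype=float),
            b1=np.array(d["b1"], dtype=float),
            W2=np.array(d["W2"], dtype=float),
            b2=float(d["b2"]),
            x_mean=np.array(d["x_mean"], dtype=float),
            x_std=np.array(d["x_std"], dtype=float),
            y_mean=float(d["y_mean"]),
            y_std=float(d["y_std"]),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _pack(W1, b1, W2, b2) -> np.ndarray:
    return np.concatenate([W1.ravel(), b1, W2, [b2]])


def _unpack(theta: np.ndarray, n_in: int, n_hid: int):
    i = 0
    W1 = theta[i : i + n_hid * n_in].reshape(n_hid, n_in); i += n_hid * n_in
    b1 = theta[i : i + n_hid]; i += n_hid
    W2 = theta[i : i + n_hid]; i += n_hid
    b2 = theta[i]
    return W1, b1, W2, b2


def _forward_std(theta: np.ndarray, Xs: np.ndarray, n_in: int, n_hid: int):
    W1, b1, W2, b2 = _unpack(theta, n_in, n_hid)
    A = _sigmoid(Xs @ W1.T + b1)        # (n, hid)
    return A @ W2 + b2, A


def _jacobian(theta: np.ndarray, Xs: np.ndarray, n_in: int, n_hid: int) -> np.ndarray:
    """Analytic Jacobian of the network output wrt all parameters."""
    W1, b1, W2, b2 = _unpack(theta, n_in, n_hid)
    A = _sigmoid(Xs @ W1.T + b1)
    dA = A * (1.0 - A)                  # (n, hid)
    n = Xs.shape[0]
    # d out / d W1[k, j] = W2[k] * dA[:, k] * Xs[:, j]
    J_W1 = (W2[None, :, None] * dA[:, :, None] * Xs[:, None, :]).reshape(n, n_hid * n_in)
    J_b1 = W2[None, :] * dA
    J_W2 = A
    J_b2 = np.ones((n, 1))
    return np.concatenate([J_W1, J_b1, J_W2, J_b2], axis=1)


def mlp_predict(model: MLPModel, X) -> np.ndarray:
    """Deterministic forward pass: z-score, sigmoid hidden layer, linear
    output, then y de-standardization."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} input columns, got {X.shape[1]}")
    Xs = (X - model.x_mean) / model.x_std
    theta = _pack(model.W1, model.b1, model.W2, model.b2)
    out, _ = _forward_std(theta, Xs, model.n_inputs, model.hidden_units)
    return out * model.y_std + model.y_mean


def train_mlp(X, y, cfg: TrainingConfig | None = None, hidden_units: int = 10) -> MLPModel:
    """Train the network by Levenberg-Marquardt.

    Each epoch attempts one LM step: the damped normal equations
    ``(J'J + lambda I) delta = J' r`` are solved and the step accepted only
    if it lowers the training MSE (lambda is raised tenfold and the solve
    retried otherwise, up to ``max_rejects`` times). The returned model's
    ``loss_trace`` holds the MSE (in original y units) after each accepted
    step; it is non-increasing. ``epochs=0`` returns the freshly
    initialized network unchanged.
    """
    cfg = cfg or TrainingConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows must match y length")
    n, n_in = X.shape

    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0)
    x_std[x_std == 0] = 1.0
    y_mean = float(y.mean())
    y_std = float(y.std()) or 1.0
    Xs = (X - x_mean) / x_std
    ys = (y - y_mean) / y_std

    rng = np.random.default_rng(cfg.seed)
    n_params = n_in * hidden_units + hidden_units + hidden_units + 1
    theta = rng.uniform(-0.5, 0.5, size=n_params)

    def mse(t):
        out, _ = _forward_std(t, Xs, n_in, hidden_units)
        r = out - ys
        return float(np.mean(r**2)), r

    def resolve_output(t: np.ndarray) -> np.ndarray:
        """Exact least-squares solve of the linear output layer."""
        W1, b1, _, _ = _unpack(t, n_in, hidden_units)
        A = _sigmoid(Xs @ W1.T + b1)
        M = np.column_stack([A, np.ones(Xs.shape[0])])
        sol, *_ = np.linalg.lstsq(M, ys, rcond=None)
        out = t.copy()
        out[n_in * hidden_units + hidden_units :] = sol
        return out

    loss_trace: list[float] = []
    lam = cfg.lam0
    cur_mse, r = mse(theta)
    if not np.isfinite(cur_mse):
        raise FloatingPointError("non-finite loss at initialization")

    for _ in range(cfg.epochs):
        J = _jacobian(theta, Xs, n_in, hidden_units)
        JtJ = J.T @ J
        Jtr = J.T @ r
        accepted = False
        for _reject in range(cfg.max_rejects):
            try:
                delta = np.linalg.solve(JtJ + lam * np.eye(n_params), Jtr)
            except np.linalg.LinAlgError:
                lam *= cfg.lam_up
                continue
            cand = resolve_output(theta - delta)
            cand_mse, cand_r = mse(cand)
            if not np.isfinite(cand_mse):
                raise FloatingPointError("non-finite loss during LM step")
            if cand_mse < cur_mse:
                theta, cur_mse, r = cand, cand_mse, cand_r
                lam /= cfg.lam_down
                accepted = True
                break
            lam *= cfg.lam_up
        if accepted:
            loss_trace.append(cur_mse * y_std**2)
        else:
            break  # epoch budget holds the best-so-far parameters

    W1, b1, W2, b2 = _unpack(theta, n_in, hidden_units)
    return MLPModel(
        n_inputs=n_in,
        hidden_units=hidden_units,
        W1=W1.copy(),
        b1=b1.copy(),
        W2=W2.copy(),
        b2=float(b2),
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        loss_trace=loss_trace,
    )
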