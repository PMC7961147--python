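"""Bayesian-regularized regression of YAP/TAZ ratio from morphology.

A small feed-forward network (14 or 15 inputs -> 4 logistic-sigmoid hidden
units -> linear output) is trained by Levenberg-Marquardt minimization of

    F = lambda_d * sum(residual^2) + lambda_w * sum(weight^2),

with the hyperparameters re-estimated each accepted step by MacKay's
evidence approximation:

    gamma    = N_w - 2 * lambda_w * tr(H^-1),      H = Gauss-Newton Hessian
    lambda_w = gamma / (2 * E_W),
    lambda_d = (n - gamma) / (2 * E_D),

where gamma is the effective number of parameters.  This regularization
replaces early stopping, so the data are split 75/25 into train/test only.
Inputs and the target are z-scored on the training split; the optional 15th
biochemical-cue input (-1 inhibitor, 0 control, +1 agonist) is passed
through unstandardized.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import FEATURE_COLUMNS


@dataclass
class TrainingRecord:
    seed: int
    objective: list[float] = field(default_factory=list)
    lambda_w: list[float] = field(default_factory=list)
    lambda_d: list[float] = field(default_factory=list)
    gamma: float = 0.0
    n_iter: int = 0
    converged: bool = False


@dataclass
class RegressionNet:
    """Weights, scalers, and training record of the YAP/TAZ predictor."""

    W1: np.ndarray  # (hidden, d)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    feature_names: list[str]
    degenerate_target: bool = False
    record: TrainingRecord | None = None

    @property
    def n_weights(self) -> int:
        return self.W1.size + self.b1.size + self.w2.size + 1

    def to_json(self, path) -> None:
        payload = {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "feature_names": self.feature_names,
            "degenerate_target": self.degenerate_target,
            "gamma": self.record.gamma if self.record else None,
            "seed": self.record.seed if self.record else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RegressionNet":
        with open(path) as fh:
            d = json.load(fh)
        rec = TrainingRecord(seed=d.get("seed") or 0, gamma=d.get("gamma") or 0.0)
        return cls(
            np.asarray(d["W1"], float),
            np.asarray(d["b1"], float),
            np.asarray(d["w2"], float),
            float(d["b2"]),
            np.asarray(d["x_mean"], float),
            np.asarray(d["x_sd"], float),
            float(d["y_mean"]),
            float(d["y_sd"]),
            list(d["feature_names"]),
            bool(d.get("degenerate_target", False)),
            rec,
        )


@dataclass
class EvalResult:
    r2: float
    errors: np.ndarray  # measured - predicted
    group_stats: pd.DataFrame | None = None
    degenerate_target: bool = False


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def split_data(n: int, train_fraction: float = 0.75, seed: int = 0):
    """Seeded shuffle split; |train| = floor(train_fraction * n)."""
    if n < 8:
        raise ValueError("need at least 8 records to split")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    idx = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(train_fraction * n))
    return np.sort(idx[:n_train]), np.sort(idx[n_train:])


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        names = feature_names or [c for c in FEATURE_COLUMNS if c in X.columns]
        missing = [c for c in names if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        return X[names].to_numpy(float), list(names)
    X = np.asarray(X, float)
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    return X, list(names)


def _nguyen_widrow(rng, hidden: int, d: int):
    W = rng.uniform(-1.0, 1.0, size=(hidden, d))
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    scale = 0.7 * hidden ** (1.0 / d)
    W *= scale
    b = scale * np.linspace(-1.0, 1.0, hidden) * np.sign(W[:, 0])
    w2 = rng.uniform(-0.5, 0.5, size=hidden)
    return W, b, w2, 0.0


def _pack(W1, b1, w2, b2):
    return np.concatenate([W1.ravel(), b1, w2, [b2]])


def _unpack(w, hidden, d):
    i = hidden * d
    return (
        w[:i].reshape(hidden, d),
        w[i : i + hidden],
        w[i + hidden : i + 2 * hidden],
        float(w[-1]),
    )


def _forward_jac(w, X, hidden):
    """Predictions and Jacobian d(pred)/d(weights) on standardized inputs."""
    n, d = X.shape
    W1, b1, w2, b2 = _unpack(w, hidden, d)
    a = _sigmoid(X @ W1.T + b1)  # (n, h)
    yhat = a @ w2 + b2
    da = a * (1.0 - a) * w2  # (n, h)
    J = np.empty((n, len(w)))
    J[:, : hidden * d] = (da[:, :, None] * X[:, None, :]).reshape(n, hidden * d)
    J[:, hidden * d : hidden * d + hidden] = da
    J[:, hidden * d + hidden : hidden * d + 2 * hidden] = a
    J[:, -1] = 1.0
    return yhat, J


def _train_core(Xs, ys, hidden, seed, max_iter, tol):
    """Levenberg-Marquardt with evidence-based hyperparameter re-estimation."""
    n, d = Xs.shape
    rng = np.random.default_rng(seed)
    W1, b1, w2, b2 = _nguyen_widrow(rng, hidden, d)
    w = _pack(W1, b1, w2, b2)
    nw = len(w)
    lam_w, lam_d = 0.01, 1.0
    mu, mu_max = 0.005, 1e10
    record = TrainingRecord(seed=seed, gamma=float(nw))
    I = np.eye(nw)

    yhat, J = _forward_jac(w, Xs, hidden)
    r = ys - yhat
    ED, EW = float(r @ r), float(w @ w)
    for it in range(max_iter):
        # Objective under the hyperparameters in force for this step; the
        # evidence update below rescales it to n/2 identically, so
        # convergence is judged on the step decrease, not across updates.
        F = lam_d * ED + lam_w * EW
        g = -2.0 * lam_d * (J.T @ r) + 2.0 * lam_w * w
        H = 2.0 * lam_d * (J.T @ J) + 2.0 * lam_w * I
        accepted = False
        while mu <= mu_max:
            try:
                dw = np.linalg.solve(H + mu * I, -g)
            except np.linalg.LinAlgError:
                dw = np.linalg.lstsq(H + mu * I, -g, rcond=None)[0]
            w_new = w + dw
            yhat_new, J_new = _forward_jac(w_new, Xs, hidden)
            r_new = ys - yhat_new
            ED_new = float(r_new @ r_new)
            F_new = lam_d * ED_new + lam_w * float(w_new @ w_new)
            if F_new < F:
                accepted = True
                mu = max(mu * 0.1, 1e-20)
                break
            mu *= 10.0
        if not accepted:
            record.converged = True
            break
        w, yhat, J, r, ED = w_new, yhat_new, J_new, r_new, ED_new
        EW = float(w @ w)
        # Evidence re-estimation of the effective parameter count and lambdas.
        try:
            Hinv = np.linalg.inv(2.0 * lam_d * (J.T @ J) + 2.0 * lam_w * I)
            gamma = nw - 2.0 * lam_w * float(np.trace(Hinv))
        except np.linalg.LinAlgError:
            gamma = record.gamma
        gamma = float(np.clip(gamma, 0.0, nw))
        if EW > 1e-12:
            lam_w = gamma / (2.0 * EW)
        if ED > 1e-12 and n > gamma:
            lam_d = (n - gamma) / (2.0 * ED)
        record.objective.append(F_new)
        record.lambda_w.append(lam_w)
        record.lambda_d.append(lam_d)
        record.gamma = gamma
        record.n_iter = it + 1
        if F - F_new < tol * max(1.0, F):
            record.converged = True
            break
    return w, record


def train_bayesian_mlp(
    X,
    y,
    hidden: int = 4,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
    feature_names: list[str] | None = None,
    _raw_columns: tuple[int, ...] = (),
) -> RegressionNet:
    """Train the morphology -> YAP/TAZ regression net with Bayesian regularization."""
    Xm, names = _as_matrix(X, feature_names)
    y = np.asarray(y, float)
    if not (np.isfinite(Xm).all() and np.isfinite(y).all()):
        raise ValueError("inputs contain non-finite values")
    if len(Xm) != len(y):
        raise ValueError("X and y length mismatch")
    n, d = Xm.shape
    nw = d * hidden + 2 * hidden + 1
    if n < nw / 2:
        warnings.warn(
            f"only {n} samples for {nw} weights; fit may be poorly determined",
            stacklevel=2,
        )

    x_mean, x_sd = Xm.mean(0), Xm.std(0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    for j in _raw_columns:  # e.g. the biochemical cue input, kept on its own scale
        x_mean[j], x_sd[j] = 0.0, 1.0
    y_mean, y_sd = float(y.mean()), float(y.std())

    if y_sd == 0:
        net = RegressionNet(
            np.zeros((hidden, d)), np.zeros(hidden), np.zeros(hidden), 0.0,
            x_mean, x_sd, y_mean, 1.0, names,
            degenerate_target=True, record=TrainingRecord(seed=seed),
        )
        return net

    Xs = (Xm - x_mean) / x_sd
    ys = (y - y_mean) / y_sd
    w, record = _train_core(Xs, ys, hidden, seed, max_iter, tol)
    W1, b1, w2, b2 = _unpack(w, hidden, d)
    return RegressionNet(W1, b1, w2, b2, x_mean, x_sd, y_mean, y_sd, names, False, record)


def predict_yap(model: RegressionNet, X) -> np.ndarray:
    """Deterministic forward pass; applies stored scalers, output unclipped."""
    Xm, _ = _as_matrix(X, model.feature_names)
    if Xm.shape[1] != len(model.x_mean):
        raise ValueError(
            f"dimension mismatch: got {Xm.shape[1]} features, model expects {len(model.x_mean)}"
        )
    Xs = (Xm - model.x_mean) / model.x_sd
    a = _sigmoid(Xs @ model.W1.T + model.b1)
    return (a @ model.w2 + model.b2) * model.y_sd + model.y_mean


def evaluate(model: RegressionNet, X, y, groups=None) -> EvalResult:
    """Pooled R^2 and signed errors (measured - predicted), optionally per group."""
    y = np.asarray(y, float)
    pred = predict_yap(model, X)
    if len(pred) != len(y):
        raise ValueError("X and y length mismatch")
    errors = y - pred
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    degenerate = ss_tot == 0
    r2 = 0.0 if degenerate else 1.0 - float(np.sum(errors**2)) / ss_tot
    stats = None
    if groups is not None:
        groups = np.asarray(groups)
        if len(groups) != len(y):
            raise ValueError("groups length mismatch")
        rows = []
        for g in pd.unique(groups):
            e = errors[groups == g]
            rows.append(
                {"group": g, "n": len(e), "mu": float(e.mean()),
                 "sigma": float(e.std(ddof=1)) if len(e) > 1 else 0.0}
            )
        stats = pd.DataFrame(rows).set_index("group")
    return EvalResult(r2, errors, stats, degenerate)


def train_with_cue(
    X,
    cue,
    y,
    hidden: int = 4,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> RegressionNet:
    """15-input variant: morphology plus a biochemical-cue column in {-1, 0, +1}."""
    if cue is None:
        raise ValueError("cue column is required (values in {-1, 0, +1})")
    cue = np.asarray(cue)
    if not np.isin(cue, (-1, 0, 1)).all():
        raise ValueError("cue values must be in {-1, 0, +1}")
    Xm, names = _as_matrix(X)
    if len(cue) != len(Xm):
        raise ValueError("cue length mismatch")
    Xc = np.column_stack([Xm, cue.astype(float)])
    return train_bayesian_mlp(
        Xc, y, hidden=hidden, seed=seed, max_iter=max_iter, tol=tol,
        feature_names=names + ["cue"], _raw_columns=(Xc.shape[1] - 1,),
    )
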