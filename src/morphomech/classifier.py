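"""Invasive vs non-invasive cell classification.

A two-class pattern-recognition network (10 logistic-sigmoid hidden units,
two-unit softmax output) trained by Moller's scaled conjugate gradient on
cross-entropy, with a seeded random 50/15/35 train/validation/test split and
early stopping on the validation loss.  Inputs are the 14 morphology
descriptors, the YAP/TAZ ratio alone, or both (15 features), mirroring the
three classification modes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import FEATURE_COLUMNS

MODES = ("morphology", "yap", "both")


@dataclass
class ClassifierNet:
    W1: np.ndarray  # (hidden, d)
    b1: np.ndarray
    W2: np.ndarray  # (2, hidden)
    b2: np.ndarray  # (2,)
    x_mean: np.ndarray
    x_sd: np.ndarray
    feature_names: list[str]
    mode: str
    seed: int
    train_idx: np.ndarray = field(default_factory=lambda: np.array([], int))
    val_idx: np.ndarray = field(default_factory=lambda: np.array([], int))
    test_idx: np.ndarray = field(default_factory=lambda: np.array([], int))
    val_curve: list[float] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "x_mean": self.x_mean.tolist(), "x_sd": self.x_sd.tolist(),
            "feature_names": self.feature_names, "mode": self.mode,
            "seed": self.seed,
            "train_idx": self.train_idx.tolist(),
            "val_idx": self.val_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ClassifierNet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.asarray(d["W1"], float), np.asarray(d["b1"], float),
            np.asarray(d["W2"], float), np.asarray(d["b2"], float),
            np.asarray(d["x_mean"], float), np.asarray(d["x_sd"], float),
            list(d["feature_names"]), d["mode"], int(d["seed"]),
            np.asarray(d["train_idx"], int), np.asarray(d["val_idx"], int),
            np.asarray(d["test_idx"], int),
        )


@dataclass
class ConfusionResult:
    matrix: pd.DataFrame  # rows true, columns predicted
    accuracy: float
    false_negative_rate: float


def split_three(n: int, fractions=(0.50, 0.15, 0.35), seed: int = 0):
    """50/15/35 split: floor for train and validation, remainder to test."""
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    idx = np.random.default_rng(seed).permutation(n)
    return (
        np.sort(idx[:n_train]),
        np.sort(idx[n_train : n_train + n_val]),
        np.sort(idx[n_train + n_val :]),
    )


def select_features(table: pd.DataFrame, mode: str):
    """Feature matrix and names for a classification mode."""
    if mode == "morphology":
        names = list(FEATURE_COLUMNS)
    elif mode == "yap":
        names = ["yap_ratio"]
    elif mode == "both":
        names = list(FEATURE_COLUMNS) + ["yap_ratio"]
    else:
        raise ValueError(f"mode must be one of {MODES}")
    missing = [c for c in names if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    return table[names].to_numpy(float), names


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _forward(w, X, hidden):
    d = X.shape[1]
    i = hidden * d
    W1 = w[:i].reshape(hidden, d)
    b1 = w[i : i + hidden]
    j = i + hidden
    W2 = w[j : j + 2 * hidden].reshape(2, hidden)
    b2 = w[j + 2 * hidden :]
    a = _sigmoid(X @ W1.T + b1)
    return _softmax(a @ W2.T + b2), a, (W1, b1, W2, b2)


def _loss_grad(w, X, T, hidden, weight_decay=1e-4):
    """Mean cross-entropy + small L2; analytic gradient."""
    n = len(X)
    P, a, (W1, b1, W2, b2) = _forward(w, X, hidden)
    loss = -np.sum(T * np.log(np.clip(P, 1e-12, None))) / n
    loss += 0.5 * weight_decay * float(w @ w)
    dz2 = (P - T) / n  # (n, 2)
    gW2 = dz2.T @ a
    gb2 = dz2.sum(0)
    da = dz2 @ W2 * a * (1 - a)
    gW1 = da.T @ X
    gb1 = da.sum(0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2]) + weight_decay * w
    return loss, grad


def _scg(w0, f_grad, val_loss, max_iter=300, max_fail=6):
    """Moller's scaled conjugate gradient with validation early stopping."""
    w = w0.copy()
    sigma0, lam, lam_bar = 5e-5, 5e-7, 0.0
    loss, grad = f_grad(w)
    r = -grad
    p = r.copy()
    success = True
    best_w, best_val, fails = w.copy(), val_loss(w), 0
    val_curve = [best_val]
    for _ in range(max_iter):
        if success:
            p_norm2 = float(p @ p)
            if p_norm2 < 1e-20:
                break
            sigma = sigma0 / np.sqrt(p_norm2)
            _, grad_plus = f_grad(w + sigma * p)
            s = (grad_plus - grad) / sigma
            delta = float(p @ s)
        delta_l = delta + (lam - lam_bar) * p_norm2
        if delta_l <= 0:
            lam_bar = 2.0 * (lam - delta_l / p_norm2)
            delta_l = -delta_l + lam * p_norm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta_l
        loss_new, _ = f_grad(w + alpha * p)
        Delta = 2.0 * delta_l * (loss - loss_new) / mu**2
        if Delta >= 0:
            w = w + alpha * p
            loss, grad = f_grad(w)
            r_new = -grad
            lam_bar = 0.0
            success = True
            v = val_loss(w)
            val_curve.append(v)
            if v < best_val - 1e-12:
                best_val, best_w, fails = v, w.copy(), 0
            else:
                fails += 1
                if fails >= max_fail:
                    break
            if Delta >= 0.75:
                lam = max(lam * 0.25, 1e-15)
            beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
            r = r_new
            p = r + beta * p
            if float(np.sqrt(grad @ grad)) < 1e-8:
                break
        else:
            lam_bar = lam
            success = False
        if Delta < 0.25:
            lam = lam + delta_l * (1.0 - Delta) / p_norm2
        if lam > 1e15:
            break
    return best_w, val_curve


def train_classifier(
    table_or_X,
    labels=None,
    mode: str = "both",
    seed: int = 0,
    hidden: int = 10,
    max_iter: int = 300,
    max_fail: int = 6,
) -> ClassifierNet:
    """Train the two-class net on a cell table (or raw feature matrix).

    With a DataFrame first argument, features are selected by ``mode`` and
    ``labels`` defaults to its ``invasive`` column.  Uses a seeded 50/15/35
    split with validation-based early stopping.
    """
    if isinstance(table_or_X, pd.DataFrame):
        X, names = select_features(table_or_X, mode)
        if labels is None:
            if "invasive" not in table_or_X.columns:
                raise ValueError("labels not given and no 'invasive' column present")
            labels = table_or_X["invasive"].to_numpy()
    else:
        X = np.asarray(table_or_X, float)
        names = [f"x{i}" for i in range(X.shape[1])]
        if labels is None:
            raise ValueError("labels are required with a raw feature matrix")
    y = np.asarray(labels).astype(bool)
    if len(X) != len(y):
        raise ValueError("features and labels length mismatch")
    if y.all() or (~y).all():
        raise ValueError("both classes must be present")

    tr, va, te = split_three(len(X), seed=seed)
    if len(np.unique(y[tr])) < 2:
        raise ValueError("training split contains a single class; reseed or rebalance")

    x_mean, x_sd = X[tr].mean(0), X[tr].std(0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    Z = (X - x_mean) / x_sd
    T = np.column_stack([~y, y]).astype(float)  # column 1 = invasive

    rng = np.random.default_rng(seed)
    d = X.shape[1]
    w0 = rng.uniform(-0.5, 0.5, size=hidden * d + hidden + 2 * hidden + 2)

    def f_grad(w):
        return _loss_grad(w, Z[tr], T[tr], hidden)

    def val_loss(w):
        if len(va) == 0:
            return _loss_grad(w, Z[tr], T[tr], hidden)[0]
        return _loss_grad(w, Z[va], T[va], hidden)[0]

    w, val_curve = _scg(w0, f_grad, val_loss, max_iter=max_iter, max_fail=max_fail)
    _, _, (W1, b1, W2, b2) = _forward(w, Z[:1], hidden)
    return ClassifierNet(
        W1, b1, W2, b2, x_mean, x_sd, names, mode if isinstance(table_or_X, pd.DataFrame) else "raw",
        seed, tr, va, te, val_curve,
    )


def predict_scores(model: ClassifierNet, X) -> np.ndarray:
    """Normalized class scores (columns: non-invasive, invasive; rows sum to 1)."""
    if isinstance(X, pd.DataFrame):
        X = X[model.feature_names].to_numpy(float)
    X = np.asarray(X, float)
    if X.shape[1] != len(model.x_mean):
        raise ValueError("feature dimension mismatch")
    Z = (X - model.x_mean) / model.x_sd
    a = _sigmoid(Z @ model.W1.T + model.b1)
    return _softmax(a @ model.W2.T + model.b2)


def predict_classes(model: ClassifierNet, X) -> np.ndarray:
    return predict_scores(model, X)[:, 1] >= 0.5


def confusion(model: ClassifierNet, X_test, labels_test) -> ConfusionResult:
    """2x2 confusion matrix, accuracy, and false-negative rate.

    The invasive class is positive; the false-negative rate is the fraction
    of truly invasive cells called non-invasive, FN / (FN + TP).
    """
    y = np.asarray(labels_test).astype(bool)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = predict_classes(model, X_test)
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    matrix = pd.DataFrame(
        [[tn, fp], [fn, tp]],
        index=pd.Index(["non-invasive", "invasive"], name="true"),
        columns=pd.Index(["non-invasive", "invasive"], name="predicted"),
    )
    accuracy = (tp + tn) / len(y)
    fnr = fn / (fn + tp) if (fn + tp) > 0 else 0.0
    return ConfusionResult(matrix, float(accuracy), float(fnr))
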