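"""Self-organizing map over standardized morphology descriptors.

A small (2x2 by default) grid of prototype vectors is trained by batch
competitive learning on z-scored descriptors: each epoch every cell is
assigned to its best-matching unit and prototypes move to the
neighborhood-weighted mean of their cells, with a Gaussian neighborhood
whose radius decays to zero (after which updates are k-means-like).
Cluster ids are 1-based unit indices in row-major grid order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import FEATURE_COLUMNS


@dataclass
class SOMModel:
    grid_shape: tuple[int, int]
    prototypes: np.ndarray  # (units, n_features), standardized space
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    config: dict = field(default_factory=dict)
    qe_history: list[float] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def standardize(self, features: pd.DataFrame) -> np.ndarray:
        X = _feature_matrix(features, self.feature_names)
        return (X - self.scaler_mean) / self.scaler_sd

    def to_json(self, path) -> None:
        payload = {
            "grid_shape": list(self.grid_shape),
            "prototypes": self.prototypes.tolist(),
            "feature_names": self.feature_names,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "config": self.config,
            "qe_history": self.qe_history,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SOMModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tuple(d["grid_shape"]),
            np.asarray(d["prototypes"], float),
            list(d["feature_names"]),
            np.asarray(d["scaler_mean"], float),
            np.asarray(d["scaler_sd"], float),
            d.get("config", {}),
            list(d.get("qe_history", [])),
        )


def _feature_matrix(features: pd.DataFrame, names: list[str]) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in names if c not in features.columns]
        if missing:
            raise ValueError(f"missing descriptor columns: {missing}")
        X = features[names].to_numpy(float)
    else:
        X = np.asarray(features, float)
        if X.shape[1] != len(names):
            raise ValueError(
                f"descriptor count mismatch: got {X.shape[1]}, model expects {len(names)}"
            )
    return X


def _bmu(X: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - prototypes[None, :, :]) ** 2).sum(-1)
    return d2.argmin(1)  # argmin takes the lowest index on ties


def train_som(
    features: pd.DataFrame,
    grid: tuple[int, int] = (2, 2),
    epochs: int = 30,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> SOMModel:
    """Train a SOM on the 14 descriptors (or ``feature_names``) of a table."""
    names = feature_names or FEATURE_COLUMNS
    if isinstance(features, pd.DataFrame):
        na_cols = [c for c in names if c in features.columns and features[c].isna().any()]
        if na_cols:
            raise ValueError(f"missing values in columns: {na_cols}")
    X = _feature_matrix(features, names)
    if not np.isfinite(X).all():
        raise ValueError("descriptors contain non-finite values")
    units = grid[0] * grid[1]
    if len(X) < units:
        raise ValueError(f"need at least {units} samples for a {grid} grid")

    mean = X.mean(0)
    sd = X.std(0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd

    rng = np.random.default_rng(seed)
    prototypes = Z[rng.choice(len(Z), size=units, replace=False)].copy()
    unit_pos = np.array([(r, c) for r in range(grid[0]) for c in range(grid[1])], float)
    grid_d2 = ((unit_pos[:, None, :] - unit_pos[None, :, :]) ** 2).sum(-1)

    # Neighborhood radius: 1 -> 0 over the first half of training, then pure
    # nearest-unit (k-means-like) refinement.
    t_order = max(epochs // 2, 1)
    qe_history = []
    for t in range(epochs):
        bmu = _bmu(Z, prototypes)
        radius = 1.0 * (1.0 - t / t_order) if t < t_order else 0.0
        if radius > 1e-6:
            H = np.exp(-grid_d2 / (2.0 * radius**2))
        else:
            H = np.eye(units)
        W = H[bmu]  # (n, units): weight of each sample on each unit
        denom = W.sum(0)
        new = prototypes.copy()
        nonempty = denom > 0
        new[nonempty] = (W.T @ Z)[nonempty] / denom[nonempty, None]
        prototypes = new
        # RMS quantization error: the k-means-type energy the batch update
        # minimizes once the neighborhood has shrunk to the unit itself.
        d2 = ((Z[:, None, :] - prototypes[None, :, :]) ** 2).sum(-1)
        qe_history.append(float(np.sqrt(d2.min(1).mean())))

    return SOMModel(
        grid_shape=tuple(grid),
        prototypes=prototypes,
        feature_names=list(names),
        scaler_mean=mean,
        scaler_sd=sd,
        config={"epochs": epochs, "seed": seed, "radius_schedule": "linear 1->0 over half"},
        qe_history=qe_history,
    )


def assign_clusters(model: SOMModel, features) -> np.ndarray:
    """Map each cell to its nearest prototype; returns 1-based unit ids."""
    Z = model.standardize(features)
    return _bmu(Z, model.prototypes) + 1


def characterize_clusters(
    assignments: np.ndarray,
    features: pd.DataFrame,
    yap=None,
    marker=None,
    n_units: int | None = None,
) -> pd.DataFrame:
    """Per-cluster summary: n, descriptor mean/SD, mean YAP, marker fraction.

    Empty clusters report n=0 with NaN statistics.  The marker column is
    formatted as "positive/total" alongside the numeric fraction.
    """
    assignments = np.asarray(assignments)
    if len(assignments) != len(features):
        raise ValueError("assignments and features length mismatch")
    if yap is not None and len(np.asarray(yap)) != len(assignments):
        raise ValueError("yap length mismatch")
    if marker is not None and len(np.asarray(marker)) != len(assignments):
        raise ValueError("marker length mismatch")
    n_units = n_units or int(assignments.max())
    names = [c for c in FEATURE_COLUMNS if c in features.columns]
    rows = []
    for unit in range(1, n_units + 1):
        sel = assignments == unit
        row: dict = {"cluster": unit, "n": int(sel.sum())}
        for c in names:
            vals = features.loc[sel, c]
            row[f"{c}_mean"] = float(vals.mean()) if sel.any() else np.nan
            row[f"{c}_sd"] = float(vals.std()) if sel.sum() > 1 else np.nan
        if yap is not None:
            y = np.asarray(yap, float)[sel]
            row["yap_mean"] = float(y.mean()) if sel.any() else np.nan
        if marker is not None:
            m = np.asarray(marker, bool)[sel]
            row["marker_positive"] = f"{int(m.sum())}/{int(sel.sum())}"
            row["marker_fraction"] = float(m.mean()) if sel.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")
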