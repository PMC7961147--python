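"""Prediction-error statistics and mechanosensing-decoupling detection.

The signed prediction error (measured - predicted YAP/TAZ ratio) indexes how
far a cell departs from the morphology-mechanosensing rule set: group mean
mu far from zero marks a systematically decoupled population, and single
cells are flagged when |error| exceeds a z threshold times the reference
error SD of the training set.  Group comparisons use the Kruskal-Wallis
omnibus test (unequal variances) with Dunn's rank-based post-hoc z tests and
Bonferroni adjustment; training targets can be screened with a two-sided
Grubbs outlier test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GrubbsResult:
    kept: np.ndarray
    removed: np.ndarray
    g_statistics: list[float]
    critical_values: list[float]


@dataclass
class GroupComparison:
    h_statistic: float
    p_value: float
    posthoc: pd.DataFrame  # columns: group1, group2, z, p_adjusted


@dataclass
class GroupErrorStats:
    group: str
    n: int
    mu: float
    sigma: float
    flag_fraction: float = math.nan


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_filter(
    values, alpha: float = 0.05, iterative: bool = False
) -> GrubbsResult:
    """Two-sided Grubbs test: G = max|x - mean| / sd vs the t-based critical value.

    Non-iterative (the default) tests only the single most extreme point;
    ``iterative`` repeats until no rejection.  Constant samples (sd = 0) are
    returned untouched.
    """
    x = np.asarray(values, float).copy()
    if len(x) < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    removed: list[float] = []
    gs: list[float] = []
    crits: list[float] = []
    while len(x) >= 3:
        s = x.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(x - x.mean())
        i = int(dev.argmax())
        g = dev[i] / s
        crit = grubbs_critical(len(x), alpha)
        gs.append(float(g))
        crits.append(float(crit))
        if g > crit:
            removed.append(float(x[i]))
            x = np.delete(x, i)
            if not iterative:
                break
        else:
            break
    return GrubbsResult(x, np.asarray(removed), gs, crits)


def compare_group_errors(errors, groups, p_adjust: str = "bonferroni") -> GroupComparison:
    """Kruskal-Wallis omnibus H (tie-corrected) plus Dunn's pairwise post-hoc.

    Dunn's z for groups i, j uses mean ranks over the pooled sample with the
    tie correction sum(t^3 - t) / (12 (N - 1)); p values are two-sided and
    Bonferroni-adjusted over all pairs.  If every value is identical the
    omnibus is reported as H = 0, p = 1.
    """
    errors = np.asarray(errors, float)
    groups = np.asarray(groups)
    if len(errors) != len(groups):
        raise ValueError("errors and groups length mismatch")
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [errors[groups == g] for g in labels]
    small = [str(g) for g, s in zip(labels, samples) if len(s) < 2]
    if small:
        raise ValueError(f"groups with n < 2: {small}")

    if np.all(errors == errors[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)

    ranks = stats.rankdata(errors)
    N = len(errors)
    _, counts = np.unique(errors, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    n_pairs = len(labels) * (len(labels) - 1) // 2
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            ri = ranks[groups == labels[i]].mean()
            rj = ranks[groups == labels[j]].mean()
            ni, nj = len(samples[i]), len(samples[j])
            se = math.sqrt(var_base * (1.0 / ni + 1.0 / nj))
            z = (ri - rj) / se if se > 0 else 0.0
            p_raw = 2.0 * stats.norm.sf(abs(z))
            if p_adjust == "bonferroni":
                p_adj = min(p_raw * n_pairs, 1.0)
            elif p_adjust in (None, "none"):
                p_adj = p_raw
            else:
                raise ValueError(f"unknown p_adjust: {p_adjust}")
            rows.append(
                {"group1": labels[i], "group2": labels[j], "z": z, "p_adjusted": p_adj}
            )
    return GroupComparison(float(h), float(p), pd.DataFrame(rows))


def flag_decoupled(
    errors,
    reference_sigma: float,
    z_threshold: float = 2.0,
    groups=None,
):
    """Per-cell decoupling flags: |error| > z_threshold * reference_sigma.

    ``reference_sigma`` is the SD of the training-set prediction errors.
    Returns (flags, per-group fraction DataFrame or overall fraction).
    """
    if reference_sigma <= 0:
        raise ValueError("reference_sigma must be > 0")
    if z_threshold <= 0:
        raise ValueError("z_threshold must be > 0")
    errors = np.asarray(errors, float)
    flags = np.abs(errors) > z_threshold * reference_sigma
    if groups is None:
        return flags, float(flags.mean())
    groups = np.asarray(groups)
    if len(groups) != len(errors):
        raise ValueError("groups length mismatch")
    rows = [
        {"group": g, "n": int((groups == g).sum()),
         "flag_fraction": float(flags[groups == g].mean())}
        for g in pd.unique(groups)
    ]
    return flags, pd.DataFrame(rows).set_index("group")


def group_error_stats(
    errors, groups, reference_sigma: float | None = None, z_threshold: float = 2.0
) -> pd.DataFrame:
    """Per-group n, mu, sigma (and flag fraction if a reference SD is given)."""
    errors = np.asarray(errors, float)
    groups = np.asarray(groups)
    if len(errors) != len(groups):
        raise ValueError("errors and groups length mismatch")
    flags = (
        np.abs(errors) > z_threshold * reference_sigma
        if reference_sigma is not None
        else None
    )
    rows = []
    for g in pd.unique(groups):
        sel = groups == g
        e = errors[sel]
        row = {
            "group": g,
            "n": int(sel.sum()),
            "mu": float(e.mean()),
            "sigma": float(e.std(ddof=1)) if sel.sum() > 1 else 0.0,
        }
        if flags is not None:
            row["flag_fraction"] = float(flags[sel].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
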