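"""Regression metrics, per-protein breakdowns, residual correlation,
feature-importance rankings and error-vs-label profiles.

Metrics follow the usual affinity-model triple: mean squared error, Pearson
correlation and Kendall's tau (tau-b, tie-corrected). Per-group summaries
are unweighted across groups (each protein counts once regardless of its
record count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MetricsReport:
    mse: float
    pearson_r: float
    kendall_tau: float
    n: int

    def as_dict(self) -> dict:
        return {
            "mse": self.mse,
            "pearson_r": self.pearson_r,
            "kendall_tau": self.kendall_tau,
            "n": self.n,
        }


def regression_metrics(y_true, y_pred) -> MetricsReport:
    """MSE, Pearson r and Kendall tau-b. Correlations are NaN (flagged
    undefined) for zero-variance inputs; the MSE is still computed."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    mse = float(np.mean((y_true - y_pred) ** 2))
    if y_true.std() == 0 or y_pred.std() == 0:
        return MetricsReport(mse=mse, pearson_r=float("nan"), kendall_tau=float("nan"),
                             n=y_true.size)
    r = float(stats.pearsonr(y_true, y_pred).statistic)
    tau = float(stats.kendalltau(y_true, y_pred).statistic)  # tau-b
    return MetricsReport(mse=mse, pearson_r=r, kendall_tau=tau, n=y_true.size)


def per_group_metrics(
    y_true, y_pred, groups, min_n: int = 100
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metrics per group with more than ``min_n`` instances, plus the
    unweighted mean +/- SD (sample SD) across qualifying groups."""
    df = pd.DataFrame(
        {"y": np.asarray(y_true, dtype=np.float64),
         "p": np.asarray(y_pred, dtype=np.float64),
         "g": list(groups)}
    )
    rows = []
    for g, sub in df.groupby("g", sort=True):
        if len(sub) <= min_n:
            continue
        m = regression_metrics(sub["y"].to_numpy(), sub["p"].to_numpy())
        rows.append({"group": g, **m.as_dict()})
    table = pd.DataFrame(rows, columns=["group", "mse", "pearson_r", "kendall_tau", "n"])
    if table.empty:
        return table, pd.DataFrame(columns=["metric", "mean", "sd"])
    summary = pd.DataFrame(
        {
            "metric": ["mse", "pearson_r", "kendall_tau"],
            "mean": [table[c].mean() for c in ("mse", "pearson_r", "kendall_tau")],
            "sd": [table[c].std(ddof=1) if len(table) > 1 else 0.0
                   for c in ("mse", "pearson_r", "kendall_tau")],
        }
    )
    return table, summary


def residual_correlation(y_true, pred_a, pred_b) -> float:
    """R^2 between the residual vectors of two models (how redundant an
    ensemble of the two would be)."""
    y = np.asarray(y_true, dtype=np.float64)
    ra = y - np.asarray(pred_a, dtype=np.float64)
    rb = y - np.asarray(pred_b, dtype=np.float64)
    if ra.shape != rb.shape:
        raise ValueError("length mismatch")
    if ra.std() == 0 or rb.std() == 0:
        return float("nan")
    return float(stats.pearsonr(ra, rb).statistic ** 2)


def rf_impurity_importance(model, block_labels=None) -> pd.DataFrame:
    """Impurity (Gini) importances of a fitted RF, ranked descending, with
    the feature's block label attached when available."""
    imp = model.feature_importances()
    table = pd.DataFrame(
        {
            "feature": np.arange(imp.size),
            "importance": imp,
            "block": block_labels if block_labels is not None else [""] * imp.size,
        }
    )
    table = table.sort_values("importance", ascending=False, kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)


def permutation_importance(
    model, matrix, y, n_repeats: int = 5, seed: int = 0, block_labels=None
) -> pd.DataFrame:
    """Model-agnostic importance: mean increase in MSE when a column is
    permuted within itself (seeded), ranked descending. Works for any model
    exposing ``predict`` (RF or FFN)."""
    X = matrix.values if hasattr(matrix, "values") else np.asarray(matrix)
    y = np.asarray(y, dtype=np.float64)
    rng = np.random.default_rng(seed)
    base_mse = np.mean((model.predict(X) - y) ** 2)
    means = np.empty(X.shape[1])
    sds = np.empty(X.shape[1])
    work = X.copy()
    for j in range(X.shape[1]):
        saved = work[:, j].copy()
        deltas = []
        for _ in range(n_repeats):
            work[:, j] = saved[rng.permutation(len(saved))]
            deltas.append(np.mean((model.predict(work) - y) ** 2) - base_mse)
        work[:, j] = saved
        means[j] = np.mean(deltas)
        sds[j] = np.std(deltas)
    table = pd.DataFrame(
        {
            "feature": np.arange(X.shape[1]),
            "importance": means,  # MSE increase
            "importance_sd": sds,
            "block": block_labels if block_labels is not None else [""] * X.shape[1],
        }
    )
    table = table.sort_values("importance", ascending=False, kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)


def error_vs_label_profile(y_true, y_pred, n_bins: int = 10) -> pd.DataFrame:
    """Mean squared error per true-label quantile bin (the error-vs-pIC50
    curve data)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y = np.asarray(y_true, dtype=np.float64)
    p = np.asarray(y_pred, dtype=np.float64)
    sq = (y - p) ** 2
    edges = np.quantile(y, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": int(sel.sum()),
                "mse": float(sq[sel].mean()) if sel.any() else float("nan"),
            }
        )
    return pd.DataFrame(rows)
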