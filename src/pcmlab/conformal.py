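"""Inductive (split) conformal regression with spread-normalized
nonconformity.

Nonconformity of an example is alpha = |y - y_hat| / lambda, where the
per-instance scaler lambda is the model's uncertainty estimate (RF per-tree
SD or MC-dropout SD) plus a small smoothing constant beta (additive mode),
or exp(spread) (exponential mode). The calibration-set scores are sorted
and, for a confidence level 1 - epsilon, the interval half-width multiplier
is the k-th smallest score with the finite-sample correction
k = ceil((1 - epsilon) * (n_cal + 1)); if k exceeds n_cal the interval is
unbounded. Under exchangeability the resulting intervals contain the true
value with probability >= 1 - epsilon (marginal validity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_BETA = 0.01


def _lambda(spread, beta: float, scaler: str) -> np.ndarray:
    spread = np.asarray(spread, dtype=np.float64)
    if np.any(spread < 0):
        raise ValueError("spread must be nonnegative")
    if scaler == "additive":
        if beta <= 0:
            raise ValueError("beta must be > 0")
        return spread + beta
    if scaler == "exponential":
        return np.exp(spread)
    raise ValueError(f"unknown scaler {scaler!r}")


def nonconformity(y, y_hat, spread, beta: float = DEFAULT_BETA, scaler: str = "additive"):
    """alpha = |y - y_hat| / lambda(spread)."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    return np.abs(y - y_hat) / _lambda(spread, beta, scaler)


@dataclass
class ConformalCalibrator:
    """Sorted calibration nonconformity scores plus the spread-scaler
    settings used to produce them."""

    alphas: np.ndarray
    beta: float = DEFAULT_BETA
    scaler: str = "additive"

    def __post_init__(self):
        self.alphas = np.sort(np.asarray(self.alphas, dtype=np.float64))
        if self.alphas.size == 0:
            raise ValueError("empty calibration set")
        if np.any(self.alphas < 0):
            raise ValueError("nonconformity scores must be nonnegative")

    @property
    def n_cal(self) -> int:
        return int(self.alphas.size)


def fit_calibrator(
    y_cal,
    y_hat_cal,
    spread_cal,
    beta: float = DEFAULT_BETA,
    scaler: str = "additive",
) -> ConformalCalibrator:
    alphas = nonconformity(y_cal, y_hat_cal, spread_cal, beta=beta, scaler=scaler)
    return ConformalCalibrator(alphas=alphas, beta=beta, scaler=scaler)


def calibrate(alphas, epsilon: float) -> float:
    """Interval half-width multiplier alpha* at confidence 1 - epsilon:
    the k-th smallest calibration score, k = ceil((1-eps)(n+1)); +inf when
    k > n (interval unbounded)."""
    alphas = np.sort(np.asarray(alphas, dtype=np.float64))
    n = alphas.size
    if n == 0:
        raise ValueError("empty calibration set")
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    # small tolerance so exact rank boundaries (e.g. 0.95 * 20 = 19) are not
    # pushed to the next rank by floating-point round-up
    k = int(np.ceil((1.0 - epsilon) * (n + 1) - 1e-9))
    if k > n:
        return float("inf")
    return float(alphas[k - 1])


@dataclass
class PredictionIntervals:
    lower: np.ndarray
    upper: np.ndarray
    confidence: float

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=np.float64)
        self.upper = np.asarray(self.upper, dtype=np.float64)
        if np.any(self.lower > self.upper):
            raise ValueError("lower must be <= upper")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def predict_interval(
    y_hat, spread, calibrator: ConformalCalibrator, epsilon: float
) -> PredictionIntervals:
    """Symmetric interval y_hat +/- alpha* x lambda(spread)."""
    y_hat = np.asarray(y_hat, dtype=np.float64)
    lam = _lambda(spread, calibrator.beta, calibrator.scaler)
    alpha_star = calibrate(calibrator.alphas, epsilon)
    half = alpha_star * lam
    return PredictionIntervals(
        lower=y_hat - half, upper=y_hat + half, confidence=1.0 - epsilon
    )


def validity(intervals: PredictionIntervals, y_true) -> float:
    """Fraction of instances whose interval contains the true value."""
    y = np.asarray(y_true, dtype=np.float64)
    if y.shape != intervals.lower.shape:
        raise ValueError("length mismatch between intervals and labels")
    return float(np.mean((intervals.lower <= y) & (y <= intervals.upper)))


def efficiency(intervals: PredictionIntervals) -> dict:
    """Interval-width summary (the box-plot statistics): median and
    quartiles over bounded intervals; unbounded ones are excluded and
    counted."""
    w = intervals.width
    bounded = np.isfinite(w)
    n_unbounded = int((~bounded).sum())
    w = w[bounded]
    if w.size == 0:
        raise ValueError("no bounded intervals to summarize")
    q1, med, q3 = np.percentile(w, [25, 50, 75])
    return {
        "widths": w,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "n_unbounded": n_unbounded,
    }


def calibration_curve(
    calibrator: ConformalCalibrator,
    y_hat,
    spread,
    y_true,
    epsilon_grid,
) -> pd.DataFrame:
    """Observed error rate (1 - validity) at each requested error level:
    the data behind a theoretical-vs-computed error-rate plot."""
    rows = []
    for eps in epsilon_grid:
        iv = predict_interval(y_hat, spread, calibrator, eps)
        rows.append(
            {"epsilon": float(eps), "observed_error": 1.0 - validity(iv, y_true)}
        )
    return pd.DataFrame(rows)
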