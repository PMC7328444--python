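"""Shared prediction containers and ensembling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class UncertaintyPrediction:
    """Per-instance predicted mean and spread (population SD across RF trees
    or MC-dropout forward passes), on the scaled-pIC50 scale."""

    mean: np.ndarray
    spread: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.spread = np.asarray(self.spread, dtype=np.float64)
        if self.mean.shape != self.spread.shape:
            raise ValueError("mean and spread must have equal length")
        if np.any(self.spread < 0):
            raise ValueError("spread must be nonnegative")


def ensemble_average(pred_a: np.ndarray, pred_b: np.ndarray) -> np.ndarray:
    """Elementwise mean of two mean-prediction vectors."""
    a = np.asarray(pred_a, dtype=np.float64)
    b = np.asarray(pred_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return (a + b) / 2.0
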