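"""Random-forest proteochemometric model with per-tree spread.

Thin wrapper over scikit-learn's RandomForestRegressor exposing per-tree
predictions (the spread is the population standard deviation across trees,
the per-instance similarity gauge used for conformal prediction), impurity
importances, grid search over the usual hyperparameter grid, and a schema
fingerprint so predict-time feature mismatches fail fast.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from ..featurization import FeatureMatrix
from .common import UncertaintyPrediction


@dataclass
class RFConfig:
    n_estimators: int = 1000
    max_features: str | float = "sqrt"
    min_samples_leaf: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")


#: default hyperparameter grid: 3 x 4 x 5 = 60 combinations
DEFAULT_RF_GRID = {
    "n_estimators": [100, 500, 1000],
    "max_features": ["sqrt", "log2", 0.3, 0.5],
    "min_samples_leaf": [1, 3, 5, 10, 25],
}


def _as_array(matrix) -> np.ndarray:
    return matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)


class RandomForestModel:
    def __init__(self, config: RFConfig):
        self.config = config
        self.estimator = RandomForestRegressor(
            n_estimators=config.n_estimators,
            max_features=config.max_features,
            min_samples_leaf=config.min_samples_leaf,
            random_state=config.seed,
            n_jobs=1,
        )
        self.schema: str | None = None
        self.n_features_: int | None = None

    def fit(self, matrix, labels) -> "RandomForestModel":
        X = _as_array(matrix)
        y = np.asarray(labels, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
            raise ValueError("degenerate training matrix")
        if X.shape[0] != y.shape[0] or y.shape[0] < 2:
            raise ValueError("need >= 2 rows with matching labels")
        self.estimator.fit(X, y)
        self.n_features_ = X.shape[1]
        if isinstance(matrix, FeatureMatrix):
            self.schema = matrix.schema_fingerprint()
        return self

    def _check_schema(self, matrix):
        X = _as_array(matrix)
        if self.n_features_ is None:
            raise ValueError("model is not fitted")
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"feature-count mismatch: model has {self.n_features_}, got {X.shape[1]}"
            )
        if (
            self.schema is not None
            and isinstance(matrix, FeatureMatrix)
            and matrix.schema_fingerprint() != self.schema
        ):
            raise ValueError("block schema mismatch between training and prediction matrix")
        return X

    def predict(self, matrix) -> np.ndarray:
        return self.estimator.predict(self._check_schema(matrix))

    def tree_predictions(self, matrix) -> np.ndarray:
        """(n_trees, n_rows) matrix of individual tree predictions."""
        X = self._check_schema(matrix)
        return np.stack([tree.predict(X) for tree in self.estimator.estimators_])

    def feature_importances(self) -> np.ndarray:
        if self.n_features_ is None:
            raise ValueError("model is not fitted")
        return self.estimator.feature_importances_

    def save(self, path):
        joblib.dump({"config": self.config, "model": self}, path)

    @staticmethod
    def load(path) -> "RandomForestModel":
        return joblib.load(path)["model"]


def train_rf(matrix, labels, config: RFConfig | None = None) -> RandomForestModel:
    return RandomForestModel(config or RFConfig()).fit(matrix, labels)


def rf_predict_uncertainty(model: RandomForestModel, matrix) -> UncertaintyPrediction:
    """Mean and population SD across the individual trees."""
    per_tree = model.tree_predictions(matrix)
    return UncertaintyPrediction(mean=per_tree.mean(axis=0), spread=per_tree.std(axis=0))


def grid_search_rf(
    train_matrix,
    train_labels,
    valid_matrix,
    valid_labels,
    grid: dict | None = None,
    seed: int = 0,
) -> tuple[RFConfig, pd.DataFrame]:
    """Exhaustive grid search scored by validation MSE. Returns the argmin
    config and the full results table."""
    grid = dict(DEFAULT_RF_GRID if grid is None else grid)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    y_val = np.asarray(valid_labels, dtype=np.float64)
    rows = []
    keys = list(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        config = RFConfig(seed=seed, **params)
        model = train_rf(train_matrix, train_labels, config)
        mse = float(np.mean((model.predict(valid_matrix) - y_val) ** 2))
        rows.append({**params, "valid_mse": mse})
    table = pd.DataFrame(rows)
    best = table.iloc[int(table["valid_mse"].idxmin())]
    best_config = RFConfig(seed=seed, **{k: best[k] for k in keys})
    return best_config, table
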