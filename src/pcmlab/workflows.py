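"""End-to-end protocols assembled from the pipeline stages.

These are the study designs the package is built around: generate (or load)
an activity table, curate it, featurize pairs, split without leakage, train
a model, calibrate a conformal predictor and measure validity/efficiency.
Each function takes a seed and is fully deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import conformal, synthetic
from .curation import CurationRules, LabelScaler, curate_table
from .featurization import DescriptorCache, FeatureMatrix, assemble_matrix
from .models import RFConfig, rf_predict_uncertainty, train_rf
from .splits import random_split, scaffold_split


@dataclass
class PCMDataset:
    """Curated pair-level dataset: one row per (molecule, protein) pair."""

    smiles: list
    protein_ids: list
    pic50: np.ndarray
    sequences: dict
    truth: synthetic.GroundTruth


def make_dataset(config: synthetic.SyntheticConfig) -> PCMDataset:
    """Generate, curate and collect the pair-level labelled dataset."""
    proteins, _, table, truth = synthetic.generate_dataset(config)
    pairs, _ = curate_table(table, CurationRules())
    return PCMDataset(
        smiles=pairs["canonical_smiles"].tolist(),
        protein_ids=pairs["uniprot_id"].tolist(),
        pic50=pairs["pic50"].to_numpy(),
        sequences=proteins,
        truth=truth,
    )


def _assemble_subsets(ds: PCMDataset, index_sets, n_bits: int):
    """Feature matrices for several row-index subsets sharing one descriptor
    cache; the scaler is fitted on the first subset (training) only."""
    cache = DescriptorCache(n_bits)
    pairs = list(zip(ds.smiles, ds.protein_ids))
    out = []
    scaler = None
    for idx in index_sets:
        sub = [pairs[i] for i in idx]
        mat = assemble_matrix(sub, ds.sequences, n_bits=n_bits, scaler=scaler, cache=cache)
        if scaler is None:
            scaler = (mat.scaler_mean, mat.scaler_scale)
        out.append(mat)
    return out


@dataclass
class CoverageRun:
    coverage: float
    median_width: float
    valid_mse: float
    n_train: int
    n_cal: int
    n_test: int


def conformal_coverage_run(
    seed: int,
    config: synthetic.SyntheticConfig | None = None,
    n_cal: int = 90,
    n_test: int = 1000,
    epsilon: float = 0.05,
    rf_config: RFConfig | None = None,
    n_bits: int = 4096,
) -> CoverageRun:
    """One seed of the conformal-validity protocol: train an RF on synthetic
    data, calibrate additive-lambda nonconformity on ``n_cal`` held-out
    points, and measure empirical coverage of the (1 - epsilon) intervals on
    ``n_test`` exchangeable test points."""
    config = replace(config or synthetic.SyntheticConfig(), seed=seed)
    ds = make_dataset(config)
    n = len(ds.pic50)
    if n < n_cal + n_test + 10:
        raise ValueError(f"dataset too small ({n}) for n_cal={n_cal}, n_test={n_test}")
    rng = np.random.default_rng([seed, 101])
    order = rng.permutation(n)
    test_idx = order[:n_test]
    cal_idx = order[n_test : n_test + n_cal]
    train_idx = order[n_test + n_cal :]

    scaler = LabelScaler.fit(ds.pic50[train_idx])
    y_train = scaler.transform(ds.pic50[train_idx])
    y_cal = scaler.transform(ds.pic50[cal_idx])
    y_test = scaler.transform(ds.pic50[test_idx])

    X_train, X_cal, X_test = _assemble_subsets(ds, [train_idx, cal_idx, test_idx], n_bits)

    model = train_rf(X_train, y_train, rf_config or RFConfig(seed=seed))
    pred_cal = rf_predict_uncertainty(model, X_cal)
    pred_test = rf_predict_uncertainty(model, X_test)

    calib = conformal.fit_calibrator(y_cal, pred_cal.mean, pred_cal.spread)
    intervals = conformal.predict_interval(pred_test.mean, pred_test.spread, calib, epsilon)
    eff = conformal.efficiency(intervals)
    return CoverageRun(
        coverage=conformal.validity(intervals, y_test),
        median_width=eff["median"],
        valid_mse=float(np.mean((pred_test.mean - y_test) ** 2)),
        n_train=len(train_idx),
        n_cal=n_cal,
        n_test=n_test,
    )


def mean_conformal_coverage(
    seeds,
    config: synthetic.SyntheticConfig | None = None,
    **kwargs,
) -> tuple[float, list[CoverageRun]]:
    runs = [conformal_coverage_run(s, config=config, **kwargs) for s in seeds]
    return float(np.mean([r.coverage for r in runs])), runs


@dataclass
class SplitComparison:
    scaffold_mse: float
    random_mse: float


def split_difficulty_run(
    seed: int,
    config: synthetic.SyntheticConfig | None = None,
    rf_config: RFConfig | None = None,
    fraction: float = 0.8,
    n_bits: int = 4096,
) -> SplitComparison:
    """Validation MSE of the same RF under a generic-scaffold split vs a
    random split of the same data (the scaffold split is the harder one)."""
    config = replace(config or synthetic.SyntheticConfig(), seed=seed)
    ds = make_dataset(config)
    ids = list(range(len(ds.pic50)))
    rf_config = rf_config or RFConfig(n_estimators=200, seed=seed)

    out = {}
    for name, split in (
        ("scaffold", scaffold_split(ids, ds.smiles, fraction=fraction, seed=seed)),
        ("random", random_split(ids, fraction=fraction, seed=seed)),
    ):
        tr, va = list(split.train_ids), list(split.valid_ids)
        scaler = LabelScaler.fit(ds.pic50[tr])
        X_tr, X_va = _assemble_subsets(ds, [tr, va], n_bits)
        model = train_rf(X_tr, scaler.transform(ds.pic50[tr]), rf_config)
        pred = model.predict(X_va)
        out[name] = float(np.mean((pred - scaler.transform(ds.pic50[va])) ** 2))
    return SplitComparison(scaffold_mse=out["scaffold"], random_mse=out["random"])


def rf_recovery_run(
    seed: int,
    config: synthetic.SyntheticConfig | None = None,
    rf_config: RFConfig | None = None,
    fraction: float = 0.8,
    n_bits: int = 4096,
) -> float:
    """Validation Pearson r of the RF on a random split: how much of the
    generator's latent signal the model recovers."""
    from scipy import stats

    config = replace(config or synthetic.SyntheticConfig(), seed=seed)
    ds = make_dataset(config)
    ids = list(range(len(ds.pic50)))
    split = random_split(ids, fraction=fraction, seed=seed)
    tr, va = list(split.train_ids), list(split.valid_ids)
    scaler = LabelScaler.fit(ds.pic50[tr])
    X_tr, X_va = _assemble_subsets(ds, [tr, va], n_bits)
    model = train_rf(X_tr, scaler.transform(ds.pic50[tr]), rf_config or RFConfig(seed=seed))
    pred = model.predict(X_va)
    return float(stats.pearsonr(pred, scaler.transform(ds.pic50[va])).statistic)


#: config sized so the curated table has ~5000 pairs (for recovery runs)
LARGE_CONFIG = synthetic.SyntheticConfig(
    n_families=6,
    members_per_family=5,
    n_scaffolds=14,
    n_rgroups=24,
    pair_fraction=0.5,
)
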