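import numpy as np
import pytest
from hypothesis import settings

from pcmlab import synthetic
from pcmlab.curation import LabelScaler, curate_table
from pcmlab.featurization import DescriptorCache, assemble_matrix
from pcmlab.splits import random_split

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: small config: 9 proteins x 48 ligands, ~173 records — fast module tests
SMALL_CONFIG = synthetic.SyntheticConfig(
    n_families=3,
    members_per_family=3,
    seq_len_range=(80, 120),
    n_scaffolds=6,
    n_rgroups=8,
    pair_fraction=0.4,
    seed=7,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Clean small dataset: (proteins, ligands, table, truth)."""
    return synthetic.generate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_curated(small_dataset):
    _, _, table, _ = small_dataset
    pairs, audit = curate_table(table)
    return pairs, audit


@pytest.fixture(scope="session")
def small_matrices(small_dataset, small_curated):
    """Train/validation FeatureMatrix pair at 256 fingerprint bits with
    scaled labels, for model-level tests."""
    proteins, _, _, _ = small_dataset
    pairs, _ = small_curated
    smiles = pairs["canonical_smiles"].tolist()
    pids = pairs["uniprot_id"].tolist()
    y = pairs["pic50"].to_numpy()
    ids = list(range(len(y)))
    split = random_split(ids, fraction=0.8, seed=7)
    tr, va = list(split.train_ids), list(split.valid_ids)
    scaler = LabelScaler.fit(y[tr])
    cache = DescriptorCache(256)
    X_tr = assemble_matrix([(smiles[i], pids[i]) for i in tr], proteins, n_bits=256, cache=cache)
    X_va = assemble_matrix(
        [(smiles[i], pids[i]) for i in va],
        proteins,
        n_bits=256,
        scaler=(X_tr.scaler_mean, X_tr.scaler_scale),
        cache=cache,
    )
    return {
        "X_train": X_tr,
        "X_valid": X_va,
        "y_train": scaler.transform(y[tr]),
        "y_valid": scaler.transform(y[va]),
    }
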