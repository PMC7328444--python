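"""Curation of ChEMBL-style IC50 activity tables.

The pipeline mirrors standard bioactivity-data hygiene: keep only records
with nM units, top confidence, no "inconclusive" comment and no duplicate
flag; standardize structures to their charge parent; drop PAINS matches and
molecules outside the 75-800 Da window; collapse replicate measurements of
the same (molecule, protein) pair to the median IC50; convert to pIC50.

Every removal is attributed to the first rule that fired, and an audit
object guarantees input = output + removals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, FilterCatalog
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

REQUIRED_COLUMNS = [
    "record_id",
    "canonical_smiles",
    "uniprot_id",
    "standard_type",
    "standard_value",
    "standard_units",
    "confidence_score",
    "activity_comment",
    "potential_duplicate",
]

# order of attribution: a record is counted under the first rule that fires
RULE_ORDER = [
    "unparseable_smiles",
    "wrong_units",
    "potential_duplicate",
    "low_confidence",
    "inconclusive_comment",
    "nonpositive_value",
    "mw_out_of_range",
    "pains",
]


@dataclass
class CurationRules:
    required_units: str = "nM"
    required_confidence: int = 9
    forbidden_comment: str = "inconclusive"
    mw_min: float = 75.0
    mw_max: float = 800.0
    pains_enabled: bool = True

    def __post_init__(self):
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be < mw_max")


@dataclass
class CurationAudit:
    n_input: int = 0
    n_output: int = 0
    removed: dict = field(default_factory=dict)

    def check_conservation(self) -> bool:
        return self.n_input == self.n_output + sum(self.removed.values())


_PAINS_CATALOG = None


def _pains_catalog() -> FilterCatalog.FilterCatalog:
    """RDKit's built-in PAINS catalog, families A+B+C (lazy singleton)."""
    global _PAINS_CATALOG
    if _PAINS_CATALOG is None:
        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
        _PAINS_CATALOG = FilterCatalog.FilterCatalog(params)
        if _PAINS_CATALOG.GetNumEntries() == 0:
            raise RuntimeError("PAINS catalog failed to load")
    return _PAINS_CATALOG


def standardize_structure(smiles: str) -> str:
    """Charge-parent standardization: largest organic fragment, charges
    neutralized where chemically valid, canonical SMILES. Idempotent."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    parent = rdMolStandardize.ChargeParent(mol)
    return Chem.MolToSmiles(parent)


def pains_match(smiles: str, enabled: bool = True) -> bool:
    """True iff the (standardized) molecule hits any PAINS pattern."""
    if not enabled:
        return False
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return _pains_catalog().HasMatch(mol)


def to_pic50(ic50_nM):
    """pIC50 = 9 - log10(IC50 in nM). Input must be positive."""
    arr = np.asarray(ic50_nM, dtype=np.float64)
    if np.any(arr <= 0):
        raise ValueError("IC50 must be positive for pIC50 conversion")
    return 9.0 - np.log10(arr)


def from_pic50(pic50):
    """Inverse conversion: IC50 nM = 10**(9 - pIC50)."""
    return np.power(10.0, 9.0 - np.asarray(pic50, dtype=np.float64))


def apply_filters(
    records: pd.DataFrame, rules: CurationRules | None = None
) -> tuple[pd.DataFrame, CurationAudit]:
    """Standardize structures and apply the record filters.

    Returns the retained records (with ``canonical_smiles`` replaced by the
    standardized form and ``mol_weight`` added) plus the audit. Removal is
    attributed to the first rule in ``RULE_ORDER`` that fires; the retained
    *set* is order-independent because rules are conjunctive.
    """
    if rules is None:
        rules = CurationRules()
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise KeyError(f"missing required column(s): {missing}")

    audit = CurationAudit(n_input=len(records), removed={r: 0 for r in RULE_ORDER})
    keep_rows = []
    std_cache: dict[str, tuple[str | None, float, bool]] = {}

    for row in records.itertuples(index=False):
        smi = row.canonical_smiles
        if smi not in std_cache:
            try:
                std = standardize_structure(smi)
                mol = Chem.MolFromSmiles(std)
                mw = Descriptors.MolWt(mol)
                pains = pains_match(std, enabled=rules.pains_enabled)
                std_cache[smi] = (std, mw, pains)
            except ValueError:
                std_cache[smi] = (None, np.nan, False)
        std, mw, pains = std_cache[smi]

        reason = None
        if std is None:
            reason = "unparseable_smiles"
        elif str(row.standard_units) != rules.required_units:
            reason = "wrong_units"
        elif int(row.potential_duplicate) != 0:
            reason = "potential_duplicate"
        elif int(row.confidence_score) < rules.required_confidence:
            reason = "low_confidence"
        elif str(row.activity_comment).strip().lower() == rules.forbidden_comment:
            reason = "inconclusive_comment"
        elif not float(row.standard_value) > 0:
            reason = "nonpositive_value"
        elif not rules.mw_min <= mw <= rules.mw_max:
            reason = "mw_out_of_range"
        elif pains:
            reason = "pains"

        if reason is None:
            d = row._asdict()
            d["canonical_smiles"] = std
            d["mol_weight"] = mw
            keep_rows.append(d)
        else:
            audit.removed[reason] += 1

    out = pd.DataFrame(keep_rows, columns=list(records.columns) + ["mol_weight"])
    audit.n_output = len(out)
    assert audit.check_conservation()
    return out, audit


def aggregate_median(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate measurements per (canonical_smiles, uniprot_id)
    pair to the median standard_value (mean-of-middle-two for even counts).
    Adds ``n_measurements``."""
    grouped = (
        records.groupby(["canonical_smiles", "uniprot_id"], as_index=False, sort=True)
        .agg(
            standard_value=("standard_value", "median"),
            n_measurements=("standard_value", "size"),
        )
    )
    return grouped


@dataclass
class LabelScaler:
    """Standard scaler for pIC50 labels, fitted on training labels only.
    Population standard deviation."""

    mean: float
    scale: float

    @classmethod
    def fit(cls, train_pic50) -> "LabelScaler":
        arr = np.asarray(train_pic50, dtype=np.float64)
        if arr.size < 2:
            raise ValueError("need at least 2 training labels")
        sd = float(arr.std())
        if sd == 0.0:
            raise ValueError("zero spread in training labels")
        return cls(mean=float(arr.mean()), scale=sd)

    def transform(self, y):
        return (np.asarray(y, dtype=np.float64) - self.mean) / self.scale

    def inverse_transform(self, y_scaled):
        return np.asarray(y_scaled, dtype=np.float64) * self.scale + self.mean


def curate_table(
    records: pd.DataFrame, rules: CurationRules | None = None
) -> tuple[pd.DataFrame, CurationAudit]:
    """Full curation: filters -> median aggregation -> pIC50 conversion.

    Returns one row per retained (canonical_smiles, uniprot_id) pair with
    columns canonical_smiles, uniprot_id, standard_value, n_measurements,
    pic50, and the filter audit.
    """
    filtered, audit = apply_filters(records, rules)
    if filtered.empty:
        out = filtered.copy()
        out["pic50"] = []
        return out, audit
    pairs = aggregate_median(filtered)
    pairs["pic50"] = to_pic50(pairs["standard_value"].to_numpy())
    return pairs, audit
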