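"""Synthetic ChEMBL-like proteochemometric data with known ground truth.

The generator emulates the statistical structure of public bioactivity
data so the whole pipeline is testable without downloads:

* protein families: members derived from a random root sequence by
  per-residue substitution, giving related sequences per family;
* ligand libraries: enumerated from a shipped template grammar
  (ring scaffolds x acyclic substituents), guaranteeing a controllable
  number of distinct generic Bemis-Murcko scaffolds;
* labels: a sparse linear latent function over the *real* computed
  descriptors (plus a few protein x ligand interaction terms), affinely
  shifted/scaled to a publication-biased pIC50 distribution (mean ~6.5),
  with Gaussian experimental noise (default 0.5 log units, the typical
  heterogeneity of public IC50 data);
* contaminants: wrong units, low confidence scores, "inconclusive"
  comments, duplicate flags, replicate measurements, PAINS-bearing
  molecules and molecules outside the 75-800 Da window, injected at
  configurable rates, with a manifest recording exactly what a correct
  curation must retain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem

from . import featurization
from .featurization import AMINO_ACIDS, DescriptorCache

#: ene-rhodanine, a classic pan-assay interference core; appending it to a
#: molecule guarantees a PAINS-filter hit
PAINS_FRAGMENT = "O=C1NC(=S)SC1=Cc1ccccc1"
#: 55-carbon chain; appending it pushes any library molecule above 800 Da
HEAVY_FRAGMENT = "C" * 55

CONTAMINANT_KINDS = (
    "wrong_units",
    "low_confidence",
    "inconclusive",
    "duplicate_flag",
    "replicate",
    "pains",
    "mw_out_of_range",
)


@dataclass
class SyntheticConfig:
    n_families: int = 6
    members_per_family: int = 4
    mutation_rate: float = 0.05
    seq_len_range: tuple[int, int] = (150, 250)
    n_scaffolds: int = 12
    n_rgroups: int = 14
    pair_fraction: float = 0.5
    noise_sd: float = 0.5
    target_mean: float = 6.5
    target_sd: float = 1.3
    contamination_rates: dict = field(default_factory=dict)
    sparsity: float = 0.02
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.seq_len_range
        if lo <= 0 or lo > hi:
            raise ValueError("seq_len_range must be a positive interval (min <= max)")
        for name, p in [("mutation_rate", self.mutation_rate),
                        ("pair_fraction", self.pair_fraction),
                        ("sparsity", self.sparsity)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for kind, p in self.contamination_rates.items():
            if kind not in CONTAMINANT_KINDS:
                raise ValueError(f"unknown contaminant kind {kind!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"contamination rate for {kind!r} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("need at least one family with one member")
        if self.n_scaffolds < 1 or self.n_rgroups < 1:
            raise ValueError("need at least one scaffold and one substituent")

    def rate(self, kind: str) -> float:
        return float(self.contamination_rates.get(kind, 0.0))


@dataclass
class GroundTruth:
    """What the generator knows and a correct analysis should recover."""

    true_weight_index: np.ndarray  # feature indices into the 4671-dim pair vector
    true_weight_value: np.ndarray
    interaction_weights: list  # (protein_feature_idx, ligand_feature_idx, weight)
    noiseless_labels: np.ndarray  # per emitted record, pIC50 scale
    expected_post_curation_count: int
    pair_labels: dict  # (canonical_smiles, protein_id) -> noiseless pIC50


def _sub_rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


def gen_protein_family_set(config: SyntheticConfig) -> dict[str, str]:
    """Families of related sequences: the first member of each family is a
    random root; every further member derives from it by substituting each
    residue (to a *different* residue) with probability ``mutation_rate``."""
    rng = _sub_rng(config, 1)
    lo, hi = config.seq_len_range
    alphabet = np.array(list(AMINO_ACIDS))
    proteins: dict[str, str] = {}
    for fam in range(config.n_families):
        length = int(rng.integers(lo, hi + 1))
        root = rng.integers(0, 20, size=length)
        for mem in range(config.members_per_family):
            seq = root.copy()
            if mem > 0:
                hit = rng.random(length) < config.mutation_rate
                if hit.any():
                    # substitute with a uniformly chosen different residue
                    shift = rng.integers(1, 20, size=int(hit.sum()))
                    seq[hit] = (seq[hit] + shift) % 20
            proteins[f"P{fam + 1:02d}{mem + 1:03d}"] = "".join(alphabet[seq])
    return proteins


def _load_templates() -> dict:
    text = resources.files("pcmlab.data").joinpath("ligand_templates.json").read_text()
    return json.loads(text)


def gen_ligand_library(config: SyntheticConfig) -> list[str]:
    """Enumerate the template grammar: ``n_scaffolds`` ring templates x
    ``n_rgroups`` substituents, canonicalized and deduplicated."""
    templates = _load_templates()
    scaffolds = templates["scaffolds"]
    subs = templates["substituents"]
    if config.n_scaffolds > len(scaffolds):
        raise ValueError(
            f"requested {config.n_scaffolds} scaffolds but only "
            f"{len(scaffolds)} templates are shipped"
        )
    if config.n_rgroups > len(subs):
        raise ValueError(
            f"requested {config.n_rgroups} substituents but only "
            f"{len(subs)} fragments are shipped"
        )
    rng = _sub_rng(config, 2)
    chosen_sc = rng.permutation(len(scaffolds))[: config.n_scaffolds]
    chosen_sub = rng.permutation(len(subs))[: config.n_rgroups]
    seen: dict[str, None] = {}
    for i in chosen_sc:
        for j in chosen_sub:
            smi = scaffolds[i]["smiles"].format(R=subs[j])
            canon = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
            seen.setdefault(canon, None)
    return list(seen)


def _attach_fragment(smiles: str, fragment: str) -> str:
    """Single-bond a fragment onto the first available carbon of a molecule."""
    mol = Chem.MolFromSmiles(smiles)
    frag = Chem.MolFromSmiles(fragment)
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    n = mol.GetNumAtoms()
    host = next(
        a.GetIdx() for a in combo.GetAtoms()
        if a.GetIdx() < n and a.GetSymbol() == "C" and a.GetTotalNumHs() > 0
    )
    guest = next(
        a.GetIdx() for a in combo.GetAtoms()
        if a.GetIdx() >= n and a.GetSymbol() == "C" and a.GetTotalNumHs() > 0
    )
    combo.AddBond(host, guest, Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _zscore_columns(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (mat - mean) / sd


def gen_activity_table(
    proteins: dict[str, str],
    ligands: list[str],
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample protein x ligand pairs, score them with the sparse latent
    function, add noise and contaminants, and emit a ChEMBL-style table."""
    if not proteins or not ligands:
        raise ValueError("need nonempty protein set and ligand library")
    rng = _sub_rng(config, 3)

    pids = list(proteins)
    n_prot, n_lig = len(pids), len(ligands)
    n_pairs_total = n_prot * n_lig
    n_sampled = max(1, int(round(config.pair_fraction * n_pairs_total)))
    flat = rng.permutation(n_pairs_total)[:n_sampled]
    pair_idx = [(int(k) // n_lig, int(k) % n_lig) for k in flat]

    # real descriptors, z-scored per column over the sampled entity sets
    cache = DescriptorCache(featurization.N_FINGERPRINT_BITS)
    lig_desc = np.array([cache.ligand(s) for s in ligands])
    prot_desc = np.array([cache.protein(proteins[p]) for p in pids])
    lig_z = _zscore_columns(lig_desc)
    prot_z = _zscore_columns(prot_desc)

    n_lig_feat = lig_desc.shape[1]  # 4096 + 8
    n_feat = n_lig_feat + prot_desc.shape[1]  # + 567 = 4671
    k = max(1, int(round(config.sparsity * n_feat)))
    support = rng.permutation(n_feat)[:k]
    weights = rng.normal(size=k)
    w_lig = np.zeros(n_lig_feat)
    w_prot = np.zeros(n_feat - n_lig_feat)
    for idx, w in zip(support, weights):
        if idx < n_lig_feat:
            w_lig[idx] = w
        else:
            w_prot[idx - n_lig_feat] = w

    n_inter = max(1, k // 10)
    inter = [
        (int(rng.integers(0, n_feat - n_lig_feat)), int(rng.integers(0, n_lig_feat)),
         float(rng.normal()))
        for _ in range(n_inter)
    ]

    lig_score = lig_z @ w_lig
    prot_score = prot_z @ w_prot
    raw = np.array(
        [
            lig_score[j] + prot_score[i]
            + sum(w * prot_z[i, a] * lig_z[j, b] for a, b, w in inter)
            for i, j in pair_idx
        ]
    )
    sd = raw.std()
    centred = (raw - raw.mean()) / sd if sd > 1e-12 else np.zeros_like(raw)
    noiseless_pair = config.target_mean + config.target_sd * centred

    # molecule-level contaminants: the ligand is replaced wholesale
    lig_variant = list(ligands)
    lig_clean = np.ones(n_lig, dtype=bool)
    for j in range(n_lig):
        if rng.random() < config.rate("pains"):
            lig_variant[j] = _attach_fragment(ligands[j], PAINS_FRAGMENT)
            lig_clean[j] = False
        elif rng.random() < config.rate("mw_out_of_range"):
            lig_variant[j] = _attach_fragment(ligands[j], HEAVY_FRAGMENT)
            lig_clean[j] = False

    # records: one per sampled pair, plus i.i.d. replicates
    rows, noiseless_records, survives = [], [], []
    pair_labels: dict[tuple[str, str], float] = {}
    rid = 0
    for (i, j), y_star in zip(pair_idx, noiseless_pair):
        n_rep = 1 + int(rng.random() < config.rate("replicate"))
        for _ in range(n_rep):
            y = y_star + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
            units, conf, comment, dup = "nM", 9, "", 0
            record_clean = True
            if rng.random() < config.rate("wrong_units"):
                units, record_clean = "ug.mL-1", False
            if rng.random() < config.rate("low_confidence"):
                conf, record_clean = int(rng.integers(0, 9)), False
            if rng.random() < config.rate("inconclusive"):
                comment, record_clean = "inconclusive", False
            if rng.random() < config.rate("duplicate_flag"):
                dup, record_clean = 1, False
            rows.append(
                {
                    "record_id": f"R{rid:07d}",
                    "canonical_smiles": lig_variant[j],
                    "uniprot_id": pids[i],
                    "standard_type": "IC50",
                    "standard_value": 10.0 ** (9.0 - y),
                    "standard_units": units,
                    "confidence_score": conf,
                    "activity_comment": comment,
                    "potential_duplicate": dup,
                }
            )
            noiseless_records.append(y_star)
            survives.append(record_clean and lig_clean[j])
            rid += 1
        if lig_clean[j]:
            pair_labels[(ligands[j], pids[i])] = float(y_star)

    table = pd.DataFrame(rows)
    surviving_pairs = {
        (r["canonical_smiles"], r["uniprot_id"])
        for r, ok in zip(rows, survives)
        if ok
    }
    truth = GroundTruth(
        true_weight_index=np.sort(support),
        true_weight_value=np.array(
            [dict(zip(support, weights))[i] for i in np.sort(support)]
        ),
        interaction_weights=inter,
        noiseless_labels=np.array(noiseless_records),
        expected_post_curation_count=len(surviving_pairs),
        pair_labels=pair_labels,
    )
    return table, truth


def generate_dataset(config: SyntheticConfig):
    """Convenience: proteins, ligands, activity table and ground truth."""
    proteins = gen_protein_family_set(config)
    ligands = gen_ligand_library(config)
    table, truth = gen_activity_table(proteins, ligands, config)
    return proteins, ligands, table, truth
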