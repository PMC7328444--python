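"""Record splits: generic Bemis-Murcko scaffold, random, protein-held-out,
and the nested training/calibration split used for conformal prediction.

Grouped splits (scaffold, protein) fill the training set greedily from a
seed-shuffled group order until the target record fraction is reached, so no
group label ever spans training and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

#: reserved group key for acyclic molecules (no ring system)
EMPTY_SCAFFOLD = ""


@dataclass
class SplitAssignment:
    train_ids: list
    valid_ids: list
    calibration_ids: list
    method: str
    group_key: dict
    seed: int
    target_fraction: float

    @property
    def achieved_fraction(self) -> float:
        n = len(self.train_ids) + len(self.valid_ids) + len(self.calibration_ids)
        return len(self.train_ids) / n if n else 0.0

    def check_partition(self, all_ids) -> bool:
        tr, va, ca = map(set, (self.train_ids, self.valid_ids, self.calibration_ids))
        disjoint = not (tr & va or tr & ca or va & ca)
        return disjoint and (tr | va | ca) == set(all_ids)


def generic_scaffold(smiles: str) -> str:
    """Generic Bemis-Murcko scaffold key: ring systems + linkers with every
    atom mapped to carbon and every bond to single, as canonical SMILES.
    Acyclic molecules map to the reserved empty key."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    return Chem.MolToSmiles(MurckoScaffold.MakeScaffoldGeneric(scaffold))


def _grouped_split(
    record_ids: list,
    groups: list,
    fraction: float,
    seed: int,
    method: str,
) -> SplitAssignment:
    by_group: dict = {}
    for rid, g in zip(record_ids, groups):
        by_group.setdefault(g, []).append(rid)
    if len(by_group) < 2:
        raise ValueError("split impossible without leakage: single group")
    rng = np.random.default_rng(seed)
    order = list(by_group)
    rng.shuffle(order)
    target = fraction * len(record_ids)
    train, valid = [], []
    count = 0
    for g in order:
        members = by_group[g]
        if count < target:
            train.extend(members)
            count += len(members)
        else:
            valid.extend(members)
    if not valid:  # greedy consumed everything; give back the last group
        last = order[-1]
        members = set(by_group[last])
        train = [r for r in train if r not in members]
        valid = list(by_group[last])
    return SplitAssignment(
        train_ids=train,
        valid_ids=valid,
        calibration_ids=[],
        method=method,
        group_key=dict(zip(record_ids, groups)),
        seed=seed,
        target_fraction=fraction,
    )


def scaffold_split(
    record_ids: list, smiles: list, fraction: float = 0.8, seed: int = 0
) -> SplitAssignment:
    """80/20-style split with no generic scaffold shared between training
    and validation. All acyclic molecules form one (empty-key) group."""
    keys = [generic_scaffold(s) for s in smiles]
    if len(set(keys)) < 2:
        raise ValueError("split impossible without leakage: single scaffold group")
    return _grouped_split(record_ids, keys, fraction, seed, "scaffold")


def protein_split(
    record_ids: list, protein_ids: list, fraction: float = 0.8, seed: int = 0
) -> SplitAssignment:
    """Held-out-protein split: no protein ID spans training and validation."""
    if len(set(protein_ids)) < 2:
        raise ValueError("split impossible without leakage: single protein ID")
    return _grouped_split(record_ids, list(protein_ids), fraction, seed, "protein")


def random_split(record_ids: list, fraction: float = 0.8, seed: int = 0) -> SplitAssignment:
    """Uniform record-level shuffle split."""
    if len(record_ids) < 2:
        raise ValueError("need at least 2 records")
    rng = np.random.default_rng(seed)
    order = list(record_ids)
    rng.shuffle(order)
    n_train = int(round(fraction * len(order)))
    n_train = min(max(n_train, 1), len(order) - 1)
    return SplitAssignment(
        train_ids=order[:n_train],
        valid_ids=order[n_train:],
        calibration_ids=[],
        method="random",
        group_key={r: "" for r in record_ids},
        seed=seed,
        target_fraction=fraction,
    )


def calibration_split(
    assignment: SplitAssignment, fraction: float = 0.8, seed: int = 0
) -> SplitAssignment:
    """Randomly split an existing training set into proper-training and
    calibration subsets; the validation set is untouched."""
    if not assignment.train_ids:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    order = list(assignment.train_ids)
    rng.shuffle(order)
    n_train = int(round(fraction * len(order)))
    if n_train >= len(order):
        raise ValueError("calibration set would be empty")
    return SplitAssignment(
        train_ids=order[:n_train],
        valid_ids=list(assignment.valid_ids),
        calibration_ids=order[n_train:],
        method="calibration",
        group_key=dict(assignment.group_key),
        seed=seed,
        target_fraction=fraction,
    )
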