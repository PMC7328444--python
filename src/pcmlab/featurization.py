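"""Ligand and protein descriptors and pair-level feature matrix assembly.

Each protein–ligand pair is described by the concatenation of three blocks:

* ``fingerprint`` — 4096-bit ECFP6 (Morgan radius 3) circular fingerprint,
  kept as raw 0/1 columns;
* ``physchem`` — 8 physicochemical ligand descriptors (MW, TPSA, HBD, HBA,
  logP, heavy atoms, rotatable bonds, ring count);
* ``protein`` — 567 sequence descriptors: amino-acid composition (20),
  dipeptide composition (400) and composition/transition/distribution
  statistics over 7 physicochemical residue groupings (147).

Continuous blocks (physchem + protein) are standard-scaled with parameters
fitted on the training rows only; the binary fingerprint block is never
scaled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, rdMolDescriptors

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: dipeptides in row-major order over the fixed alphabet
DIPEPTIDES = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]

PHYSCHEM_NAMES = [
    "mol_weight",
    "tpsa",
    "num_hbd",
    "num_hba",
    "logp",
    "heavy_atoms",
    "rotatable_bonds",
    "ring_count",
]

N_FINGERPRINT_BITS = 4096
N_PHYSCHEM = 8
N_PROTEIN = 567


def _load_ctd_attributes() -> list[tuple[str, list[str]]]:
    text = resources.files("pcmlab.data").joinpath("ctd_attributes.json").read_text()
    raw = json.loads(text)
    out = []
    for att in raw["attributes"]:
        groups = att["groups"]
        joined = "".join(groups)
        if sorted(joined) != sorted(AMINO_ACIDS):
            raise ValueError(f"CTD attribute {att['name']} is not a partition of the alphabet")
        out.append((att["name"], groups))
    return out


CTD_ATTRIBUTES = _load_ctd_attributes()


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def ecfp6(smiles: str, n_bits: int = N_FINGERPRINT_BITS) -> np.ndarray:
    """Binary ECFP6 fingerprint (Morgan radius 3) folded to ``n_bits``."""
    fp = AllChem.GetMorganFingerprintAsBitVect(_mol(smiles), 3, nBits=n_bits)
    arr = np.zeros(n_bits, dtype=np.float64)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr


def physchem(smiles: str) -> np.ndarray:
    """The 8 ligand physicochemical descriptors, in the fixed order
    ``PHYSCHEM_NAMES``."""
    mol = _mol(smiles)
    return np.array(
        [
            Descriptors.MolWt(mol),
            Descriptors.TPSA(mol),
            rdMolDescriptors.CalcNumHBD(mol),
            rdMolDescriptors.CalcNumHBA(mol),
            Descriptors.MolLogP(mol),
            mol.GetNumHeavyAtoms(),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
            rdMolDescriptors.CalcNumRings(mol),
        ],
        dtype=np.float64,
    )


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    for pos, res in enumerate(sequence):
        if res not in _AA_INDEX:
            raise ValueError(f"non-canonical residue {res!r} at position {pos}")
    return sequence


def aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: per-residue frequencies (sums to 1)."""
    sequence = _check_sequence(sequence)
    counts = np.zeros(20, dtype=np.float64)
    for res in sequence:
        counts[_AA_INDEX[res]] += 1.0
    return counts / len(sequence)


def dpc(sequence: str) -> np.ndarray:
    """Dipeptide composition: overlapping dipeptide counts / (L-1)."""
    sequence = _check_sequence(sequence)
    if len(sequence) < 2:
        raise ValueError("dipeptide composition needs length >= 2")
    counts = np.zeros(400, dtype=np.float64)
    for a, b in zip(sequence, sequence[1:]):
        counts[_AA_INDEX[a] * 20 + _AA_INDEX[b]] += 1.0
    return counts / (len(sequence) - 1)


def _ctd_one_attribute(groups: Sequence[str], sequence: str) -> np.ndarray:
    """21 values for one attribute: composition (3), transition (3),
    distribution (15)."""
    L = len(sequence)
    member = {}
    for g, residues in enumerate(groups):
        for res in residues:
            member[res] = g
    labels = [member[res] for res in sequence]

    comp = np.bincount(labels, minlength=3).astype(np.float64) / L

    trans = np.zeros(3, dtype=np.float64)
    pair_slot = {(0, 1): 0, (1, 0): 0, (0, 2): 1, (2, 0): 1, (1, 2): 2, (2, 1): 2}
    for a, b in zip(labels, labels[1:]):
        slot = pair_slot.get((a, b))
        if slot is not None:
            trans[slot] += 1.0
    trans /= L - 1

    dist = np.zeros(15, dtype=np.float64)
    for g in range(3):
        positions = [i + 1 for i, lab in enumerate(labels) if lab == g]  # 1-based
        n_g = len(positions)
        if n_g == 0:
            continue
        for j, frac in enumerate((0.0, 0.25, 0.50, 0.75, 1.00)):
            # "first" occurrence for frac=0, else the ceil(frac*n_g)-th occurrence
            k = 1 if frac == 0.0 else int(np.ceil(frac * n_g))
            dist[g * 5 + j] = 100.0 * positions[k - 1] / L
    return np.concatenate([comp, trans, dist])


def ctd(sequence: str) -> np.ndarray:
    """Composition/transition/distribution descriptors: 7 attributes x 21
    values = 147, in the fixed attribute order of the shipped table."""
    sequence = _check_sequence(sequence)
    if len(sequence) < 2:
        raise ValueError("CTD needs length >= 2")
    return np.concatenate([_ctd_one_attribute(groups, sequence) for _, groups in CTD_ATTRIBUTES])


def protein_vector(sequence: str) -> np.ndarray:
    """Full 567-dimensional protein descriptor: [aac | dpc | ctd]."""
    return np.concatenate([aac(sequence), dpc(sequence), ctd(sequence)])


@dataclass
class FeatureMatrix:
    """Pair-level feature matrix with named column blocks and the standard
    scaler fitted on the training rows.

    ``block_index`` maps block name to a ``(start, stop)`` column range in
    order fingerprint, physchem, protein. ``scaler_mean``/``scaler_scale``
    cover the continuous columns (everything after the fingerprint block).
    """

    values: np.ndarray
    block_index: dict[str, tuple[int, int]]
    row_keys: list[tuple[str, str]]
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    n_bits: int = N_FINGERPRINT_BITS

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block(self, name: str) -> np.ndarray:
        start, stop = self.block_index[name]
        return self.values[:, start:stop]

    def feature_block_labels(self) -> np.ndarray:
        """Per-column block name, aligned with the columns of ``values``."""
        labels = np.empty(self.n_features, dtype=object)
        for name, (start, stop) in self.block_index.items():
            labels[start:stop] = name
        return labels

    def schema_fingerprint(self) -> str:
        return json.dumps(sorted((k, list(v)) for k, v in self.block_index.items()))


class DescriptorCache:
    """Memoizes per-entity descriptors so repeated (SMILES, protein) rows are
    assembled cheaply."""

    def __init__(self, n_bits: int = N_FINGERPRINT_BITS):
        self.n_bits = n_bits
        self._lig: dict[str, np.ndarray] = {}
        self._prot: dict[str, np.ndarray] = {}

    def ligand(self, smiles: str) -> np.ndarray:
        if smiles not in self._lig:
            self._lig[smiles] = np.concatenate([ecfp6(smiles, self.n_bits), physchem(smiles)])
        return self._lig[smiles]

    def protein(self, sequence: str) -> np.ndarray:
        if sequence not in self._prot:
            self._prot[sequence] = protein_vector(sequence)
        return self._prot[sequence]


def assemble_matrix(
    pairs: Sequence[tuple[str, str]],
    sequences: Mapping[str, str],
    n_bits: int = N_FINGERPRINT_BITS,
    scaler: tuple[np.ndarray, np.ndarray] | None = None,
    cache: DescriptorCache | None = None,
) -> FeatureMatrix:
    """Assemble the dense pair-level matrix for ``pairs`` of
    ``(smiles, protein_id)``.

    If ``scaler`` is None the continuous-block scaler is fitted on these rows
    (training usage); otherwise the provided ``(mean, scale)`` is applied
    (validation/calibration/test usage). Population standard deviation;
    zero-variance columns are centred but left unscaled.
    """
    if cache is None or cache.n_bits != n_bits:
        cache = DescriptorCache(n_bits)
    rows = []
    for smiles, pid in pairs:
        if pid not in sequences:
            raise KeyError(f"no sequence for protein ID {pid!r}")
        rows.append(np.concatenate([cache.ligand(smiles), cache.protein(sequences[pid])]))
    values = np.array(rows, dtype=np.float64)

    block_index = {
        "fingerprint": (0, n_bits),
        "physchem": (n_bits, n_bits + N_PHYSCHEM),
        "protein": (n_bits + N_PHYSCHEM, n_bits + N_PHYSCHEM + N_PROTEIN),
    }
    cont = values[:, n_bits:]
    if scaler is None:
        mean = cont.mean(axis=0)
        scale = cont.std(axis=0)  # population SD
        scale = np.where(scale == 0.0, 1.0, scale)
    else:
        mean, scale = scaler
    values[:, n_bits:] = (cont - mean) / scale
    return FeatureMatrix(
        values=values,
        block_index=block_index,
        row_keys=[tuple(p) for p in pairs],
        scaler_mean=np.asarray(mean, dtype=np.float64),
        scaler_scale=np.asarray(scale, dtype=np.float64),
        n_bits=n_bits,
    )
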