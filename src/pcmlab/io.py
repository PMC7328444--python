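"""Reading and writing the pipeline's on-disk formats.

Activity tables are plain CSV in the ChEMBL-style dialect defined by the
generator; sequences are FASTA (ID = protein accession); the ground-truth
manifest is JSON; feature matrices are persisted as NPZ with a JSON header
carrying the block index and scaler parameters; split assignments are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .featurization import FeatureMatrix
from .splits import SplitAssignment
from .synthetic import GroundTruth


def write_activity_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_activity_csv(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={"activity_comment": str},
        keep_default_na=False,
        na_values=[],
    )


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "true_weight_index": truth.true_weight_index.tolist(),
        "true_weight_value": truth.true_weight_value.tolist(),
        "interaction_weights": [list(t) for t in truth.interaction_weights],
        "noiseless_labels": truth.noiseless_labels.tolist(),
        "expected_post_curation_count": truth.expected_post_curation_count,
        "pair_labels": [
            {"canonical_smiles": s, "uniprot_id": p, "pic50": y}
            for (s, p), y in truth.pair_labels.items()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        true_weight_index=np.array(payload["true_weight_index"], dtype=int),
        true_weight_value=np.array(payload["true_weight_value"]),
        interaction_weights=[tuple(t) for t in payload["interaction_weights"]],
        noiseless_labels=np.array(payload["noiseless_labels"]),
        expected_post_curation_count=payload["expected_post_curation_count"],
        pair_labels={
            (d["canonical_smiles"], d["uniprot_id"]): d["pic50"]
            for d in payload["pair_labels"]
        },
    )


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    header = {
        "block_index": {k: list(v) for k, v in matrix.block_index.items()},
        "n_bits": matrix.n_bits,
        "row_keys": [list(k) for k in matrix.row_keys],
    }
    np.savez_compressed(
        path,
        values=matrix.values,
        scaler_mean=matrix.scaler_mean,
        scaler_scale=matrix.scaler_scale,
        header=np.array(json.dumps(header)),
    )


def read_feature_matrix(path) -> FeatureMatrix:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        return FeatureMatrix(
            values=data["values"],
            block_index={k: tuple(v) for k, v in header["block_index"].items()},
            row_keys=[tuple(k) for k in header["row_keys"]],
            scaler_mean=data["scaler_mean"],
            scaler_scale=data["scaler_scale"],
            n_bits=header["n_bits"],
        )


def write_split(assignment: SplitAssignment, path) -> None:
    rows = []
    for subset, ids in (
        ("train", assignment.train_ids),
        ("valid", assignment.valid_ids),
        ("calibration", assignment.calibration_ids),
    ):
        for rid in ids:
            rows.append(
                {
                    "record_id": rid,
                    "subset": subset,
                    "group_key": assignment.group_key.get(rid, ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_intervals_csv(record_ids, y_hat, spread, intervals, path) -> None:
    pd.DataFrame(
        {
            "record_id": record_ids,
            "y_hat": y_hat,
            "spread": spread,
            "lower": intervals.lower,
            "upper": intervals.upper,
            "confidence": intervals.confidence,
        }
    ).to_csv(path, index=False)
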