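"""File I/O: FASTA sequence sets, pair tables, feature matrices, score tables."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

PAIR_COLUMNS = ["protein_id", "rna_id", "label"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly line-wrapped, mixed-case) FASTA file into id -> sequence."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_pairs(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a 3-column TSV (protein_id, rna_id, label) with header."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "rna_id": str})
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pairs file missing columns: {missing}")
    labels = df["label"].astype(int)
    if not labels.isin([0, 1]).all():
        raise ValueError("pair labels must be 0 or 1")
    return list(zip(df["protein_id"], df["rna_id"], labels))


def write_pairs(pairs: Sequence[tuple[str, str, int]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def write_feature_matrix(
    X: np.ndarray, column_names: Sequence[str], path: str | Path
) -> None:
    """Write a feature matrix as TSV with a header naming each column."""
    pd.DataFrame(X, columns=list(column_names)).to_csv(path, sep="\t", index=False)


def write_scores(
    pairs: Sequence[tuple[str, str]],
    probabilities: np.ndarray,
    calls: np.ndarray,
    path: str | Path,
) -> None:
    df = pd.DataFrame(
        {
            "protein_id": [p[0] for p in pairs],
            "rna_id": [p[1] for p in pairs],
            "probability": probabilities,
            "call": calls.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str, "rna_id": str})
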