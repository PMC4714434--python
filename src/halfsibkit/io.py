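"""TSV/JSON dialects for genotype tables, count tables and pairwise matrices.

Genotypes: header ``sample_id`` then marker ids; cells 0/1/2/NA (NA =
missing).  Counts: columns ``contig_id``, ``length_bp``, then one column
per sample.  Pairwise matrices: square, labelled.  All files are plain
tab-separated text; JSON carries simulation truth and test results.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CountTable,
    GenotypeTable,
    Lot,
    MatrixKind,
    PairwiseMatrix,
    SampleRecord,
    Sex,
    SizeClass,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_counts",
    "write_counts",
    "read_matrix",
    "write_matrix",
    "read_samples",
    "write_samples",
]

MISSING_TOKEN = "NA"
_DOSAGE_TOKENS = {"0": 0.0, "1": 1.0, "2": 2.0, MISSING_TOKEN: np.nan}


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read a genotype TSV; every cell must be 0, 1, 2 or NA."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if not header or header[0] != "sample_id":
            raise ValueError(f"{path}: first header column must be 'sample_id'")
        markers = header[1:]
        rows, index = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} columns, got {len(row)}")
            index.append(row[0])
            parsed = []
            for marker, tok in zip(markers, row[1:]):
                if tok not in _DOSAGE_TOKENS:
                    raise ValueError(
                        f"{path}:{lineno}: invalid dosage {tok!r} for sample "
                        f"{row[0]!r}, marker {marker!r} (expected 0/1/2/NA)"
                    )
                parsed.append(_DOSAGE_TOKENS[tok])
            rows.append(parsed)
    if len(set(index)) != len(index):
        raise ValueError(f"{path}: duplicate sample ids")
    if len(set(markers)) != len(markers):
        raise ValueError(f"{path}: duplicate marker ids")
    return GenotypeTable(pd.DataFrame(rows, index=index, columns=markers))


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    def fmt(v: float) -> str:
        return MISSING_TOKEN if np.isnan(v) else str(int(v))

    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", *table.marker_ids])
        for sid, row in zip(table.sample_ids, table.dosages.to_numpy()):
            w.writerow([sid, *(fmt(v) for v in row)])


def read_counts(path: str | Path) -> CountTable:
    """Read a count TSV with columns contig_id, length_bp, then samples."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    if list(df.columns[:2]) != ["contig_id", "length_bp"]:
        raise ValueError(f"{path}: first columns must be contig_id, length_bp")
    sample_cols = list(df.columns[2:])
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns")
    counts = df[sample_cols]
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or not np.array_equal(vals, np.floor(vals)):
        raise ValueError(f"{path}: counts must be integers")
    if (vals < 0).any():
        r, c = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"{path}: negative count for contig {df['contig_id'].iloc[r]!r}, sample {sample_cols[c]!r}"
        )
    counts = counts.copy()
    counts.index = df["contig_id"]
    counts.index.name = None
    lengths = pd.Series(df["length_bp"].to_numpy(), index=counts.index, name="length_bp")
    if (lengths < 1).any():
        bad = lengths.index[lengths < 1][0]
        raise ValueError(f"{path}: length must be >= 1 bp (contig {bad!r})")
    return CountTable(counts, lengths)


def write_counts(table: CountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.insert(0, "length_bp", table.lengths)
    df.insert(0, "contig_id", table.contig_ids)
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, kind: MatrixKind | str) -> PairwiseMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    return PairwiseMatrix(df, MatrixKind(kind))


def write_matrix(matrix: PairwiseMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="sample_id")


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Read sample records from a TSV with columns sample_id, lot,
    size_class, dam_id, sire_id[, sex]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "lot", "size_class", "dam_id", "sire_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                lot=Lot(row["lot"]),
                size_class=SizeClass(row["size_class"]),
                dam_id=row["dam_id"],
                sire_id=row["sire_id"],
                sex=Sex(row["sex"]) if "sex" in df.columns and pd.notna(row.get("sex")) else Sex.UNKNOWN,
            )
        )
    return records


def write_samples(samples: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame([s.to_dict() for s in samples]).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
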