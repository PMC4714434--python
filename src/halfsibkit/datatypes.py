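"""Core in-memory containers shared across the pipeline.

All tabular data are held in pandas objects with domain validation applied
at construction time, so downstream stages can assume well-formed input:
genotype dosages are biallelic (0/1/2 with NaN for missing), counts are
non-negative integers with positive contig lengths, and pairwise matrices
are exactly symmetric with a zero diagonal.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Lot",
    "SizeClass",
    "Sex",
    "SampleRecord",
    "SimTruth",
    "GenotypeTable",
    "CountTable",
    "AbundanceTable",
    "Unit",
    "PairwiseMatrix",
    "UninformativePairError",
]


class UninformativePairError(ValueError):
    """Raised when a sample pair shares no informative (non-missing) marker."""


class Lot(str, enum.Enum):
    """Seasonal spawning lot (September or December cohort)."""

    SEPT = "SEPT"
    DEC = "DEC"


class SizeClass(str, enum.Enum):
    LARGE = "LARGE"
    SMALL = "SMALL"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class SampleRecord:
    """One offspring fish: its lot, size class and pedigree links."""

    sample_id: str
    lot: Lot
    size_class: SizeClass
    dam_id: str
    sire_id: str
    sex: Sex = Sex.UNKNOWN

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "lot": self.lot.value,
            "size_class": self.size_class.value,
            "dam_id": self.dam_id,
            "sire_id": self.sire_id,
            "sex": self.sex.value,
        }


def validate_design(samples: Sequence[SampleRecord]) -> None:
    """Check the default 12-fish design: 2 lots x 3 dams x {LARGE, SMALL},
    one sire per lot, one large and one small fish per (lot, dam)."""
    if len(samples) != 12:
        raise ValueError(f"expected 12 samples, got {len(samples)}")
    for lot in Lot:
        in_lot = [s for s in samples if s.lot == lot]
        if len(in_lot) != 6:
            raise ValueError(f"lot {lot.value}: expected 6 fish, got {len(in_lot)}")
        if len({s.sire_id for s in in_lot}) != 1:
            raise ValueError(f"lot {lot.value}: fish do not share a single sire")
        by_dam: dict[str, list[SampleRecord]] = {}
        for s in in_lot:
            by_dam.setdefault(s.dam_id, []).append(s)
        if len(by_dam) != 3:
            raise ValueError(f"lot {lot.value}: expected 3 dams, got {len(by_dam)}")
        for dam, sibs in by_dam.items():
            sizes = sorted(s.size_class for s in sibs)
            if sizes != [SizeClass.LARGE, SizeClass.SMALL]:
                raise ValueError(
                    f"lot {lot.value}, dam {dam}: need exactly one LARGE and one SMALL fish"
                )


@dataclass
class SimTruth:
    """Ground truth emitted by the simulators for parameter-recovery tests."""

    seed: int
    parameters: dict = field(default_factory=dict)
    planted_marker_ids: list[str] = field(default_factory=list)
    de_contig_ids: list[tuple[str, str, float]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "parameters": self.parameters,
                "planted_marker_ids": self.planted_marker_ids,
                "de_contig_ids": [list(t) for t in self.de_contig_ids],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            parameters=d["parameters"],
            planted_marker_ids=list(d["planted_marker_ids"]),
            de_contig_ids=[(c, f, float(l)) for c, f, l in d["de_contig_ids"]],
        )


_ALLOWED_DOSAGES = (0.0, 1.0, 2.0)


@dataclass
class GenotypeTable:
    """Biallelic dosage matrix, samples x markers; NaN encodes missing.

    Only dosages 0, 1 and 2 are permitted — the coefficient of shared
    alleles 2 - |d_a - d_b| is exact for biallelic markers only, so
    anything else is rejected at construction.
    """

    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = self.dosages.astype(float)
        vals = self.dosages.to_numpy()
        bad = ~(np.isnan(vals) | np.isin(vals, _ALLOWED_DOSAGES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {vals[i, j]!r} at sample "
                f"{self.dosages.index[i]!r}, marker {self.dosages.columns[j]!r}; "
                "dosages must be 0, 1, 2 or missing"
            )
        if self.dosages.index.has_duplicates:
            raise ValueError("duplicate sample ids in genotype table")
        if self.dosages.columns.has_duplicates:
            raise ValueError("duplicate marker ids in genotype table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset(self, sample_ids: Sequence[str]) -> "GenotypeTable":
        return GenotypeTable(self.dosages.loc[list(sample_ids)])


@dataclass
class CountTable:
    """Raw read counts, contigs x samples, with per-contig lengths in bp."""

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate contig ids in count table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValueError("negative counts are not allowed")
        if not np.array_equal(vals, np.floor(vals)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][0]
            raise ValueError(f"missing length for contig {missing!r}")
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise ValueError(f"non-positive length for contig {bad!r}")
        self.lengths = self.lengths.astype(np.int64)

    @property
    def contig_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, contig_ids: Sequence[str]) -> "CountTable":
        ids = list(contig_ids)
        return CountTable(self.counts.loc[ids], self.lengths.loc[ids])


class Unit(str, enum.Enum):
    CPM = "CPM"
    RPKM = "RPKM"
    MEDIAN_RATIO = "MEDIAN_RATIO"


@dataclass
class AbundanceTable:
    """Normalised expression values (CPM, RPKM or median-ratio units)."""

    values: pd.DataFrame
    unit: Unit

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        self.values = self.values.astype(float)
        vals = self.values.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.unit is Unit.MEDIAN_RATIO and vals.size and (vals > 2 + 1e-12).any():
            raise ValueError("median-ratio values must lie in [0, 2]")

    @property
    def contig_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


class MatrixKind(str, enum.Enum):
    CSSC_DISTANCE = "CSSC_DISTANCE"
    PAD = "PAD"


@dataclass
class PairwiseMatrix:
    """Symmetric sample x sample distance matrix with per-cell support counts.

    `n_informative` records, for each pair, how many markers (or transcripts)
    backed the distance value.
    """

    values: pd.DataFrame
    kind: MatrixKind
    n_informative: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.kind = MatrixKind(self.kind)
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValueError("pairwise matrix must be square")
        if not list(self.values.index) == list(self.values.columns):
            raise ValueError("row and column labels must match")
        if not np.allclose(np.diag(v), 0.0, atol=0.0):
            raise ValueError("diagonal must be exactly zero")
        if not np.array_equal(v, v.T):
            raise ValueError("matrix must be exactly symmetric")
        if v.size and (v < 0).any():
            raise ValueError("distances must be non-negative")
        if self.kind is MatrixKind.CSSC_DISTANCE and v.size and (v > 1 + 1e-12).any():
            raise ValueError("1-CSSC distances must lie in [0, 1]")

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)
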