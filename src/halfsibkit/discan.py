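"""Per-marker Dissimilarity Index (DI) scan for size-associated SNPs.

Within each seasonal lot, every SMALL fish is compared to every LARGE fish
(9 pairs in the default 3+3 design).  A pair scores 1 if the two genotypes
differ (full-genotype comparison: heterozygote vs homozygote counts as
different) and 0 if identical; the DI is the mean over pairs where both
genotypes are observed.  Because each lot is a set of paternal half-sib
families, a marker with DI near 1 in BOTH lots flags a region whose
paternally transmitted alleles segregate with size class.

Two pass criteria are provided: the default requires DI strictly greater
than the threshold (0.89) in both lots; the alternative ``max_one_match``
criterion allows at most one identical small/large pair per lot, the
intent behind "one allowed similarity match" (note 8/9 = 0.889 fails the
strict 0.89 cutoff but passes max_one_match).

A permutation null — shuffling size-class labels within each lot while
keeping lot membership fixed — calibrates how many passing markers to
expect by chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import GenotypeTable, Lot, SampleRecord, SizeClass

__all__ = ["DIRecord", "di_per_marker", "scan_size_markers", "permutation_null", "PermutationNull"]


@dataclass
class DIRecord:
    """One marker's DI per lot with its pass/fail decision."""

    marker_id: str
    di_by_lot: dict[str, float]
    n_informative_by_lot: dict[str, int]
    n_identical_by_lot: dict[str, int]
    passes: bool
    threshold: float

    def to_dict(self) -> dict:
        return {
            "marker_id": self.marker_id,
            "di_by_lot": self.di_by_lot,
            "n_informative_by_lot": self.n_informative_by_lot,
            "n_identical_by_lot": self.n_identical_by_lot,
            "passes": self.passes,
            "threshold": self.threshold,
        }


def _size_partition(
    samples: Sequence[SampleRecord], lot: Lot
) -> tuple[list[str], list[str]]:
    small = [s.sample_id for s in samples if s.lot == lot and s.size_class is SizeClass.SMALL]
    large = [s.sample_id for s in samples if s.lot == lot and s.size_class is SizeClass.LARGE]
    return small, large


def _di_all_markers(
    dos: np.ndarray, small_rows: np.ndarray, large_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised DI over all markers for one small/large partition.

    Returns (di, n_informative, n_identical) arrays of length n_markers;
    di is NaN where no pair is informative.
    """
    s = dos[small_rows]  # (n_small, m)
    l = dos[large_rows]  # (n_large, m)
    informative = ~np.isnan(s)[:, None, :] & ~np.isnan(l)[None, :, :]
    different = (s[:, None, :] != l[None, :, :]) & informative
    n_inf = informative.sum(axis=(0, 1))
    n_diff = different.sum(axis=(0, 1))
    with np.errstate(invalid="ignore"):
        di = np.where(n_inf > 0, n_diff / np.maximum(n_inf, 1), np.nan)
    return di, n_inf, n_inf - n_diff


def di_per_marker(
    genotypes: GenotypeTable,
    samples: Sequence[SampleRecord],
    lot: Lot | str,
    marker: str,
) -> tuple[float, int]:
    """DI and informative-pair count for one marker within one lot.

    Returns ``(nan, 0)`` when no small/large pair is informative — such a
    marker is flagged as undefined and excluded from scans.
    """
    lot = Lot(lot)
    small, large = _size_partition(samples, lot)
    if not small or not large:
        raise ValueError(f"lot {lot.value} needs at least one small and one large fish")
    col = genotypes.marker_ids.index(marker)
    dos = genotypes.dosages.to_numpy(dtype=float)[:, [col]]
    idx = {sid: i for i, sid in enumerate(genotypes.sample_ids)}
    di, n_inf, _ = _di_all_markers(
        dos, np.array([idx[s] for s in small]), np.array([idx[s] for s in large])
    )
    return float(di[0]), int(n_inf[0])


def _scan_arrays(
    genotypes: GenotypeTable,
    samples: Sequence[SampleRecord],
    partitions: dict[Lot, tuple[list[str], list[str]]],
):
    dos = genotypes.dosages.to_numpy(dtype=float)
    idx = {sid: i for i, sid in enumerate(genotypes.sample_ids)}
    out = {}
    for lot, (small, large) in partitions.items():
        out[lot] = _di_all_markers(
            dos, np.array([idx[s] for s in small]), np.array([idx[s] for s in large])
        )
    return out


def _passing_mask(
    per_lot, threshold: float, min_informative: int, criterion: str
) -> np.ndarray:
    masks = []
    for di, n_inf, n_same in per_lot.values():
        ok_inf = n_inf >= min_informative
        if criterion == "strict":
            masks.append(ok_inf & ~np.isnan(di) & (di > threshold))
        elif criterion == "max_one_match":
            masks.append(ok_inf & (n_same <= 1))
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    return np.logical_and.reduce(masks)


def scan_size_markers(
    genotypes: GenotypeTable,
    samples: Sequence[SampleRecord],
    threshold: float = 0.89,
    min_informative: int = 9,
    criterion: str = "strict",
) -> list[DIRecord]:
    """Markers whose DI exceeds the threshold in every seasonal lot.

    A marker passes iff, in BOTH lots, it has at least ``min_informative``
    informative small/large pairs and meets the pass criterion (strict
    DI > threshold by default).  Results are sorted by the minimum-over-lots
    DI, descending, ties broken by marker id.
    """
    lots = sorted({s.lot for s in samples}, key=lambda l: l.value)
    if len(lots) < 2:
        raise ValueError("scan requires both seasonal lots")
    partitions = {lot: _size_partition(samples, lot) for lot in lots}
    per_lot = _scan_arrays(genotypes, samples, partitions)
    passing = _passing_mask(per_lot, threshold, min_informative, criterion)

    records = []
    markers = genotypes.marker_ids
    for m in np.flatnonzero(passing):
        records.append(
            DIRecord(
                marker_id=markers[m],
                di_by_lot={lot.value: float(per_lot[lot][0][m]) for lot in lots},
                n_informative_by_lot={lot.value: int(per_lot[lot][1][m]) for lot in lots},
                n_identical_by_lot={lot.value: int(per_lot[lot][2][m]) for lot in lots},
                passes=True,
                threshold=threshold,
            )
        )
    records.sort(key=lambda r: (-min(r.di_by_lot.values()), r.marker_id))
    return records


@dataclass
class PermutationNull:
    """Null distribution of passing-marker counts under size-label shuffling."""

    observed: int
    null_counts: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.null_counts, q))


def permutation_null(
    genotypes: GenotypeTable,
    samples: Sequence[SampleRecord],
    n_perm: int = 199,
    threshold: float = 0.89,
    seed: int = 0,
    min_informative: int = 9,
    criterion: str = "strict",
) -> PermutationNull:
    """Empirical null for the number of scan-passing markers.

    Each permutation independently shuffles size-class labels among the fish
    of each lot (lot and family structure fixed) and re-runs the scan.  The
    empirical p-value is ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    lots = sorted({s.lot for s in samples}, key=lambda l: l.value)
    if len(lots) < 2:
        raise ValueError("permutation scan requires both seasonal lots")

    dos = genotypes.dosages.to_numpy(dtype=float)
    idx = {sid: i for i, sid in enumerate(genotypes.sample_ids)}
    lot_members = {lot: [s.sample_id for s in samples if s.lot == lot] for lot in lots}
    n_small = {
        lot: sum(1 for s in samples if s.lot == lot and s.size_class is SizeClass.SMALL)
        for lot in lots
    }

    def count_passing(partitions: dict[Lot, tuple[list[str], list[str]]]) -> int:
        per_lot = {}
        for lot, (small, large) in partitions.items():
            per_lot[lot] = _di_all_markers(
                dos, np.array([idx[s] for s in small]), np.array([idx[s] for s in large])
            )
        return int(_passing_mask(per_lot, threshold, min_informative, criterion).sum())

    observed = count_passing({lot: _size_partition(samples, lot) for lot in lots})

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    null = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        partitions = {}
        for lot in lots:
            members = list(lot_members[lot])
            perm = rng.permutation(len(members))
            k = n_small[lot]
            partitions[lot] = (
                [members[i] for i in perm[:k]],
                [members[i] for i in perm[k:]],
            )
        null[b] = count_passing(partitions)
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return PermutationNull(observed=observed, null_counts=null, p_value=p, n_perm=n_perm, seed=seed)
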