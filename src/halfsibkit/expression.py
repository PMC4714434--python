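"""Library-size normalisation (CPM/RPKM) and contig-filtering rules.

Two pre-analysis filters are implemented: a low-expression exclusion
(contigs must be detected in more than three fish AND exceed one CPM summed
across fish) and a high-expression subset (at least 5 RPKM, inclusive, in
two or more fish) used for expression-distance analyses over the most
highly expressed transcripts.  Benjamini-Hochberg FDR control is exposed as
a small utility for consumers of per-contig p-values.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import AbundanceTable, CountTable, Unit

__all__ = [
    "compute_cpm",
    "compute_rpkm",
    "filter_low_expression",
    "high_expression_subset",
    "bh_fdr",
]


def _column_totals(counts: CountTable) -> np.ndarray:
    return counts.counts.to_numpy(dtype=float).sum(axis=0)


def compute_cpm(counts: CountTable) -> AbundanceTable:
    """Counts per million aligned reads: count * 1e6 / library column total.

    Columns with zero total reads are returned all-zero rather than raising.
    """
    if counts.counts.size == 0:
        raise ValueError("empty count table")
    totals = _column_totals(counts)
    safe = np.where(totals > 0, totals, 1.0)
    cpm = counts.counts.to_numpy(dtype=float) * 1e6 / safe[None, :]
    cpm[:, totals == 0] = 0.0
    return AbundanceTable(
        pd.DataFrame(cpm, index=counts.counts.index, columns=counts.counts.columns),
        Unit.CPM,
    )


def compute_rpkm(counts: CountTable) -> AbundanceTable:
    """Reads per kilobase of contig per million aligned reads:
    count / (length/1000) / (column total / 1e6)."""
    if counts.counts.size == 0:
        raise ValueError("empty count table")
    totals = _column_totals(counts)
    safe = np.where(totals > 0, totals, 1.0)
    kb = counts.lengths.to_numpy(dtype=float) / 1000.0
    rpkm = counts.counts.to_numpy(dtype=float) / kb[:, None] / (safe[None, :] / 1e6)
    rpkm[:, totals == 0] = 0.0
    return AbundanceTable(
        pd.DataFrame(rpkm, index=counts.counts.index, columns=counts.counts.columns),
        Unit.RPKM,
    )


def filter_low_expression(
    counts: CountTable,
    min_expressing_fish: int = 4,
    min_total_cpm: float = 1.0,
    per_sample_cpm: bool = False,
) -> list[str]:
    """Contig ids passing the low-expression exclusion rules.

    A contig is kept iff it is detected (raw count > 0) in at least
    ``min_expressing_fish`` samples AND its CPM, summed across samples,
    exceeds ``min_total_cpm``.  The defaults keep contigs detected in more
    than 3 fish with total CPM above 1.  With ``per_sample_cpm`` the CPM
    clause instead requires at least one sample above the threshold.
    Input order is preserved.
    """
    n_samples = counts.counts.shape[1]
    if min_expressing_fish > n_samples:
        raise ValueError("min_expressing_fish exceeds the number of samples")
    detected = (counts.counts.to_numpy() > 0).sum(axis=1)
    cpm = compute_cpm(counts).values.to_numpy()
    if per_sample_cpm:
        cpm_ok = (cpm > min_total_cpm).any(axis=1)
    else:
        cpm_ok = cpm.sum(axis=1) > min_total_cpm
    keep = (detected >= min_expressing_fish) & cpm_ok
    return [cid for cid, k in zip(counts.contig_ids, keep) if k]


def high_expression_subset(
    rpkm: AbundanceTable,
    min_rpkm: float = 5.0,
    min_fish: int = 2,
) -> list[str]:
    """Contigs whose expression matches or exceeds ``min_rpkm`` RPKM
    (inclusive) in at least ``min_fish`` samples."""
    if rpkm.unit is not Unit.RPKM:
        raise ValueError(f"expected RPKM values, got {rpkm.unit.value}")
    qualifying = (rpkm.values.to_numpy() >= min_rpkm).sum(axis=1)
    return [cid for cid, q in zip(rpkm.contig_ids, qualifying) if q >= min_fish]


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject flags, adjusted p-values) in the input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, adjusted
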