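"""Pairwise Absolute Difference (PAD) expression distances.

Per transcript, each fish's RPKM value is first expressed relative to the
median across fish, giving ratios bounded in [0, 2]; the PAD between two
fish is then the mean absolute difference of these ratios over the shared
transcript set — a (scaled) L1 metric over a fixed coordinate space.

Two bounded ratio transforms are provided.  The default divides by the
median and caps at 2 (``capped``); the alternative ``rational`` transform
2*v/(v + m) is smooth, bounded by construction, and equals 1 at the median.
Transcripts whose median is zero have no defined ratio and are excluded
(and reported) rather than assigned an arbitrary value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AbundanceTable, MatrixKind, PairwiseMatrix, Unit

__all__ = ["median_ratio_adjust", "pad_matrix"]


def median_ratio_adjust(
    expr: AbundanceTable,
    transform: str = "capped",
) -> tuple[AbundanceTable, list[str]]:
    """Adjust expression values to per-transcript median ratios in [0, 2].

    Returns the ratio table and the list of excluded (median-zero)
    transcript ids.  ``transform`` is ``"capped"`` (v/m clipped at 2) or
    ``"rational"`` (2*v/(v+m)).
    """
    if expr.unit is not Unit.RPKM:
        raise ValueError(f"expected RPKM values, got {expr.unit.value}")
    if expr.values.shape[1] < 2:
        raise ValueError("need at least two samples")
    if expr.values.size == 0:
        raise ValueError("empty abundance table")
    if transform not in ("capped", "rational"):
        raise ValueError(f"unknown transform {transform!r}")

    vals = expr.values.to_numpy(dtype=float)
    medians = np.median(vals, axis=1)
    keep = medians > 0
    excluded = [cid for cid, k in zip(expr.contig_ids, keep) if not k]
    v = vals[keep]
    m = medians[keep][:, None]
    if transform == "capped":
        ratios = np.minimum(v / m, 2.0)
    else:
        ratios = 2.0 * v / (v + m)
    out = AbundanceTable(
        pd.DataFrame(
            ratios,
            index=[cid for cid, k in zip(expr.contig_ids, keep) if k],
            columns=expr.sample_ids,
        ),
        Unit.MEDIAN_RATIO,
    )
    return out, excluded


def pad_matrix(ratios: AbundanceTable) -> PairwiseMatrix:
    """Mean absolute difference of median ratios between every pair of fish.

    Values lie in [0, 2]; the matrix is exactly symmetric with zero
    diagonal, and every cell is backed by the full included transcript set.
    """
    if ratios.unit is not Unit.MEDIAN_RATIO:
        raise ValueError(f"expected MEDIAN_RATIO values, got {ratios.unit.value}")
    n_transcripts, n_samples = ratios.values.shape
    if n_transcripts == 0:
        raise ValueError("no transcripts to compare")
    v = ratios.values.to_numpy(dtype=float)
    pad = np.zeros((n_samples, n_samples))
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            d = float(np.mean(np.abs(v[:, i] - v[:, j])))
            pad[i, j] = pad[j, i] = d
    ids = ratios.sample_ids
    n_inf = pd.DataFrame(
        np.full((n_samples, n_samples), n_transcripts, dtype=np.int64), index=ids, columns=ids
    )
    return PairwiseMatrix(
        values=pd.DataFrame(pad, index=ids, columns=ids),
        kind=MatrixKind.PAD,
        n_informative=n_inf,
    )
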