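"""Identity-by-state allele sharing (CSSC) and the 1-CSSC distance matrix.

The chromosome segment sharing coefficient between two fish is the mean,
over markers where both genotypes are observed, of the number of alleles
shared identical-by-state (0, 1 or 2) divided by 2.  For biallelic dosages
the shared-allele count is exactly ``2 - |d_a - d_b|``.  Each pair's
denominator is its own informative-marker count (pairwise-complete), so a
marker failing in one fish only removes that fish's pairs.  No allele
frequency enters: this is IBS sharing, not an IBD kinship estimate.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .datatypes import (
    GenotypeTable,
    MatrixKind,
    PairwiseMatrix,
    UninformativePairError,
)

__all__ = ["cssc_pair", "cssc_distance_matrix"]


def cssc_pair(g_a, g_b) -> tuple[float, int]:
    """Allele-sharing coefficient for one pair of dosage vectors.

    Returns ``(cssc, n_informative)`` where cssc is the mean of
    (shared alleles / 2) over the markers informative for this pair.
    Raises :class:`UninformativePairError` if no marker is informative.
    """
    a = np.asarray(g_a, dtype=float)
    b = np.asarray(g_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    informative = ~np.isnan(a) & ~np.isnan(b)
    n = int(informative.sum())
    if n == 0:
        raise UninformativePairError("no informative markers for this pair")
    shared = 2.0 - np.abs(a[informative] - b[informative])
    return float(shared.sum() / (2.0 * n)), n


def cssc_distance_matrix(genotypes: GenotypeTable) -> PairwiseMatrix:
    """Symmetric 1-CSSC distance matrix over all sample pairs.

    Every pair must have at least one informative marker; a fully
    uninformative pair raises an error naming the two samples.
    """
    ids = genotypes.sample_ids
    if len(ids) < 2:
        raise ValueError("need at least two samples")
    dos = genotypes.dosages.to_numpy(dtype=float)
    n = len(ids)
    dist = np.zeros((n, n))
    n_inf = np.zeros((n, n), dtype=np.int64)
    n_inf[np.diag_indices(n)] = (~np.isnan(dos)).sum(axis=1)
    for i, j in itertools.combinations(range(n), 2):
        try:
            cssc, k = cssc_pair(dos[i], dos[j])
        except UninformativePairError as err:
            raise UninformativePairError(
                f"samples {ids[i]!r} and {ids[j]!r} share no informative marker"
            ) from err
        dist[i, j] = dist[j, i] = 1.0 - cssc
        n_inf[i, j] = n_inf[j, i] = k
    return PairwiseMatrix(
        values=pd.DataFrame(dist, index=ids, columns=ids),
        kind=MatrixKind.CSSC_DISTANCE,
        n_informative=pd.DataFrame(n_inf, index=ids, columns=ids),
    )
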