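"""Contingency tests on category counts: Pearson chi-square, G-tests,
backward-elimination heterogeneity screening, and the replicated-G
decomposition.

The 2x2 overlap test contrasts how many significant contigs each size class
shares with each seasonal lot; it is the uncorrected Pearson statistic (no
continuity correction).  The G-test framework operates on 2xk
group-by-category count tables (e.g. GOSlim term counts for two contrasts);
backward elimination repeatedly removes the category contributing most to
heterogeneity until the remaining table is homogeneous, the removed
categories being the ones declared significantly different.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2xK",
    "TestResult",
    "EliminationTrace",
    "shared_contigs",
    "overlap_2x2",
    "chi_square_2x2",
    "g_test",
    "backward_elimination_g",
    "replicated_g_decomposition",
]


@dataclass
class ContingencyTable2xK:
    """A 2 x k table of non-negative integer counts."""

    counts: np.ndarray
    group_labels: tuple[str, str] = ("group1", "group2")
    category_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2 or self.counts.shape[1] < 1:
            raise ValueError("counts must be a 2 x k array with k >= 1")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.category_labels is None:
            self.category_labels = [f"cat{i + 1}" for i in range(self.counts.shape[1])]
        self.category_labels = list(self.category_labels)
        if len(self.category_labels) != self.counts.shape[1]:
            raise ValueError("category_labels length must match k")

    @property
    def k(self) -> int:
        return self.counts.shape[1]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TestResult:
    statistic_name: str  # "CHI2" or "G"
    value: float
    df: int
    p_value: float
    correction: str = "NONE"  # or "WILLIAMS"

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "value": self.value,
            "df": self.df,
            "p_value": self.p_value,
            "correction": self.correction,
        }


def shared_contigs(list_a: Iterable[str], list_b: Iterable[str]) -> tuple[int, list[str]]:
    """Size and sorted members of the intersection of two contig-id lists
    (duplicates within a list collapse)."""
    shared = sorted(set(list_a) & set(list_b))
    return len(shared), shared


def overlap_2x2(
    sept_shared_small: int,
    dec_shared_small: int,
    sept_shared_large: int,
    dec_shared_large: int,
) -> ContingencyTable2xK:
    """Assemble the size-class x season shared-contig table:
    rows = {small, large}, columns = {Sept, Dec}."""
    counts = [[sept_shared_small, dec_shared_small], [sept_shared_large, dec_shared_large]]
    if min(min(r) for r in counts) < 0:
        raise ValueError("overlap counts must be non-negative")
    return ContingencyTable2xK(
        np.asarray(counts), group_labels=("small", "large"), category_labels=["Sept", "Dec"]
    )


def _check_margins(counts: np.ndarray) -> None:
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: every row and column total must be positive")


def chi_square_2x2(table: ContingencyTable2xK) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 table, 1 df."""
    if table.k != 2:
        raise ValueError("chi_square_2x2 requires a 2 x 2 table")
    _check_margins(table.counts)
    chi2, p, df, _ = stats.chi2_contingency(table.counts, correction=False)
    return TestResult("CHI2", float(chi2), int(df), float(p))


def _g_terms(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Per-cell contributions 2*o*ln(o/e), with the 0*ln0 := 0 convention."""
    terms = np.zeros_like(expected, dtype=float)
    nz = observed > 0
    terms[nz] = 2.0 * observed[nz] * np.log(observed[nz] / expected[nz])
    return terms


def g_test(table: ContingencyTable2xK, williams: bool = False) -> TestResult:
    """Log-likelihood-ratio (G) test of independence on a 2 x k table.

    Zero cells contribute zero; categories with both cells zero are dropped
    with a warning before testing.  The Williams correction divides G by
    q = 1 + (N*sum(1/row)-1)(N*sum(1/col)-1) / (6*N*df).
    """
    counts = table.counts
    empty = counts.sum(axis=0) == 0
    if empty.any():
        dropped = [l for l, e in zip(table.category_labels, empty) if e]
        warnings.warn(f"dropping all-zero categories before G-test: {dropped}")
        counts = counts[:, ~empty]
    if counts.shape[1] < 2:
        raise ValueError("G-test needs at least two non-empty categories")
    _check_margins(counts)
    row = counts.sum(axis=1, dtype=float)
    col = counts.sum(axis=0, dtype=float)
    n = counts.sum(dtype=float)
    expected = np.outer(row, col) / n
    g = float(_g_terms(counts, expected).sum())
    df = counts.shape[1] - 1
    correction = "NONE"
    if williams:
        q = 1.0 + (n * (1.0 / row).sum() - 1.0) * (n * (1.0 / col).sum() - 1.0) / (6.0 * n * df)
        g /= q
        correction = "WILLIAMS"
    g = max(g, 0.0)
    return TestResult("G", g, df, float(stats.chi2.sf(g, df)), correction)


@dataclass
class EliminationStep:
    removed_category: str
    g_before: float
    p_before: float
    contributions: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "removed_category": self.removed_category,
            "g_before": self.g_before,
            "p_before": self.p_before,
            "contributions": self.contributions,
        }


@dataclass
class EliminationTrace:
    steps: list[EliminationStep]
    final: TestResult | None
    flagged: list[str]
    retained: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "steps": [s.to_dict() for s in self.steps],
            "final": self.final.to_dict() if self.final else None,
            "flagged": self.flagged,
            "retained": self.retained,
        }


def backward_elimination_g(
    table: ContingencyTable2xK,
    alpha: float = 0.05,
    williams: bool = False,
) -> EliminationTrace:
    """Iteratively remove the most heterogeneous category until homogeneous.

    At each step the G-test of independence is run on the current table; if
    p < alpha, the category whose two cells contribute most (largest
    absolute summed G terms) is removed, margins are recomputed and the test
    repeated, stopping when the remaining table is homogeneous (p >= alpha)
    or a single category remains.  Removed categories are the ones flagged
    as significantly different between the groups.
    """
    if table.k < 2:
        raise ValueError("backward elimination requires k >= 2 categories")
    counts = table.counts.copy()
    labels = list(table.category_labels)
    steps: list[EliminationStep] = []
    final: TestResult | None = None
    while counts.shape[1] >= 2:
        current = ContingencyTable2xK(counts, table.group_labels, labels)
        res = g_test(current, williams=williams)
        if res.p_value >= alpha:
            final = res
            break
        row = counts.sum(axis=1, dtype=float)
        col = counts.sum(axis=0, dtype=float)
        expected = np.outer(row, col) / counts.sum(dtype=float)
        per_cat = np.abs(_g_terms(counts, expected).sum(axis=0))
        worst = int(np.argmax(per_cat))  # first index wins ties
        steps.append(
            EliminationStep(
                removed_category=labels[worst],
                g_before=res.value,
                p_before=res.p_value,
                contributions=dict(zip(labels, per_cat.tolist())),
            )
        )
        log.debug("eliminating %s (G=%.4f, p=%.3g)", labels[worst], res.value, res.p_value)
        counts = np.delete(counts, worst, axis=1)
        del labels[worst]
    flagged = [s.removed_category for s in steps]
    return EliminationTrace(steps=steps, final=final, flagged=flagged, retained=labels)


def replicated_g_decomposition(
    replicate_counts: np.ndarray,
    expected_proportions: Sequence[float] | None = None,
) -> dict:
    """Partition replicated goodness-of-fit G into pooled and heterogeneity
    components.

    ``replicate_counts`` is an m x k matrix, one row of category counts per
    replicate, tested against a common hypothesis of category proportions
    (``expected_proportions``; pooled proportions if omitted).  The identity

        sum of individual G  =  pooled G  +  heterogeneity G

    holds exactly, with the heterogeneity term equal to the G-test of
    independence of the stacked m x k table.  Both routes (subtraction and
    the direct independence G) are returned for cross-checking.
    """
    obs = np.asarray(replicate_counts, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an m x k matrix with m, k >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate margins")
    if expected_proportions is None:
        p = col / n
    else:
        p = np.asarray(expected_proportions, dtype=float)
        if p.shape != (obs.shape[1],) or (p <= 0).any():
            raise ValueError("expected_proportions must be k positive values")
        p = p / p.sum()

    g_individual = np.array(
        [_g_terms(obs[i], row[i] * p).sum() for i in range(obs.shape[0])]
    )
    g_pooled = float(_g_terms(col, n * p).sum())
    g_het_direct = float(_g_terms(obs, np.outer(row, col) / n).sum())
    m, k = obs.shape
    return {
        "g_individual": g_individual,
        "g_total": float(g_individual.sum()),
        "g_pooled": g_pooled,
        "g_heterogeneity": float(g_individual.sum()) - g_pooled,
        "g_heterogeneity_direct": g_het_direct,
        "df_total": m * (k - 1),
        "df_pooled": k - 1,
        "df_heterogeneity": (m - 1) * (k - 1),
    }
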