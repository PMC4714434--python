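"""Chi-square, G-tests, backward elimination and the replicated-G identity."""

import numpy as np
import pytest
from scipy import stats

from halfsibkit import (
    ContingencyTable2xK,
    backward_elimination_g,
    chi_square_2x2,
    g_test,
    overlap_2x2,
    replicated_g_decomposition,
    shared_contigs,
)

from oracles import g_statistic_oracle, pearson_2x2_closed_form


class TestSharedContigs:
    def test_disjoint_lists_share_nothing(self):
        assert shared_contigs(["a", "b"], ["c"]) == (0, [])

    def test_intersection_is_sorted_and_deduplicated(self):
        n, ids = shared_contigs(["c3", "c1", "c2", "c2"], ["c2", "c3", "c4"])
        assert (n, ids) == (2, ["c2", "c3"])

    def test_self_intersection_is_the_deduplicated_size(self):
        n, ids = shared_contigs(["x", "x", "y"], ["y", "x"])
        assert n == 2 and ids == ["x", "y"]


class TestOverlapChiSquare:
    def test_study_overlap_counts_assemble_correctly(self):
        table = overlap_2x2(432, 68, 60, 562)
        assert table.counts.tolist() == [[432, 68], [60, 562]]
        assert table.total == 1122

    def test_shared_contig_overlap_reproduces_printed_statistic(self):
        """Shared-contig counts 432/68/60/562 give the uncorrected Pearson
        chi-square 663.2 on 1 df, p < 0.001."""
        res = chi_square_2x2(overlap_2x2(432, 68, 60, 562))
        assert res.value == pytest.approx(663.2, abs=0.05)
        assert res.df == 1
        assert res.p_value < 0.001

    def test_agrees_with_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 500, size=4)
            res = chi_square_2x2(overlap_2x2(a, b, c, d))
            assert res.value == pytest.approx(pearson_2x2_closed_form(a, b, c, d), rel=1e-12)

    def test_proportional_rows_give_zero(self):
        assert chi_square_2x2(ContingencyTable2xK([[30, 60], [10, 20]])).value == pytest.approx(0.0)

    def test_diagonal_table_closed_form(self):
        assert chi_square_2x2(ContingencyTable2xK([[10, 0], [0, 10]])).value == pytest.approx(20.0)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(ContingencyTable2xK([[0, 0], [5, 5]]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            overlap_2x2(-1, 2, 3, 4)

    def test_row_and_column_swap_invariance(self):
        r1 = chi_square_2x2(ContingencyTable2xK([[11, 7], [3, 29]]))
        r2 = chi_square_2x2(ContingencyTable2xK([[29, 3], [7, 11]]))
        assert r1.value == pytest.approx(r2.value, rel=1e-12)


class TestGTest:
    def test_proportional_table_gives_zero(self):
        res = g_test(ContingencyTable2xK([[10, 20, 30], [20, 40, 60]]))
        assert res.value == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_symmetric_table(self):
        # expecteds all 15; G = 2*sum o ln(o/e) = 6.796
        res = g_test(ContingencyTable2xK([[10, 20], [20, 10]]))
        assert res.value == pytest.approx(6.796, abs=0.001)
        assert res.df == 1

    def test_agrees_with_cellwise_oracle_and_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(1, 200, size=(2, 4))
            res = g_test(ContingencyTable2xK(counts))
            assert res.value == pytest.approx(g_statistic_oracle(counts), rel=1e-12)
            g_scipy = stats.chi2_contingency(counts, correction=False, lambda_="log-likelihood")[0]
            assert res.value == pytest.approx(g_scipy, rel=1e-10)

    def test_g_close_to_pearson_for_large_cells(self):
        """Asymptotic equivalence: with all cells >= 50 and sampling-level
        deviations from homogeneity, G tracks Pearson chi-square within 5%."""
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 20:
            p = rng.dirichlet([5.0, 5.0])
            counts = rng.multinomial(2000, p, size=2)
            if counts.min() < 50:
                continue
            checked += 1
            g = g_test(ContingencyTable2xK(counts)).value
            chi2 = stats.chi2_contingency(counts, correction=False)[0]
            if chi2 > 1e-3:
                assert g == pytest.approx(chi2, rel=0.05)

    def test_williams_correction_shrinks_g(self):
        table = ContingencyTable2xK([[5, 9, 2], [8, 1, 7]])
        plain = g_test(table)
        corrected = g_test(table, williams=True)
        assert corrected.correction == "WILLIAMS"
        assert 0 < corrected.value < plain.value

    def test_zero_cells_allowed_but_empty_categories_dropped(self):
        res = g_test(ContingencyTable2xK([[5, 0, 3], [2, 4, 3]]))
        assert np.isfinite(res.value)
        with pytest.warns(UserWarning, match="all-zero"):
            res2 = g_test(ContingencyTable2xK([[5, 0, 3], [2, 0, 3]]))
        assert res2.df == 1

    def test_group_and_category_permutation_invariance(self):
        counts = np.array([[12, 5, 31], [7, 19, 2]])
        base = g_test(ContingencyTable2xK(counts)).value
        flipped = g_test(ContingencyTable2xK(counts[::-1, ::-1])).value
        assert base == pytest.approx(flipped, rel=1e-12)


class TestReplicatedGDecomposition:
    def test_additivity_identity_holds_exactly(self):
        """Sum of individual goodness-of-fit Gs equals pooled G plus the
        heterogeneity (independence) G, to 1e-9 relative."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            m, k = rng.integers(2, 6, size=2)
            counts = rng.integers(1, 100, size=(m, k))
            p = rng.dirichlet(np.ones(k))
            out = replicated_g_decomposition(counts, p)
            assert out["g_total"] == pytest.approx(
                out["g_pooled"] + out["g_heterogeneity_direct"], rel=1e-9
            )
            assert out["g_heterogeneity"] == pytest.approx(out["g_heterogeneity_direct"], rel=1e-9)
            assert out["df_total"] == out["df_pooled"] + out["df_heterogeneity"]

    def test_pooled_proportions_put_all_g_in_heterogeneity(self):
        counts = [[10, 20, 5], [30, 10, 25]]
        out = replicated_g_decomposition(counts)
        assert out["g_pooled"] == pytest.approx(0.0, abs=1e-12)
        assert out["g_total"] == pytest.approx(out["g_heterogeneity_direct"], rel=1e-12)


class TestBackwardElimination:
    def test_homogeneous_table_flags_nothing(self):
        trace = backward_elimination_g(ContingencyTable2xK([[10, 20, 30], [20, 40, 60]]))
        assert trace.flagged == [] and trace.steps == []
        assert trace.final is not None and trace.final.p_value >= 0.05

    def test_single_planted_discrepant_category_is_flagged(self):
        """One category with a 3x excess in group 2 among homogeneous
        categories: exactly that category is removed and the remainder
        is homogeneous."""
        table = ContingencyTable2xK(
            [[100, 100, 100], [100, 100, 300]], category_labels=["a", "b", "c"]
        )
        trace = backward_elimination_g(table)
        assert trace.flagged == ["c"]
        assert trace.retained == ["a", "b"]
        assert trace.final.p_value >= 0.05

    def test_planted_removal_matches_single_removal_oracle(self):
        """On a table with one planted discrepant category, the category the
        elimination removes is also the one whose removal leaves the smallest
        residual G among all single-category removals (exhaustive check)."""
        counts = np.array([[80, 120, 100, 95], [85, 115, 105, 310]])
        labels = ["w", "x", "y", "z"]
        trace = backward_elimination_g(ContingencyTable2xK(counts, category_labels=labels))
        residuals = {
            labels[j]: g_test(ContingencyTable2xK(np.delete(counts, j, axis=1))).value
            for j in range(counts.shape[1])
        }
        assert trace.steps[0].removed_category == min(residuals, key=residuals.get) == "z"

    def test_trace_g_values_strictly_decrease(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.integers(1, 150, size=(2, 6))
            trace = backward_elimination_g(ContingencyTable2xK(counts), alpha=0.99)
            gs = [s.g_before for s in trace.steps]
            assert all(g1 > g2 for g1, g2 in zip(gs, gs[1:]))

    def test_single_category_input_rejected(self):
        with pytest.raises(ValueError):
            backward_elimination_g(ContingencyTable2xK([[5], [6]]))
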