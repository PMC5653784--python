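"""Time/class vector selection, BH adjustment, gene and compound scoring."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from tdfe import (
    benjamini_hochberg,
    gene_pvalues,
    select_class_vectors,
    select_compounds,
    select_time_vector,
)
from tdfe.hosvd import HOSVDFactors


def factors_from_rows(rows, n_cols=None):
    """Wrap raw row vectors as a single-mode factor matrix (not orthonormal;
    the selection statistics only read the rows)."""
    u = np.atleast_2d(np.asarray(rows, dtype=float))
    return HOSVDFactors([u], [np.ones(u.shape[0])], (u.shape[1],))


class TestSelectTimeVector:
    days = [0.25, 1.0, 3.0, 5.0]

    def test_vector_proportional_to_days_has_r_one(self):
        u = np.asarray(self.days) / np.linalg.norm(self.days)
        f = factors_from_rows([u, [1, -1, 1, -1]])
        sel = select_time_vector(f, 0, self.days)
        assert sel.correlations[0] == pytest.approx(1.0)
        assert sel.chosen == 1

    def test_constant_vector_flagged_not_nan(self):
        f = factors_from_rows([[0.5, 0.5, 0.5, 0.5], [1, 2, 3, 4]])
        sel = select_time_vector(f, 0, self.days)
        assert sel.correlations[0] == 0.0
        assert sel.degenerate[0]
        assert not np.isnan(sel.correlations).any()

    def test_alternating_vector_matches_hand_pearson(self):
        u = np.array([1.0, -1.0, 1.0, -1.0])
        t = np.asarray(self.days)
        r_hand = (((u - u.mean()) * (t - t.mean())).sum()
                  / np.sqrt(((u - u.mean()) ** 2).sum() * ((t - t.mean()) ** 2).sum()))
        sel = select_time_vector(factors_from_rows([u]), 0, self.days)
        assert sel.correlations[0] == pytest.approx(r_hand, rel=1e-12)

    def test_override_pins_the_choice(self):
        f = factors_from_rows([[1, 2, 3, 4], [4, 3, 2, 1]])
        sel = select_time_vector(f, 0, self.days, override=2)
        assert sel.chosen == 2


class TestSelectClassVectors:
    def test_two_group_anova_matches_hand_computation(self):
        # groups (1,2,3) vs (4,5,6): SSB = 13.5, SSW = 4, F = 13.5 on (1, 4) df
        f = factors_from_rows([[1, 2, 3, 4, 5, 6]])
        labels = ["a"] * 3 + ["b"] * 3
        sel = select_class_vectors(f, 0, labels)
        p_hand = sp_stats.f.sf(13.5, 1, 4)
        assert sel.p_values[0] == pytest.approx(p_hand, rel=1e-10)
        assert sel.p_values[0] == pytest.approx(0.0213, abs=2e-4)

    def test_identical_groups_give_f_zero_p_one(self):
        f = factors_from_rows([[1, 2, 3, 1, 2, 3]])
        sel = select_class_vectors(f, 0, ["a"] * 3 + ["b"] * 3)
        assert sel.p_values[0] == pytest.approx(1.0)

    def test_small_class_rejected(self):
        f = factors_from_rows([[1, 2, 3]])
        with pytest.raises(ValueError, match="fewer than two"):
            select_class_vectors(f, 0, ["a", "a", "b"])

    def test_planted_effect_vectors_recovered_among_many(self, rng):
        # 202 spherically random vectors; 5 of them get a strong class shift
        n, n_vec = 40, 202
        labels = ["a"] * 20 + ["b"] * 20
        u = rng.normal(size=(n_vec, n))
        planted = [3, 57, 100, 150, 201]
        shift = np.r_[np.zeros(20), np.ones(20)]
        for l in planted:
            u[l] = 0.1 * rng.normal(size=n) + shift
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        sel = select_class_vectors(factors_from_rows(u), 0, labels, threshold=0.05)
        assert sel.chosen == sorted(l + 1 for l in planted)

    def test_adjusted_never_below_raw(self, rng):
        u = rng.normal(size=(30, 24))
        sel = select_class_vectors(factors_from_rows(u), 0,
                                   ["a"] * 12 + ["b"] * 12)
        assert (sel.adjusted >= sel.p_values - 1e-15).all()


class TestBenjaminiHochberg:
    def test_hand_computed_step_up_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_equal_inputs_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2] * 5), [0.2] * 5)

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.7]), [0.7])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_matches_statsmodels_and_permutation_invariant(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        mine = benjamini_hochberg(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(mine, theirs, rtol=1e-12)
        perm = rng.permutation(200)
        np.testing.assert_allclose(benjamini_hochberg(p[perm]), mine[perm])
        assert (mine >= p - 1e-15).all()


class TestGenePvalues:
    def test_chi2_df2_closed_form(self):
        # rows with unit sd make every u/sigma = +-1: score 2, P = exp(-1)
        row = [1.0, -1.0, 1.0, -1.0]
        sel = gene_pvalues(factors_from_rows([row, row]), 0, [1, 2])
        np.testing.assert_allclose(sel.scores, 2.0)
        np.testing.assert_allclose(sel.p_values, np.exp(-1.0), rtol=1e-10)

    def test_chi2_df1_matches_normal_two_sided_tail(self, rng):
        # with one vector the tail P equals the two-sided normal tail of
        # u/sigma; a gene planted at 1.96 sd lands at P ~ 0.05
        row = rng.normal(size=5000)
        row[0] = 1.96 * row[1:].std()
        sel = gene_pvalues(factors_from_rows([row]), 0, [1])
        z = row / row.std()
        np.testing.assert_allclose(
            sel.p_values, 2 * sp_stats.norm.sf(np.abs(z)), rtol=1e-10
        )
        assert sel.p_values[0] == pytest.approx(0.05, abs=2e-3)

    def test_zero_loading_gives_p_one_never_selected(self, rng):
        u = rng.normal(size=(1, 50))
        u[0, 7] = 0.0
        sel = gene_pvalues(factors_from_rows(u), 0, [1])
        assert sel.scores[7] == 0.0
        assert sel.p_values[7] == 1.0
        assert not sel.selected[7]

    def test_monotone_in_loading_magnitude(self, rng):
        u = rng.normal(size=(1, 100))
        sel = gene_pvalues(factors_from_rows(u), 0, [1])
        order = np.argsort(np.abs(u[0]))
        assert (np.diff(sel.p_values[order]) <= 1e-12).all()

    def test_zero_sigma_rejected(self):
        f = factors_from_rows([np.zeros(10)])
        with pytest.raises(ValueError, match="zero standard deviation"):
            gene_pvalues(f, 0, [1])


class TestSelectCompounds:
    def test_gap_method_dominant_split(self):
        f = factors_from_rows([[0.9, 0.85, 0.02, 0.01, 0.015]])
        sel = select_compounds(f, 0, [1], method="gap")
        assert list(np.flatnonzero(sel.selected)) == [0, 1]

    def test_all_equal_scores_empty_with_flag(self):
        f = factors_from_rows([[0.3, 0.3, 0.3, 0.3]])
        sel = select_compounds(f, 0, [1])
        assert not sel.selected.any()
        assert sel.degenerate

    def test_zscore_recovers_planted_outliers(self, rng):
        scores = rng.normal(size=205)
        planted = [11, 60, 123, 180, 200]
        for j, sign in zip(planted, [1, -1, 1, -1, 1]):
            scores[j] = sign * 6.0
        sel = select_compounds(factors_from_rows([scores]), 0, [1], method="zscore")
        assert sorted(np.flatnonzero(sel.selected)) == planted

    def test_method_and_params_recorded(self):
        f = factors_from_rows([[0.9, 0.1, 0.1, 0.1, 0.1]])
        sel = select_compounds(f, 0, [1], method="gap")
        assert sel.method == "gap"
        assert "max_fraction" in sel.params
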