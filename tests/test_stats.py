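"""Overlap tables, exact tests, enrichment, and affinity conversion."""

import math

import numpy as np
import pytest
from scipy import stats as sp_stats

from tdfe import (
    AffinityParams,
    ContingencyTable2x2,
    GeneSetLibrary,
    chi_square_2x2,
    delta_g_to_ki,
    evaluate_overlap,
    fisher_exact,
    format_ki,
    gene_set_enrichment,
    overlap_table,
    read_gmt,
    target_overlap_report,
)


def enumerate_two_sided_p(table: ContingencyTable2x2) -> float:
    """Oracle: sum hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed one."""
    r1, r2, c1, _ = table.margins
    n = table.total
    a_min, a_max = max(0, r1 - (n - c1)), min(r1, c1)
    a_vals = np.arange(a_min, a_max + 1)
    pmf = sp_stats.hypergeom.pmf(a_vals, n, r1, c1)
    observed = pmf[table.a - a_min]
    return float(pmf[pmf <= observed * (1 + 1e-7)].sum())


class TestOverlapTable:
    def test_full_overlap(self):
        universe = [f"G{i}" for i in range(10)]
        t = overlap_table(universe, universe, universe)
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 10)

    def test_disjoint_sets_covering_universe(self):
        universe = ["A", "B", "C", "D"]
        t = overlap_table(["A", "B"], ["C", "D"], universe)
        assert t.d == 0
        assert (t.a, t.b, t.c) == (0, 2, 2)

    def test_random_sets_match_membership_scan(self, rng):
        universe = [f"G{i}" for i in range(200)]
        pred = set(rng.choice(universe, 40, replace=False))
        ref = set(rng.choice(universe, 60, replace=False))
        t = overlap_table(pred, ref, universe)
        a = b = c = d = 0
        for g in universe:
            if g in pred and g in ref:
                d += 1
            elif g in pred:
                b += 1
            elif g in ref:
                c += 1
            else:
                a += 1
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)

    def test_element_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            overlap_table(["X"], ["A"], ["A", "B"])


class TestFisherExact:
    def test_heart_failure_up_odds_ratio(self):
        res = fisher_exact(ContingencyTable2x2(521, 517, 13, 39))
        assert math.floor(res.or_mle * 100) / 100 == 3.02
        assert res.fisher_p == pytest.approx(3.4e-4, rel=0.1)

    def test_diabetes_down_odds_ratio(self):
        res = fisher_exact(ContingencyTable2x2(936, 130, 14, 10))
        assert math.floor(res.or_mle * 100) / 100 == 5.13

    def test_balanced_table_no_association(self):
        res = fisher_exact(ContingencyTable2x2(10, 10, 10, 10))
        assert res.or_mle == pytest.approx(1.0)
        assert res.fisher_p == pytest.approx(1.0)

    def test_two_sided_p_matches_enumeration_sample(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 8, size=4)
            if counts.sum() == 0:
                continue
            t = ContingencyTable2x2(*counts)
            if 0 in t.margins:
                continue
            assert fisher_exact(t).fisher_p == pytest.approx(
                enumerate_two_sided_p(t), rel=1e-10
            )

    def test_zero_margin_flagged(self):
        res = fisher_exact(ContingencyTable2x2(5, 0, 7, 0))
        assert res.fisher_p == 1.0
        assert not res.or_defined
        assert math.isnan(res.or_mle)

    def test_conditional_mle_shrinks_toward_one(self, rng):
        for _ in range(30):
            t = ContingencyTable2x2(*(rng.integers(1, 40, size=4)))
            res = fisher_exact(t)
            if res.or_sample > 1 and math.isfinite(res.or_sample):
                assert 1.0 <= res.or_mle <= res.or_sample + 1e-9


class TestChiSquare:
    def test_balanced_table_zero_statistic(self):
        res = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # 60 * (400 - 100)^2 / 30^4 = 20/3
        res = chi_square_2x2(ContingencyTable2x2(20, 10, 10, 20))
        assert res.statistic == pytest.approx(20 / 3, rel=1e-12)
        assert res.pvalue == pytest.approx(sp_stats.chi2.sf(20 / 3, 1), rel=1e-12)

    def test_uncorrected_at_least_yates(self, rng):
        for _ in range(20):
            t = ContingencyTable2x2(*(rng.integers(1, 30, size=4)))
            plain = chi_square_2x2(t).statistic
            yates = chi_square_2x2(t, correction=True).statistic
            assert plain >= yates - 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            chi_square_2x2(ContingencyTable2x2(5, 0, 7, 0))

    def test_matches_scipy_uncorrected(self, rng):
        t = ContingencyTable2x2(*(rng.integers(5, 50, size=4)))
        chi2, p, _, _ = sp_stats.chi2_contingency(t.as_array(), correction=False)
        res = chi_square_2x2(t)
        assert res.statistic == pytest.approx(chi2, rel=1e-12)
        assert res.pvalue == pytest.approx(p, rel=1e-12)


class TestAffinityConversion:
    def test_bezafibrate_hnf4a(self):
        assert format_ki(delta_g_to_ki(9.44)) == "0.13 uM"

    def test_morphine_hnf4a(self):
        assert format_ki(delta_g_to_ki(8.08)) == "1.3 uM"

    def test_zero_energy_gives_one_molar(self):
        assert delta_g_to_ki(0.0) == 1.0

    def test_strictly_decreasing_and_multiplicative(self):
        g1, g2 = 3.7, 5.2
        k1, k2 = delta_g_to_ki(g1), delta_g_to_ki(g2)
        assert k1 > k2
        assert delta_g_to_ki(g1 + g2) == pytest.approx(k1 * k2, rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AffinityParams(T=-1.0)
        with pytest.raises(ValueError):
            delta_g_to_ki(-2.0)


class TestEnrichment:
    def library(self, rng, universe, n_sets=20, size=25):
        sets = {
            f"SET_{k}": list(rng.choice(universe, size, replace=False))
            for k in range(n_sets)
        }
        return GeneSetLibrary(sets)

    def test_identical_set_ranked_first(self, rng):
        universe = [f"G{i}" for i in range(500)]
        lib = self.library(rng, universe)
        target = lib.sets["SET_7"]
        table = gene_set_enrichment(target, lib, universe)
        best = table.sort_values("p_value").iloc[0]
        assert best["set"] == "SET_7"
        assert best["overlap"] == len(target)
        assert best["selected"]

    def test_zero_overlap_gives_p_one(self):
        universe = [f"G{i}" for i in range(100)]
        lib = GeneSetLibrary({"S": universe[:10]})
        table = gene_set_enrichment(universe[50:60], lib, universe)
        assert table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_empty_selection_all_p_one(self, rng):
        universe = [f"G{i}" for i in range(100)]
        lib = self.library(rng, universe, n_sets=5, size=10)
        table = gene_set_enrichment([], lib, universe)
        assert (table["p_value"] == 1.0).all()
        assert not table["selected"].any()

    def test_permutation_invariance_in_gene_labels(self, rng):
        universe = [f"G{i}" for i in range(300)]
        lib = self.library(rng, universe, n_sets=10)
        selected = list(rng.choice(universe, 40, replace=False))
        perm = {g: p for g, p in zip(universe, rng.permutation(universe))}
        lib2 = GeneSetLibrary({k: [perm[g] for g in v] for k, v in lib.sets.items()})
        t1 = gene_set_enrichment(selected, lib, universe)
        t2 = gene_set_enrichment([perm[g] for g in selected], lib2, universe)
        np.testing.assert_allclose(t1["p_value"], t2["p_value"])

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "lib.gmt"
        path.write_text("SET_A\tdesc\tTp53\tBRCA1\nSET_B\tdesc\tEGFR\n")
        lib = read_gmt(path)
        assert lib.sets == {"SET_A": ["BRCA1", "TP53"], "SET_B": ["EGFR"]}


class TestTargetOverlapReport:
    def test_single_compound_perfect_prediction(self):
        universe = [f"G{i}" for i in range(20)]
        targets = universe[:5]
        rep = target_overlap_report({"drugA": targets}, {"drugA": targets}, universe)
        assert rep.table.d == 5

    def test_multi_targeting_counts(self):
        universe = ["G1", "G2", "G3"]
        rep = target_overlap_report(
            {"a": ["G1"], "b": ["G2"]},
            {"a": ["G1", "G3"], "b": ["G2", "G3"]},
            universe,
        )
        assert rep.multi_targeting["G3"] == 2
        assert rep.multi_targeting["G1"] == 1

    def test_pooled_counts_match_brute_force(self, rng):
        universe = [f"G{i}" for i in range(100)]
        predicted = {
            f"c{k}": list(rng.choice(universe, 15, replace=False)) for k in range(4)
        }
        reference = {
            f"c{k}": list(rng.choice(universe, 10, replace=False)) for k in range(4)
        }
        rep = target_overlap_report(predicted, reference, universe)
        pool_p = set().union(*predicted.values())
        pool_r = set().union(*reference.values())
        d = len(pool_p & pool_r)
        b = len(pool_p - pool_r)
        c = len(pool_r - pool_p)
        assert (rep.table.a, rep.table.b, rep.table.c, rep.table.d) == (
            100 - b - c - d, b, c, d,
        )
        assert rep.result.fisher_p == evaluate_overlap(rep.table).fisher_p
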