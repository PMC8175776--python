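"""Statistical inference: exact Wilcoxon, Kruskal-Wallis, Type III ANOVA,
Benjamini-Hochberg FDR, and FDR-corrected pairwise comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fxephys import (CohortDesign, anova_two_way, exact_wilcoxon_ranksum,
                     fdr_adjust, kruskal_wallis, pairwise_group_comparisons,
                     simulate_cohort)
from fxephys.io import GENOTYPES, TREATMENTS

from conftest import brute_force_wilcoxon_p


class TestExactWilcoxon:
    def test_textbook_enumeration(self):
        """{1,2} vs {3,4}: 2 of the 6 equally likely assignments are as
        extreme as observed, so the exact two-sided p is 1/3."""
        r = exact_wilcoxon_ranksum([1, 2], [3, 4])
        assert r.mode == "exact"
        assert r.p_raw == pytest.approx(1 / 3)

    def test_complete_ties(self):
        r = exact_wilcoxon_ranksum([5, 5, 5], [5, 5, 5])
        assert r.p_raw == 1.0

    def test_label_swap_symmetry(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, size=6).astype(float)
            y = rng.integers(0, 5, size=9).astype(float)
            a = exact_wilcoxon_ranksum(x, y).p_raw
            b = exact_wilcoxon_ranksum(y, x).p_raw
            assert a == pytest.approx(b, abs=1e-12)

    def test_matches_brute_force(self, rng):
        """Enumeration-mode p equals a literal loop over all assignments on
        random problems (with heavy ties) up to C(n+m, n) = 10^4."""
        import math
        checked = 0
        while checked < 30:
            n = int(rng.integers(2, 7))
            m = int(rng.integers(2, 7))
            if math.comb(n + m, n) > 10_000:
                continue
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=m).astype(float)
            got = exact_wilcoxon_ranksum(x, y).p_raw
            ref = brute_force_wilcoxon_p(x, y)
            assert got == pytest.approx(ref, abs=1e-12)
            checked += 1

    def test_monte_carlo_converges_to_exact(self):
        x = [1.0, 4.0, 2.0, 6.0, 3.0]
        y = [5.0, 7.0, 8.0, 2.0, 9.0, 10.0]
        exact = exact_wilcoxon_ranksum(x, y, mode="exact").p_raw
        mc = exact_wilcoxon_ranksum(x, y, mode="mc", seed=1,
                                    n_draws=100_000)
        se = np.sqrt(exact * (1 - exact) / mc.n_draws)
        assert abs(mc.p_raw - exact) <= 3 * se + 1 / mc.n_draws

    def test_mode_errors(self):
        with pytest.raises(ValueError, match="empty"):
            exact_wilcoxon_ranksum([], [1.0])
        with pytest.raises(ValueError, match="enumeration limit"):
            exact_wilcoxon_ranksum(np.arange(30), np.arange(30), mode="exact")


class TestKruskalWallis:
    def test_identical_groups(self):
        r = kruskal_wallis([[3, 3], [3, 3], [3, 3]])
        assert r.statistic == 0.0
        assert r.p_raw == 1.0

    def test_matches_direct_formula(self):
        """{1,2,3} vs {4,5,6}: no ties, H from the textbook rank formula."""
        groups = [[1, 2, 3], [4, 5, 6]]
        ranks = sps.rankdata([1, 2, 3, 4, 5, 6])
        n_tot = 6
        r_sums = [ranks[:3].sum(), ranks[3:].sum()]
        h_ref = (12 / (n_tot * (n_tot + 1))
                 * sum(r ** 2 / 3 for r in r_sums) - 3 * (n_tot + 1))
        r = kruskal_wallis(groups)
        assert r.statistic == pytest.approx(h_ref)
        assert r.df[0] == 1

    def test_shifted_group_power(self):
        """Six seizure-score groups, one shifted: KW rejects at 0.05 in
        >= 90% of 200 replicates."""
        groups_keys = [(g, t) for g in GENOTYPES for t in TREATMENTS]
        rejections = 0
        for seed in range(200):
            d = CohortDesign(
                n={k: 12 for k in groups_keys},
                seizure_score_probs={
                    k: ([0, 0, 0.2, 0.6, 0.2] if k == ("KO", "VEH")
                        else [0.9, 0.1, 0, 0, 0]) for k in groups_keys},
                seed=seed)
            data = simulate_cohort(d)
            sc = data[data.measure == "seizure_score"]
            groups = [g["value"].to_numpy() for _, g in
                      sc.groupby(["genotype", "treatment"], sort=True)]
            rejections += kruskal_wallis(groups).p_raw < 0.05
        assert rejections / 200 >= 0.9

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


def _frame(cells):
    """cells: {(geno, treat): values}."""
    rows = []
    for (g, t), values in cells.items():
        for v in values:
            rows.append({"genotype": g, "treatment": t, "value": float(v)})
    return pd.DataFrame(rows)


class TestAnovaTwoWay:
    def test_null_case_zero_f(self):
        """Identical values in every cell: all effect SS are exactly 0."""
        cells = {(g, t): [1.0, 2.0, 3.0]
                 for g in GENOTYPES for t in ("VEH", "1BAER")}
        for r in anova_two_way(_frame(cells)):
            assert r.statistic == pytest.approx(0.0, abs=1e-10)
            assert r.p_raw == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_balanced_table(self):
        """Balanced 2x2, n=3/cell, cell means (2, 5 / 4, 9), each cell
        mean +/- 1.  Hand computation: SS_A = 27, SS_B = 48, SS_AB = 3,
        SS_err = 8 on 8 df, so F = (27, 48, 3) on (1, 8) df."""
        cells = {("WT", "VEH"): [1, 2, 3], ("WT", "1BAER"): [4, 5, 6],
                 ("KO", "VEH"): [3, 4, 5], ("KO", "1BAER"): [8, 9, 10]}
        res = {r.comparison: r for r in anova_two_way(_frame(cells))}
        assert res["genotype"].statistic == pytest.approx(27.0)
        assert res["treatment"].statistic == pytest.approx(48.0)
        assert res["genotype:treatment"].statistic == pytest.approx(3.0)
        for r in res.values():
            assert r.df == (1.0, 8.0)
            assert r.p_raw == pytest.approx(
                1 - sps.f.cdf(r.statistic, 1, 8), rel=1e-9)

    def test_interaction_p_uniform_under_null(self):
        """Additive truth: the interaction p-value is uniform over 500
        seeded replicates (KS sanity bound at the 0.1% level)."""
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(500):
            cells = {}
            for gi, g in enumerate(GENOTYPES):
                for ti, t in enumerate(("VEH", "1BAER")):
                    mean = 1.0 * gi + 2.0 * ti  # additive, no interaction
                    cells[(g, t)] = mean + rng.standard_normal(8)
            res = {r.comparison: r for r in anova_two_way(_frame(cells))}
            pvals.append(res["genotype:treatment"].p_raw)
        d, _ = sps.kstest(pvals, "uniform")
        assert d < 1.95 / np.sqrt(500)  # alpha ~ 0.001 critical value

    def test_unbalanced_type_iii(self):
        """Type III F-statistics are finite and sane on unbalanced cells."""
        cells = {("WT", "VEH"): [1, 2, 3, 4, 5], ("WT", "1BAER"): [4, 5],
                 ("KO", "VEH"): [3, 4, 5, 6], ("KO", "1BAER"): [9, 10, 11]}
        res = anova_two_way(_frame(cells))
        assert len(res) == 3
        for r in res:
            assert np.isfinite(r.statistic)
            assert 0 <= r.p_raw <= 1

    def test_empty_cell_drops_to_one_way(self):
        cells = {("WT", "VEH"): [1, 2, 3], ("WT", "1BAER"): [4, 5, 6],
                 ("KO", "VEH"): [3, 4, 5]}
        with pytest.warns(UserWarning, match="empty cell"):
            res = anova_two_way(_frame(cells))
        assert len(res) == 1
        assert res[0].method == "anova_one_way"


class TestFdr:
    def test_step_up_worked_example(self):
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37]) == [pytest.approx(0.37)]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100)
    def test_adjusted_at_least_raw(self, pvals):
        adj = fdr_adjust(pvals)
        assert all(a >= p - 1e-12 for a, p in zip(adj, pvals))
        assert all(a <= 1.0 + 1e-12 for a in adj)


class TestPairwise:
    def _cohort(self, seed=0, n=10):
        keys = [(g, t) for g in GENOTYPES for t in TREATMENTS]
        d = CohortDesign(
            n={k: n for k in keys},
            seizure_score_probs={
                k: ([0, 0, 0.2, 0.6, 0.2] if k == ("KO", "VEH")
                    else [0.9, 0.1, 0, 0, 0]) for k in keys},
            seed=seed)
        return simulate_cohort(d)

    def test_six_groups_fifteen_rows(self):
        table = pairwise_group_comparisons(self._cohort(), "seizure_score")
        assert len(table) == 15
        assert set(table.columns) >= {"comparison", "p_raw", "p_adj"}
        assert (table["p_adj"] >= table["p_raw"] - 1e-12).all()
        assert table["p_adj"].is_monotonic_increasing

    def test_identical_groups_p_one(self):
        data = pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(8)],
            "genotype": ["WT"] * 4 + ["KO"] * 4,
            "treatment": ["VEH"] * 8,
            "measure": ["di"] * 8,
            "value": [1.0, 2.0, 3.0, 4.0] * 2,
        })
        table = pairwise_group_comparisons(data, "di")
        assert table["p_raw"].iloc[0] == 1.0
        assert table["p_adj"].iloc[0] == 1.0

    def test_absent_group_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            pairwise_group_comparisons(self._cohort(), "seizure_score",
                                       groups=[("WT", "VEH"), ("KO", "XXX")])

    def test_shifted_group_has_smallest_adjusted_ps(self):
        """Only KO-VEH shifted: its five comparisons carry the five
        smallest adjusted p's in >= 90% of 200 replicates."""
        hits = 0
        for seed in range(200):
            table = pairwise_group_comparisons(self._cohort(seed=seed),
                                               "seizure_score", seed=seed)
            top5 = table.head(5)["comparison"]
            hits += all("KO/VEH" in c for c in top5)
        assert hits / 200 >= 0.9
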