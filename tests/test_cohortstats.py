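"""Nonparametric cohort statistics against hand and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ifnsig.cohortstats import (
    ConstantInputError,
    anova_power,
    classify_strength,
    correlation_table,
    dunn_posthoc,
    kruskal_wallis,
    normality_test,
    spearman,
)


# -- independent oracles -----------------------------------------------------

def kw_by_hand(groups):
    """Rank-sum formula with tie correction, written independently."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(t**3 - t) / (n**3 - n)
    return h / correction


def kw_exact_permutation_p(groups):
    """Exact permutation p-value of the tie-corrected H (tiny N only)."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    observed = kw_by_hand(groups)
    count, total = 0, 0
    for perm in itertools.permutations(range(len(pooled))):
        values = pooled[list(perm)]
        bounds = np.cumsum([0, *sizes])
        regrouped = [values[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        if kw_by_hand(regrouped) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


# -- normality ---------------------------------------------------------------

class TestNormality:
    def test_calibration_against_normal_and_lognormal(self):
        normal_ok, lognormal_rejected = 0, 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            if normality_test(rng.normal(size=200))[1] > 0.05:
                normal_ok += 1
            if normality_test(rng.lognormal(0, 1, size=200))[1] < 0.05:
                lognormal_rejected += 1
        assert normal_ok >= 90
        assert lognormal_rejected >= 99

    def test_preconditions(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])
        with pytest.raises(ConstantInputError):
            normality_test([3.0, 3.0, 3.0, 3.0])


# -- Kruskal-Wallis ----------------------------------------------------------

class TestKruskalWallis:
    def test_hand_computed_toy_statistic(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)  # rank sums 6 / 15 / 24, no ties
        assert df == 2
        assert p == pytest.approx(stats.chi2.sf(7.2, 2))

    def test_identical_groups_are_degenerate(self):
        h, df, p = kruskal_wallis([[5, 5, 5], [5, 5]])
        assert (h, p) == (0.0, 1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=8), rng.normal(1, 1, size=5), rng.normal(size=7)]
        h1, _, _ = kruskal_wallis(groups)
        h2, _, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_rank_sum_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 5, size=n).astype(float) for n in (6, 9, 7)]
        h, _, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kw_by_hand(groups), abs=1e-10)

    def test_chi_square_p_close_to_exact_permutation_p_at_tiny_n(self):
        groups = [np.array([1.0, 2.0, 5.0]), np.array([3.0, 7.0]), np.array([4.0, 6.0])]
        _, _, p_chi2 = kruskal_wallis(groups)
        p_exact = kw_exact_permutation_p(groups)
        # chi-square is an approximation at N = 7; the gap stays modest
        assert abs(p_chi2 - p_exact) < 0.1

    def test_preconditions(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


# -- Dunn post hoc -----------------------------------------------------------

class TestDunn:
    def test_hand_computed_toy_z(self):
        table = dunn_posthoc([[1, 2], [3, 4]])
        # mean ranks 1.5 vs 3.5; z = 2 / sqrt((20/12) * 1) = 1.549
        assert table.loc[0, "z"] == pytest.approx(-2 / math.sqrt(20 / 12))
        assert abs(table.loc[0, "z"]) == pytest.approx(1.5491933, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_group_z_squared_equals_h_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(size=9), rng.normal(0.5, 1, size=6)]
        h, _, _ = kruskal_wallis(groups)
        z = dunn_posthoc(groups).loc[0, "z"]
        assert z**2 == pytest.approx(h, abs=1e-9)

    def test_tie_correction_enters_the_standard_error(self):
        untied = dunn_posthoc([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        tied = dunn_posthoc([[1.0, 2.0, 2.0], [4.0, 5.0, 5.0]])
        assert abs(tied.loc[0, "z"]) > 0
        assert not np.isclose(untied.loc[0, "z"], tied.loc[0, "z"])

    @pytest.mark.parametrize("adjustment", ["bonferroni", "holm", "sidak"])
    def test_adjusted_p_values_are_monotone_and_bounded(self, adjustment):
        rng = np.random.default_rng(7)
        groups = [rng.normal(loc, 1, size=12) for loc in (0, 0.3, 0.9, 1.5)]
        table = dunn_posthoc(groups, adjustment=adjustment).sort_values("p_raw")
        assert (table["p_adj"].to_numpy() >= table["p_raw"].to_numpy() - 1e-15).all()
        assert (table["p_adj"] <= 1).all()
        assert table["p_adj"].is_monotonic_increasing

    def test_family_wise_error_rate_under_the_null(self):
        rejections = 0
        n_rep = 1000
        rng = np.random.default_rng(2024)
        for _ in range(n_rep):
            groups = rng.normal(size=(3, 50))
            table = dunn_posthoc(list(groups))
            if (table["p_adj"] < 0.05).any():
                rejections += 1
        # Bonferroni keeps FWER at or below nominal; allow binomial noise up
        assert rejections / n_rep <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_rep)

    def test_labels_and_unknown_adjustment(self):
        table = dunn_posthoc([[1, 2], [3, 4]], labels=["a", "b"])
        assert (table.loc[0, "group_1"], table.loc[0, "group_2"]) == ("a", "b")
        with pytest.raises(ValueError, match="adjustment"):
            dunn_posthoc([[1, 2], [3, 4]], adjustment="fdr")


# -- Spearman ----------------------------------------------------------------

class TestSpearman:
    def test_hand_computed_rank_correlation(self):
        res = spearman([1, 2, 3, 4, 5], [5, 6, 4, 8, 7])
        assert res.r == pytest.approx(0.6)  # y ranks 2, 3, 1, 5, 4
        assert res.n == 5

    def test_monotone_association_is_perfect_and_strong(self):
        res = spearman([1, 2, 3, 10, 100], [0.1, 0.5, 0.7, 2.0, 3.0])
        assert res.r == pytest.approx(1.0)
        assert res.strength == "strong"

    @pytest.mark.parametrize(
        "r, expected",
        [(0.2, "weak"), (0.4, "moderate"), (0.55, "strong"),
         (-0.6, "strong"), (0.3, "moderate"), (0.5, "moderate")],
    )
    def test_strength_classification(self, r, expected):
        assert classify_strength(r) == expected

    def test_invariance_and_antisymmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        base = spearman(x, y).r
        assert spearman(np.exp(x), y).r == pytest.approx(base, abs=1e-12)
        assert spearman(-x, y).r == pytest.approx(-base, abs=1e-12)

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, 3.0, np.nan, 5.0]
        y = [1.0, 2.0, np.nan, 4.0, 5.0]
        assert spearman(x, y).n == 3

    def test_errors(self):
        with pytest.raises(ConstantInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="3"):
            spearman([1, 2], [1, 2])


class TestCorrelationTable:
    def test_shape_and_planted_association(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        n = 70
        measures = pd.DataFrame(
            rng.lognormal(0, 1, size=(n, 10)), columns=[f"m{i}" for i in range(10)]
        )
        clinical = pd.DataFrame(rng.normal(size=(n, 3)), columns=["bvas", "crp", "creat"])
        # plant one strong monotone association
        clinical["bvas"] = np.log(measures["m0"]) + rng.normal(0, 0.4, size=n)
        table = correlation_table(measures, clinical)
        assert len(table) == 30
        planted = table[(table["measure"] == "m0") & (table["variable"] == "bvas")].iloc[0]
        assert planted["strong_and_significant"]
        assert planted["r"] > 0.5

    def test_independent_measures_show_no_strong_correlations(self):
        """Null sampling: SD(r) ~ 1/sqrt(n-1), so |r| stays well under 0.5."""
        import pandas as pd

        ok_strong, ok_median = 0, 0
        for rep in range(50):
            rng = np.random.default_rng(300 + rep)
            n = 70
            measures = pd.DataFrame(
                rng.lognormal(0, 1, size=(n, 10)), columns=[f"m{i}" for i in range(10)]
            )
            clinical = pd.DataFrame(
                rng.lognormal(0, 0.5, size=(n, 3)), columns=["bvas", "crp", "creat"]
            )
            table = correlation_table(measures, clinical)
            if (table["r"].abs() < 0.5).all():
                ok_strong += 1
            if table["r"].abs().median() < 0.15:
                ok_median += 1
        assert ok_strong >= 48
        assert ok_median >= 48


# -- ANOVA power -------------------------------------------------------------

class TestAnovaPower:
    def test_null_identity(self):
        spec = anova_power(k=3, n=20, deltas=(0.4, 0.4, 0.4))
        assert spec.noncentrality == 0.0
        assert spec.power == pytest.approx(0.05)

    def test_power_increases_with_sample_size(self):
        p1 = anova_power(k=4, n=20, deltas=(0, 0.25, 0.5, 0.75)).power
        p2 = anova_power(k=4, n=40, deltas=(0, 0.25, 0.5, 0.75)).power
        assert p2 > p1

    def test_noncentrality_formula(self):
        spec = anova_power(k=4, n=40, deltas=(0, 0.25, 0.5, 0.75))
        assert spec.noncentrality == pytest.approx(12.5)  # 40 * 0.3125
        alt = anova_power(k=4, n=40, deltas=(0, 0.25, 0.5, 0.75), convention="between-var")
        assert alt.noncentrality == pytest.approx(12.5 * 4 / 3)

    def test_delta_assignment_to_groups_is_irrelevant_when_balanced(self):
        a = anova_power(k=4, n=30, deltas=(0, 0.25, 0.5, 0.75)).power
        b = anova_power(k=4, n=30, deltas=(0, 0.75, 0.25, 0.5)).power
        assert a == pytest.approx(b, abs=1e-15)

    def test_two_group_power_equals_pooled_t_power(self):
        """F(1, nu) is t(nu) squared, so k = 2 must match the two-sample t."""
        d, n, alpha = 0.6, 25, 0.05
        spec = anova_power(k=2, n=n, deltas=(0.0, d), alpha=alpha)
        df = 2 * n - 2
        ncp = d * math.sqrt(n / 2)
        tcrit = stats.t.isf(alpha / 2, df)
        t_power = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
        assert spec.power == pytest.approx(t_power, abs=1e-6)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            anova_power(k=1, n=10, deltas=(0,))
        with pytest.raises(ValueError):
            anova_power(k=2, n=1, deltas=(0, 1))
        with pytest.raises(ValueError):
            anova_power(k=2, n=10, deltas=(0, 1), alpha=1.5)
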