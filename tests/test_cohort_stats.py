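"""Cohort statistics against from-scratch textbook oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import photom as ph
from photom.cohort_stats import (
    DegenerateStatisticError,
    collapse_group,
    fisher_exact_2x2,
    friedman_dunn,
    gg_epsilon,
    mixed_two_way_anova,
    paired_t,
    rm_anova_gg,
)

from conftest import make_binned

COLS = ["baseline", "injection", "day2", "day6", "day28"]


def random_matrix(rng, n=20, k=5, cols=None):
    return pd.DataFrame(rng.normal(size=(n, k)), columns=cols or COLS[:k])


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_rm_anova(matrix: pd.DataFrame):
    """One-way RM ANOVA by explicit sums of squares + definitional GG epsilon."""
    y = matrix.to_numpy()
    n, k = y.shape
    grand = y.mean()
    ss_cond = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_row = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_row
    ms_cond = ss_cond / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    F = ms_cond / ms_err
    S = np.cov(y, rowvar=False, ddof=1)
    C = np.eye(k) - np.ones((k, k)) / k
    Sc = C @ S @ C
    eps = np.trace(Sc) ** 2 / ((k - 1) * np.sum(Sc ** 2))
    return F, float(np.clip(eps, 1 / (k - 1), 1.0)), ms_err


def oracle_friedman(matrix: pd.DataFrame):
    """Friedman chi-square with midrank tie correction."""
    y = matrix.to_numpy()
    n, k = y.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, y)
    R = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(R ** 2) - 3 * n * (k + 1)
    ties = 0.0
    for row in y:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts ** 3 - counts)
    correction = 1.0 - ties / (n * k * (k ** 2 - 1))
    return chi2 / correction


def oracle_split_plot(a: np.ndarray, b: np.ndarray):
    """Mixed two-way (group between, condition within) by explicit SS."""
    y = np.stack([a, b])  # (2, n, k)
    g, n, k = y.shape
    grand = y.mean()
    group_means = y.mean(axis=(1, 2))
    cond_means = y.mean(axis=(0, 1))
    cell_means = y.mean(axis=1)  # (g, k)
    subj_means = y.mean(axis=2)  # (g, n)
    ss_group = n * k * np.sum((group_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - group_means[:, None]) ** 2)
    ss_cond = g * n * np.sum((cond_means - grand) ** 2)
    ss_int = n * np.sum(
        (cell_means - group_means[:, None] - cond_means[None, :] + grand) ** 2
    )
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_group - ss_subj - ss_cond - ss_int
    F_group = (ss_group / (g - 1)) / (ss_subj / (g * (n - 1)))
    df_w = (k - 1) * g * (n - 1)
    F_cond = (ss_cond / (k - 1)) / (ss_err / df_w)
    F_int = (ss_int / ((g - 1) * (k - 1))) / (ss_err / df_w)
    return F_group, F_cond, F_int


def oracle_fisher_two_sided(table):
    """Two-sided Fisher p by hypergeometric enumeration at fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: stats.hypergeom.pmf(x, n, r1, c1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


# ---------------------------------------------------------------------------
# collapse / matrix construction
# ---------------------------------------------------------------------------


class TestCollapse:
    def test_identical_subjects(self):
        t = np.r_[np.zeros(10), np.arange(20.0) - 9.5]
        t -= t[:10].mean()
        group = [make_binned(t, normalized=True) for _ in range(4)]
        np.testing.assert_array_equal(collapse_group(group), t[10:])

    def test_two_subjects_midpoint(self):
        a = np.zeros(30)
        b = np.r_[np.zeros(10), np.full(20, 2.0)]
        b = b - b[:10].mean()
        group = [make_binned(a, normalized=True), make_binned(b, normalized=True)]
        np.testing.assert_allclose(collapse_group(group), 1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        mats = rng.normal(size=(6, 30))
        mats -= mats[:, :10].mean(axis=1, keepdims=True)
        group = [make_binned(m, normalized=True) for m in mats]
        np.testing.assert_allclose(collapse_group(group),
                                   mats[:, 10:].mean(axis=0), atol=1e-12)


# ---------------------------------------------------------------------------
# RM-ANOVA + Dunnett
# ---------------------------------------------------------------------------


class TestRmAnova:
    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            m = random_matrix(rng)
            res = rm_anova_gg(m)
            F, eps, _ = oracle_rm_anova(m)
            assert res.F == pytest.approx(F, abs=1e-8)
            assert res.epsilon == pytest.approx(eps, abs=1e-8)
            assert res.df1 == pytest.approx(eps * 4, abs=1e-8)
            assert res.df2 == pytest.approx(eps * 4 * 19, abs=1e-8)

    def test_identical_columns_give_zero_F(self):
        col = np.random.default_rng(4).normal(size=20)
        m = pd.DataFrame({c: col for c in COLS})
        res = rm_anova_gg(m)
        assert res.F == 0.0
        assert all(c.p_adjusted > 0.99 for c in res.posthoc)

    def test_two_level_design_epsilon_is_one(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, k=2, cols=["baseline", "injection"])
        res = rm_anova_gg(m)
        assert res.epsilon == pytest.approx(1.0, abs=1e-10)

    def test_dunnett_single_comparison_equals_paired_t(self):
        """With k=2 the Dunnett family has one member: plain two-sided t."""
        rng = np.random.default_rng(6)
        m = random_matrix(rng, k=2, cols=["baseline", "injection"])
        res = rm_anova_gg(m)
        t, df, p = paired_t(m["injection"], m["baseline"])
        (cmp,) = res.posthoc
        assert cmp.statistic == pytest.approx(t, abs=1e-10)
        assert cmp.p_adjusted == pytest.approx(p, abs=1e-10)

    def test_dunnett_quadrature_is_seed_deterministic(self):
        rng = np.random.default_rng(21)
        m = random_matrix(rng)
        a = rm_anova_gg(m, dunnett_seed=3)
        b = rm_anova_gg(m, dunnett_seed=3)
        assert [c.p_adjusted for c in a.posthoc] == [
            c.p_adjusted for c in b.posthoc
        ]

    def test_dunnett_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            res = rm_anova_gg(random_matrix(rng))
            for c in res.posthoc:
                assert c.p_adjusted >= c.p_uncorrected - 1e-12

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng)
        a = rm_anova_gg(m)
        b = rm_anova_gg(m + 11.5)
        assert a.F == pytest.approx(b.F, rel=1e-9)
        assert a.epsilon == pytest.approx(b.epsilon, rel=1e-9)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng)
        a = rm_anova_gg(m)
        b = rm_anova_gg(m.sample(frac=1, random_state=1).reset_index(drop=True))
        assert a.F == pytest.approx(b.F, rel=1e-9)


# ---------------------------------------------------------------------------
# Friedman + Dunn
# ---------------------------------------------------------------------------


class TestFriedman:
    def test_rowwise_permutations_of_identical_values(self):
        rng = np.random.default_rng(10)
        rows = [rng.permutation([1.0, 2.0, 3.0]) for _ in range(12)]
        m = pd.DataFrame(rows, columns=COLS[:3])
        # every column has the same rank distribution only when rank sums tie;
        # build rows so each condition gets each rank exactly 4 times
        ordered = np.array([[1.0, 2.0, 3.0]] * 4 + [[2.0, 3.0, 1.0]] * 4
                           + [[3.0, 1.0, 2.0]] * 4)
        m = pd.DataFrame(ordered, columns=COLS[:3])
        res = friedman_dunn(m)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_strict_ordering_three_by_three(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [0.1, 0.2, 0.3]],
            columns=COLS[:3],
        )
        res = friedman_dunn(m)
        assert res.chi2 == pytest.approx(6.0, abs=1e-12)
        assert res.df == 2

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            m = random_matrix(rng)
            m.iloc[:5, 0] = m.iloc[:5, 1]  # inject ties
            res = friedman_dunn(m)
            assert res.chi2 == pytest.approx(oracle_friedman(m), abs=1e-9)

    def test_dunn_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(12)
        res = friedman_dunn(random_matrix(rng), family="all_pairs")
        assert len(res.posthoc) == 10
        for c in res.posthoc:
            assert c.p_adjusted >= c.p_uncorrected - 1e-12

    def test_vs_baseline_family_size(self):
        rng = np.random.default_rng(13)
        res = friedman_dunn(random_matrix(rng))
        assert len(res.posthoc) == 4


# ---------------------------------------------------------------------------
# Mixed two-way ANOVA + Sidak
# ---------------------------------------------------------------------------


class TestMixedAnova:
    def test_identical_groups_have_null_between_terms(self):
        rng = np.random.default_rng(14)
        m = random_matrix(rng)
        res = mixed_two_way_anova(m, m.copy())
        assert res.between.F == pytest.approx(0.0, abs=1e-20)
        assert res.interaction.F == pytest.approx(0.0, abs=1e-20)

    def test_default_design_dfs(self):
        rng = np.random.default_rng(15)
        res = mixed_two_way_anova(random_matrix(rng), random_matrix(rng))
        assert (res.between.df1, res.between.df2) == (1, 38)
        assert (res.interaction.df1, res.interaction.df2) == (4, 152)
        # the within factor reports GG-corrected, hence non-integer, dfs
        assert res.within.df1 == pytest.approx(4 * res.within.epsilon, abs=1e-9)

    def test_matches_split_plot_oracle(self):
        rng = np.random.default_rng(16)
        for _ in range(5):
            a, b = random_matrix(rng), random_matrix(rng)
            res = mixed_two_way_anova(a, b)
            Fg, Fc, Fi = oracle_split_plot(a.to_numpy(), b.to_numpy())
            assert res.between.F == pytest.approx(Fg, abs=1e-8)
            assert res.within.F == pytest.approx(Fc, abs=1e-8)
            assert res.interaction.F == pytest.approx(Fi, abs=1e-8)

    def test_sidak_adjustment(self):
        rng = np.random.default_rng(17)
        res = mixed_two_way_anova(random_matrix(rng), random_matrix(rng))
        assert len(res.posthoc) == 5
        for c in res.posthoc:
            expected = 1 - (1 - c.p_uncorrected) ** 5
            assert c.p_adjusted == pytest.approx(max(expected, c.p_uncorrected),
                                                 abs=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(18)
        a, b = random_matrix(rng), random_matrix(rng)
        r1 = mixed_two_way_anova(a, b)
        r2 = mixed_two_way_anova(a + 3.0, b + 3.0)
        assert r1.interaction.F == pytest.approx(r2.interaction.F, rel=1e-9)


# ---------------------------------------------------------------------------
# paired t, Fisher, epsilon
# ---------------------------------------------------------------------------


class TestPairedT:
    def test_identical_vectors(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_matches_closed_form(self):
        rng = np.random.default_rng(19)
        a, b = rng.normal(size=12), rng.normal(size=12)
        t, df, p = paired_t(a, b)
        d = a - b
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(12))
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert df == 11
        assert p == pytest.approx(2 * stats.t.sf(abs(t_ref), 11), abs=1e-12)


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_association_matches_enumeration(self):
        table = [[10, 0], [0, 10]]
        assert fisher_exact_2x2(table) == pytest.approx(
            oracle_fisher_two_sided(table), abs=1e-12
        )

    def test_degenerate_margins(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == pytest.approx(1.0)
        assert fisher_exact_2x2([[0, 3], [0, 4]]) == pytest.approx(1.0)

    def test_non_integer_rejected(self):
        with pytest.raises(Exception):
            fisher_exact_2x2([[1.5, 2], [3, 4]])


class TestGgEpsilon:
    def test_compound_symmetry_gives_one(self):
        k = 5
        S = 0.3 * np.ones((k, k)) + 0.7 * np.eye(k)
        assert gg_epsilon(S) == pytest.approx(1.0, abs=1e-12)

    def test_two_conditions_give_one(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert gg_epsilon(S) == pytest.approx(1.0, abs=1e-12)

    def test_matches_pingouin_on_data(self):
        import pingouin as pg

        rng = np.random.default_rng(20)
        data = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("wxyz"))
        ours = gg_epsilon(np.cov(data.to_numpy(), rowvar=False, ddof=1))
        assert ours == pytest.approx(float(pg.epsilon(data, correction="gg")),
                                     abs=1e-10)

    def test_lower_bound_clamp(self):
        # rank-one covariance: maximal sphericity violation -> eps = 1/(k-1)
        v = np.array([3.0, -1.0, 0.5, 1.5])
        S = np.outer(v, v)
        assert gg_epsilon(S) == pytest.approx(1 / 3, abs=1e-12)
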