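"""Agreement and group-comparison statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from objscd.classification import ContingencyTable
from objscd.stats import (
    ancova_fit,
    cohen_kappa,
    oneway_anova,
    pairwise_contrasts,
    pearson_chi2,
    percent_agreement,
    proportion_table,
)


def table(counts, labels=None):
    counts = np.asarray(counts, dtype=int)
    r = labels or tuple(f"r{i}" for i in range(counts.shape[0]))
    c = labels or tuple(f"c{i}" for i in range(counts.shape[1]))
    return ContingencyTable.from_array(counts, r, c)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(table([[10, 0], [0, 7]])).kappa == pytest.approx(1.0)

    def test_independence_table_gives_zero(self):
        # counts proportional to row x column marginal products
        assert cohen_kappa(table([[1, 2], [2, 4]])).kappa == pytest.approx(0.0)

    def test_bounds_and_observed_expected(self):
        res = cohen_kappa(table([[5, 9], [8, 3]]))
        assert -1.0 <= res.kappa <= 1.0
        assert 0.0 <= res.observed_agreement <= 1.0
        assert 0.0 <= res.expected_agreement <= 1.0
        assert res.kappa == pytest.approx(
            (res.observed_agreement - res.expected_agreement)
            / (1 - res.expected_agreement)
        )

    @settings(derandomize=True, max_examples=100)
    @given(
        counts=st.lists(st.integers(1, 40), min_size=4, max_size=4),
        scale=st.integers(2, 9),
    )
    def test_invariant_to_count_scaling(self, counts, scale):
        a = np.array(counts).reshape(2, 2)
        k1 = cohen_kappa(table(a)).kappa
        k2 = cohen_kappa(table(a * scale)).kappa
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_matches_sklearn_on_label_vectors(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(21)
        for _ in range(10):
            a = rng.integers(0, 3, 200)
            b = rng.integers(0, 3, 200)
            mat = pd.crosstab(a, b).reindex(
                index=range(3), columns=range(3), fill_value=0
            ).to_numpy()
            ours = cohen_kappa(table(mat)).kappa
            theirs = sklearn_metrics.cohen_kappa_score(a, b)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_degenerate_expected_agreement(self):
        with pytest.raises(ZeroDivisionError):
            cohen_kappa(table([[5, 0], [0, 0]]))


class TestPercentAgreement:
    @pytest.mark.parametrize(
        "counts,expected",
        [([[5, 0], [0, 5]], 100.0), ([[0, 3], [4, 0]], 0.0), ([[1, 1], [1, 1]], 50.0)],
    )
    def test_examples(self, counts, expected):
        assert percent_agreement(table(counts)) == pytest.approx(expected)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            percent_agreement(table([[0, 0], [0, 0]]))


class TestChiSquared:
    def test_zero_when_observed_equals_expected(self):
        res = pearson_chi2(table([[10, 20], [20, 40]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_matches_brute_force_exhaustively_on_small_tables(self):
        """Enumerate all 2x2 tables with total <= 12 and cross-check the formula."""
        for total in range(4, 13):
            for a, b, c in itertools.combinations_with_replacement(range(total + 1), 3):
                cells = np.array([a, b - a, c - b, total - c])
                if np.any(cells < 0):
                    continue
                mat = cells.reshape(2, 2)
                if np.any(mat.sum(0) == 0) or np.any(mat.sum(1) == 0):
                    continue
                expected = np.outer(mat.sum(1), mat.sum(0)) / mat.sum()
                brute = float(((mat - expected) ** 2 / expected).sum())
                res = pearson_chi2(table(mat))
                assert res.statistic == pytest.approx(brute, abs=1e-10)
                assert res.statistic >= 0

    def test_matches_brute_force_on_random_larger_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            shape = rng.choice([2, 3]), rng.choice([2, 3, 4])
            mat = rng.integers(1, 30, size=shape)
            expected = np.outer(mat.sum(1), mat.sum(0)) / mat.sum()
            brute = float(((mat - expected) ** 2 / expected).sum())
            res = pearson_chi2(table(mat))
            assert res.statistic == pytest.approx(brute, abs=1e-9)
            assert res.df == (shape[0] - 1) * (shape[1] - 1)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2(table([[3, 0], [5, 0]]))

    def test_proportion_table_builder(self):
        t = proportion_table([3, 5], [10, 20], ["g1", "g2"])
        assert t.matrix.tolist() == [[3, 7], [5, 15]]
        with pytest.raises(ValueError):
            proportion_table([11], [10], ["g1"])


class TestOnewayAnova:
    def test_identical_groups_give_zero_f(self):
        values = [3.0, 4.0, 5.0, 3.0, 4.0, 5.0]
        groups = ["a"] * 3 + ["b"] * 3
        assert oneway_anova(values, groups).f == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_decomposition(self):
        values = np.array([1.0, 2.0, 3.0, 2.0, 4.0, 6.0, 5.0, 5.0, 8.0])
        groups = np.repeat(["a", "b", "c"], 3)
        grand = values.mean()
        ss_between = sum(
            3 * (values[groups == g].mean() - grand) ** 2 for g in "abc"
        )
        ss_within = sum(
            ((values[groups == g] - values[groups == g].mean()) ** 2).sum()
            for g in "abc"
        )
        f_brute = (ss_between / 2) / (ss_within / 6)
        res = oneway_anova(values, groups)
        assert res.f == pytest.approx(f_brute)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova([1.0, 2.0], ["a", "a"])


def _brute_force_ancova(y, X_full, X_red, df_num):
    """Independent normal-equations solution of the extra-sum-of-squares F test."""
    def ssr(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        return float(resid @ resid)

    ssr_full, ssr_red = ssr(X_full), ssr(X_red)
    df_den = len(y) - X_full.shape[1]
    ss_group = ssr_red - ssr_full
    f = (ss_group / df_num) / (ssr_full / df_den)
    eta2 = ss_group / (ss_group + ssr_full)
    return f, eta2


class TestAncova:
    def test_reduces_to_oneway_anova_without_covariates(self):
        rng = np.random.default_rng(31)
        y = rng.normal(size=30)
        groups = rng.choice(["a", "b", "c"], size=30)
        fit = ancova_fit(y, groups, covariates=None, group_order=["a", "b", "c"])
        anova = oneway_anova(y, groups)
        assert fit.f == pytest.approx(anova.f, abs=1e-10)
        assert (fit.df_num, fit.df_den) == (anova.df_between, anova.df_within)

    def test_matches_normal_equations_oracle_on_small_fixture(self):
        # n = 12, two groups, two covariates: solvable by hand with (X'X)^-1 X'y
        rng = np.random.default_rng(32)
        y = rng.normal(size=12)
        groups = np.repeat(["a", "b"], 6)
        cov = pd.DataFrame({"c1": rng.normal(size=12), "c2": rng.normal(size=12)})
        fit = ancova_fit(y, groups, covariates=cov, group_order=["a", "b"])
        X_full = np.column_stack(
            [np.ones(12), (groups == "b").astype(float), cov.to_numpy()]
        )
        X_red = np.column_stack([np.ones(12), cov.to_numpy()])
        f_brute, eta_brute = _brute_force_ancova(y, X_full, X_red, df_num=1)
        assert fit.f == pytest.approx(f_brute, abs=1e-8)
        assert fit.partial_eta_squared == pytest.approx(eta_brute, abs=1e-10)
        assert (fit.df_num, fit.df_den) == (1, 8)

    def test_two_group_f_equals_squared_t(self):
        rng = np.random.default_rng(33)
        y = rng.normal(size=40)
        groups = rng.choice(["x", "y"], size=40)
        cov = pd.DataFrame({"age": rng.normal(70, 6, 40)})
        fit = ancova_fit(y, groups, covariates=cov, group_order=["x", "y"])
        contrast = pairwise_contrasts(fit, [("y", "x")])[("y", "x")]
        assert contrast.t ** 2 == pytest.approx(fit.f, abs=1e-8)
        assert contrast.p_value == pytest.approx(fit.p_value, abs=1e-10)

    def test_null_effect_has_vanishing_partial_eta(self):
        rng = np.random.default_rng(34)
        n = 4000
        y = rng.normal(size=n)
        groups = rng.choice(["a", "b"], size=n)
        fit = ancova_fit(y, groups, covariates=pd.DataFrame({"c": rng.normal(size=n)}))
        assert fit.partial_eta_squared < 0.005

    def test_adjusted_means_at_covariate_means(self):
        # with a balanced design and centred covariate, adjusted = raw group means
        y = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 7.0])
        groups = np.repeat(["a", "b"], 3)
        cov = pd.DataFrame({"c": [-1.0, 0.0, 1.0, -1.0, 0.0, 1.0]})
        fit = ancova_fit(y, groups, covariates=cov, group_order=["a", "b"])
        assert fit.adjusted_means["a"] == pytest.approx(2.0)
        assert fit.adjusted_means["b"] == pytest.approx(6.0)

    def test_complete_case_deletion(self):
        y = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0, 8.0])
        groups = np.repeat(["a", "b"], 4)
        cov = pd.DataFrame({"c": [0.1, np.nan, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]})
        fit = ancova_fit(y, groups, covariates=cov)
        assert fit.n == 6

    def test_rank_deficiency_rejected(self):
        y = np.arange(6, dtype=float)
        groups = np.repeat(["a", "b"], 3)
        cov = pd.DataFrame({"c": np.repeat([0.0, 1.0], 3)})  # aliases the group dummy
        with pytest.raises(ValueError):
            ancova_fit(y, groups, covariates=cov)


class TestContrasts:
    def test_self_contrast_is_null(self):
        rng = np.random.default_rng(35)
        y = rng.normal(size=20)
        groups = np.repeat(["a", "b"], 10)
        fit = ancova_fit(y, groups)
        c = pairwise_contrasts(fit, [("a", "a")])[("a", "a")]
        assert c.t == 0.0 and c.p_value == 1.0 and c.difference == 0.0

    def test_equal_groups_by_construction_give_t_zero(self):
        y = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        groups = np.repeat(["a", "b"], 4)
        fit = ancova_fit(y, groups)
        c = pairwise_contrasts(fit, [("a", "b")])[("a", "b")]
        assert abs(c.t) < 1e-10
        assert c.p_value == pytest.approx(1.0, abs=1e-9)

    def test_unknown_group_rejected(self):
        y = np.arange(8, dtype=float)
        fit = ancova_fit(y, np.repeat(["a", "b"], 4))
        with pytest.raises(KeyError):
            pairwise_contrasts(fit, [("a", "zzz")])

    def test_null_p_values_are_roughly_uniform(self):
        """Under H0 the contrast p-values should not concentrate anywhere."""
        rng = np.random.default_rng(36)
        pvals = []
        for _ in range(400):
            y = rng.normal(size=24)
            groups = np.repeat(["a", "b"], 12)
            fit = ancova_fit(y, groups)
            pvals.append(pairwise_contrasts(fit, [("a", "b")])[("a", "b")].p_value)
        pvals = np.asarray(pvals)
        # coarse uniformity: rejection rate near alpha and mean near 1/2
        assert abs((pvals < 0.05).mean() - 0.05) < 0.03
        assert abs(pvals.mean() - 0.5) < 0.05
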