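"""Psychometric statistics against independent oracles: a brute-force
permutation null for the correlation p-value, normal equations for the
regression, a two-pass streaming pass for descriptives, and a published
correlation matrix for standardized alpha."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import keystrokes as ks
from keystrokes.psychometrics import (
    UndefinedStatisticError,
    alpha_from_correlations,
    correlation_matrix,
    cronbach_alpha,
    descriptives,
    group_alphas,
    pearson,
    regress_age_education,
)

KCOLS = [f"k{i}" for i in range(1, 7)]

# Published inter-subtest correlation matrix of the six conditions
# (two-decimal cells; symmetric, unit diagonal).
SUBTEST_R = np.array([
    [1.00, 0.89, 0.87, 0.72, 0.79, 0.80],
    [0.89, 1.00, 0.87, 0.81, 0.81, 0.77],
    [0.87, 0.87, 1.00, 0.79, 0.87, 0.76],
    [0.72, 0.81, 0.79, 1.00, 0.88, 0.82],
    [0.79, 0.81, 0.87, 0.88, 1.00, 0.84],
    [0.80, 0.77, 0.76, 0.82, 0.84, 1.00],
])


class TestPearson:
    def test_perfect_linearity(self):
        res = pearson([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)
        assert res.n == 3

    def test_hand_computed_product_moment(self):
        # Sxy = 3, Sxx = 2, Syy = 14/3 -> r = 3 / sqrt(28/3)
        res = pearson([1, 2, 3], [1, 2, 4])
        assert res.r == pytest.approx(3 / math.sqrt(28 / 3))
        assert round(res.r, 3) == 0.982

    def test_pairwise_deletion_and_min_pairs(self):
        x = [1.0, 2.0, np.nan, 4.0]
        y = [2.0, 1.0, 5.0, 8.0]
        assert pearson(x, y).n == 3
        with pytest.raises(UndefinedStatisticError):
            pearson([1, np.nan, 3], [2, 5, np.nan])

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson([1, 1, 1, 1], [2, 3, 4, 5])

    def test_t_based_p_close_to_exhaustive_permutation(self):
        """On an n = 8 dataset the parametric two-tailed p agrees with the
        exact permutation distribution of |r| to within .05."""
        x = np.array([2.0, 4.0, 3.0, 7.0, 6.0, 9.0, 8.0, 12.0])
        y = np.array([1.0, 3.0, 6.0, 5.0, 8.0, 7.0, 11.0, 10.0])
        obs = pearson(x, y)
        xz = (x - x.mean()) / x.std()
        count = 0
        total = 0
        for perm in itertools.permutations(y):
            yp = np.asarray(perm)
            r = float(np.dot(xz, (yp - yp.mean()) / yp.std())) / len(x)
            if abs(r) >= abs(obs.r) - 1e-12:
                count += 1
            total += 1
        assert total == math.factorial(8)
        perm_p = count / total
        assert abs(obs.p - perm_p) < 0.05


class TestCorrelationMatrix:
    def test_no_missingness_gives_equal_n(self, analytic_cohort):
        cm = correlation_matrix(analytic_cohort.data, KCOLS)
        assert (cm.n.to_numpy() == len(analytic_cohort.data)).all()

    def test_masking_rows_lowers_pairwise_n(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(87, 2)), columns=["a", "b"])
        df.loc[df.index[:42], "a"] = np.nan
        cm = correlation_matrix(df, ["a", "b"])
        assert cm.n.loc["a", "b"] == 45

    def test_symmetric_and_positive_semidefinite(self, analytic_cohort):
        cm = correlation_matrix(analytic_cohort.data, KCOLS)
        r = cm.r.to_numpy()
        assert np.allclose(r, r.T)
        assert np.diag(r) == pytest.approx(np.ones(6))
        assert np.linalg.eigvalsh(r).min() > -1e-10

    def test_flag_hierarchy(self, analytic_cohort):
        """p < .01 implies the .05 flag is also set."""
        cols = KCOLS + ["age", "BDI", "BAI"]
        cm = correlation_matrix(analytic_cohort.data, cols)
        assert (cm.flag05.to_numpy() | ~cm.flag01.to_numpy()).all()

    def test_unknown_variable_rejected(self, analytic_cohort):
        with pytest.raises(KeyError):
            correlation_matrix(analytic_cohort.data, ["k1", "nonexistent"])


class TestCronbachAlpha:
    def test_whole_test_alpha_from_published_matrix(self):
        """Standardized alpha of the printed six-subtest correlation matrix:
        rbar = .8193 over the 15 cells, alpha = 6 rbar / (1 + 5 rbar)."""
        alpha = alpha_from_correlations(SUBTEST_R)
        rbar = SUBTEST_R[~np.eye(6, dtype=bool)].mean()
        assert rbar == pytest.approx(0.8193, abs=1e-4)
        assert alpha == pytest.approx(6 * rbar / (1 + 5 * rbar))
        assert round(alpha, 2) == 0.96

    def test_two_item_alpha_is_spearman_brown(self):
        alpha = alpha_from_correlations(np.array([[1.0, 0.84], [0.84, 1.0]]))
        assert alpha == pytest.approx(2 * 0.84 / 1.84)
        assert round(alpha, 2) == 0.91

    def test_duplicated_items_give_raw_alpha_one(self):
        x = np.random.default_rng(1).normal(size=50)
        res = cronbach_alpha(pd.DataFrame({"a": x, "b": x, "c": x}))
        assert res.alpha_raw == pytest.approx(1.0)

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        base = rng.normal(size=(120, 1))
        items = pd.DataFrame(
            base + rng.normal(scale=0.8, size=(120, 4)),
            columns=list("abcd"))
        ours = cronbach_alpha(items)
        theirs = float(pg.cronbach_alpha(data=items)[0])
        assert ours.alpha_raw == pytest.approx(theirs, abs=1e-10)

    def test_two_paths_one_answer(self, analytic_cohort):
        """Standardized alpha from raw scores equals alpha computed from
        those scores' correlation matrix."""
        scores = analytic_cohort.data[KCOLS]
        direct = cronbach_alpha(scores).alpha_standardized
        via_matrix = alpha_from_correlations(
            correlation_matrix(analytic_cohort.data, KCOLS).r)
        assert direct == pytest.approx(via_matrix, abs=1e-12)

    def test_zscored_items_make_raw_equal_standardized(self, analytic_cohort):
        z = analytic_cohort.data[KCOLS].apply(
            lambda s: (s - s.mean()) / s.std())
        res = cronbach_alpha(z)
        assert res.alpha_raw == pytest.approx(res.alpha_standardized, abs=1e-10)

    def test_group_alphas_cover_condition_groups(self, analytic_cohort):
        alphas = group_alphas(analytic_cohort.data)
        assert set(alphas) == {"all", "speeded", "inhibition", "switching"}
        assert alphas["all"].k == 6 and alphas["speeded"].k == 2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cronbach_alpha(pd.DataFrame({"a": [1.0, 2.0]}))
        with pytest.raises(UndefinedStatisticError):
            cronbach_alpha(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000),
           st.integers(min_value=2, max_value=6),
           st.integers(min_value=8, max_value=40))
    def test_alpha_path_equivalence_property(self, seed, k, n):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(n, 1))
        items = pd.DataFrame(base + rng.normal(scale=0.7, size=(n, k)))
        res = cronbach_alpha(items)
        assert res.alpha_standardized == pytest.approx(
            alpha_from_correlations(np.corrcoef(items.T)), abs=1e-10)
        assert res.alpha_raw <= 1.0


class TestRegression:
    def test_constant_outcome(self, analytic_cohort):
        df = analytic_cohort.data.copy().head(50)
        df["flat"] = 7.0
        fit = regress_age_education(df, "flat")
        assert fit.r2 == 0.0 and fit.f == 0.0

    def test_exact_linear_outcome(self, analytic_cohort):
        df = analytic_cohort.data.copy().head(60)
        df["twice_age"] = 2.0 * df["age"]
        fit = regress_age_education(df, "twice_age")
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coefficient("age").estimate == pytest.approx(2.0)
        assert fit.coefficient("age").p < 1e-12

    def test_matches_normal_equations_oracle(self):
        df = pd.DataFrame({
            "age": [25.0, 40.0, 55.0, 33.0, 61.0, 47.0],
            "education": [12.0, 16.0, 14.0, 18.0, 12.0, 20.0],
            "k1": [110.0, 95.0, 72.0, 104.0, 66.0, 90.0],
        })
        X = np.column_stack([np.ones(6), df["age"], df["education"]])
        y = df["k1"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (6 - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
        fit = regress_age_education(df, "k1")
        for i, name in enumerate(("intercept", "age", "education")):
            assert fit.coefficient(name).estimate == pytest.approx(beta[i])
            assert fit.coefficient(name).se == pytest.approx(se[i])
        assert fit.r2 == pytest.approx(r2)
        assert (fit.df1, fit.df2) == (2, 3)

    def test_r2_equals_squared_fitted_correlation(self, analytic_cohort):
        df = analytic_cohort.data
        fit = regress_age_education(df, "k3")
        b = {c.name: c.estimate for c in fit.coefficients}
        fitted = (b["intercept"] + b["age"] * df["age"]
                  + b["education"] * df["education"])
        assert fit.r2 == pytest.approx(np.corrcoef(fitted, df["k3"])[0, 1] ** 2)
        assert (fit.df1, fit.df2) == (2, len(df) - 3)

    def test_collinear_predictors_rejected(self):
        df = pd.DataFrame({
            "age": [30.0, 40.0, 50.0, 60.0],
            "education": [15.0, 20.0, 25.0, 30.0],  # exactly age/2
            "k1": [1.0, 2.0, 3.0, 4.0],
        })
        with pytest.raises(UndefinedStatisticError):
            regress_age_education(df, "k1")


class TestDescriptives:
    def test_single_row_sd_is_zero(self):
        out = descriptives(pd.DataFrame({"age": [50.0]}))
        assert out["numeric"].loc["age", "SD"] == 0.0
        assert out["numeric"].loc["age", "N"] == 1

    def test_two_pass_streaming_oracle(self, analytic_cohort):
        ages = analytic_cohort.data["age"].to_numpy()
        mean = sum(ages) / len(ages)                      # pass one
        var = sum((a - mean) ** 2 for a in ages) / (len(ages) - 1)  # pass two
        out = descriptives(analytic_cohort.data)["numeric"]
        assert out.loc["age", "M"] == pytest.approx(mean)
        assert out.loc["age", "SD"] == pytest.approx(math.sqrt(var))
        assert out.loc["age", "min"] == ages.min()
        assert out.loc["age", "max"] == ages.max()

    def test_categorical_frequencies(self, analytic_cohort):
        out = descriptives(analytic_cohort.data)
        assert "freq_gender" in out and "freq_ethnicity" in out
        assert out["freq_gender"]["N"].sum() == len(analytic_cohort.data)
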