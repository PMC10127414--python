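"""Clinical statistics: composites, subgrouping, ANOVA/ANCOVA/LSD,
exact tests, partial correlation and FDR — checked against hand
computations and independent library oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from subcovnet import clinical as cl


# ---------------------------------------------------------------------------
# composites and subgrouping
# ---------------------------------------------------------------------------


def test_zscores_hand_example():
    z = cl._zscore(np.array([1.0, 2.0, 3.0, 4.0]), "x")
    np.testing.assert_allclose(z, [-1.1619, -0.3873, 0.3873, 1.1619], atol=1e-4)


def test_single_test_domain_equals_zscore(default_cohort):
    comp = cl.composite_zscores(default_cohort, {"bnt": ("language", True)})
    z = cl._zscore(default_cohort["bnt"].to_numpy(float), "bnt")
    np.testing.assert_allclose(comp["language"].to_numpy()[: len(z)], z)


def test_time_scores_flip_sign(default_cohort):
    comp = cl.composite_zscores(default_cohort, {"tmt_a": ("executive", False)})
    z = cl._zscore(default_cohort["tmt_a"].to_numpy(float), "tmt_a")
    np.testing.assert_allclose(comp["executive"].to_numpy(), -z)


def test_navigation_composite_not_flipped(default_cohort):
    comp = cl.composite_zscores(default_cohort)
    trials = [c for c in default_cohort.columns if "_trial_" in c]
    raw = default_cohort[trials].mean(axis=1)
    # higher error -> higher navigation composite
    assert np.corrcoef(raw, comp["navigation"])[0, 1] > 0.999


def test_composite_sign_pattern_matches_group_severity(default_cohort):
    comp = cl.composite_zscores(default_cohort)
    comp["group"] = default_cohort["group"]
    means = comp.groupby("group")["memory"].mean()
    assert means["NC"] > means["MCI"]


def test_zero_variance_test_named():
    df = pd.DataFrame({"cdt": np.ones(10)})
    with pytest.raises(ValueError, match="cdt"):
        cl.composite_zscores(df, {"cdt": ("executive", True)})


class TestSplit:
    def _cohort(self, errors):
        n = len(errors)
        return pd.DataFrame({"group": ["SCD"] * n, "err": errors})

    def test_even_split_by_rank(self):
        df = self._cohort(list(range(1, 81)))
        labels = cl.split_scd_by_score(df, df["err"])
        assert (labels.iloc[:40] == "G-SCD").all()
        assert (labels.iloc[40:] == "B-SCD").all()

    def test_higher_is_better_scores_supported(self):
        df = self._cohort([10, 20, 30, 40])
        labels = cl.split_scd_by_score(df, df["err"], lower_is_better=False)
        assert list(labels) == ["B-SCD", "B-SCD", "G-SCD", "G-SCD"]

    def test_boundary_tie_resolved_stably_and_logged(self, caplog):
        df = self._cohort([1.0, 2.0, 2.0, 3.0])
        with caplog.at_level("WARNING"):
            labels = cl.split_scd_by_score(df, df["err"])
        assert list(labels) == ["G-SCD", "G-SCD", "B-SCD", "B-SCD"]
        assert any("tie" in r.message for r in caplog.records)

    def test_odd_count_needs_rule(self):
        df = self._cohort([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="odd"):
            cl.split_scd_by_score(df, df["err"])
        labels = cl.split_scd_by_score(df, df["err"], odd_rule="extra_good")
        assert list(labels) == ["G-SCD", "G-SCD", "B-SCD"]

    def test_non_scd_rows_untouched(self):
        df = pd.DataFrame({"group": ["NC", "SCD", "SCD"], "err": [9.0, 1.0, 2.0]})
        labels = cl.split_scd_by_score(df, df["err"])
        assert list(labels) == ["NC", "G-SCD", "B-SCD"]


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------


def test_anova_hand_example():
    vals = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], dtype=float)
    groups = np.repeat(["a", "b", "c"], 3)
    res = cl.oneway_anova(vals, groups)
    assert res.df == (2, 6)
    assert res.statistic == pytest.approx(3.0)


def test_anova_equals_squared_t_for_two_groups(rng):
    a = rng.normal(size=12)
    b = rng.normal(0.4, 1, size=15)
    f = cl.oneway_anova(np.r_[a, b], np.r_[["a"] * 12, ["b"] * 15])
    t = cl.two_sample_t(a, b)
    assert f.statistic == pytest.approx(t.statistic**2)
    assert f.p == pytest.approx(t.p)


def test_anova_zero_between_variance_gives_zero_f():
    vals = np.array([1, 2, 3, 1, 2, 3], dtype=float)
    res = cl.oneway_anova(vals, np.repeat(["a", "b"], 3))
    assert res.statistic == pytest.approx(0.0)


def test_chi_square_printed_tables():
    sex = np.array([[14, 7, 7, 4], [63, 33, 33, 19]])
    assert cl.chi_square_test(sex).statistic == pytest.approx(0.015, abs=5e-4)
    scanner = np.array([[30, 13, 17, 9], [47, 27, 23, 14]])
    assert cl.chi_square_test(scanner).statistic == pytest.approx(0.889, abs=5e-4)


def test_chi_square_zero_iff_proportional_margins():
    assert cl.chi_square_test(np.array([[10, 20], [20, 40]])).statistic == pytest.approx(0.0)
    assert cl.chi_square_test(np.array([[10, 5], [5, 10]])).statistic > 0


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        cl.chi_square_test(np.array([[0, 0], [3, 4]]))


def _fisher_enumeration(table):
    """Brute-force two-tailed Fisher p by enumerating all tables with the
    observed margins via exact binomial coefficients."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, c1)
    probs = []
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        probs.append(math.comb(r1, x) * math.comb(n - r1, c1 - x) / denom)
    p_obs = probs[a - max(0, r1 + c1 - n)]
    return sum(p for p in probs if p <= p_obs * (1 + 1e-7))


class TestFisher:
    def test_printed_followup_table(self):
        res = cl.fisher_exact_two_tailed(np.array([[0, 20], [4, 15]]))
        assert round(res.p, 3) == 0.047

    def test_identical_rows_give_p_one(self):
        assert cl.fisher_exact_two_tailed(np.array([[5, 5], [5, 5]])).p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        t = np.array([[1, 9], [9, 1]])
        assert cl.fisher_exact_two_tailed(t).p == pytest.approx(_fisher_enumeration(t))

    def test_matches_scipy(self):
        for t in ([[2, 7], [8, 2]], [[0, 12], [5, 5]], [[3, 3], [4, 4]]):
            t = np.array(t)
            assert cl.fisher_exact_two_tailed(t).p == pytest.approx(
                stats.fisher_exact(t)[1]
            )

    def test_doubling_rule_alternative(self):
        t = np.array([[1, 9], [9, 1]])
        res = cl.fisher_exact_two_tailed(t, rule="doubling")
        lower = sum(stats.hypergeom(20, 10, 10).pmf(x) for x in range(0, 2))
        assert res.p == pytest.approx(min(1.0, 2 * lower))

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            cl.fisher_exact_two_tailed(np.array([[0.5, 1], [1, 1]]))


def test_two_sample_t_hand_example():
    res = cl.two_sample_t(np.array([1, 2, 3, 4.0]), np.array([3, 4, 5, 6.0]))
    assert res.statistic == pytest.approx(-2.1909, abs=1e-4)
    assert res.df == (6.0,)


def test_two_sample_t_identical_samples():
    res = cl.two_sample_t(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
    assert res.statistic == 0.0 and res.p == 1.0


# ---------------------------------------------------------------------------
# ANCOVA / LSD / partial correlation / FDR
# ---------------------------------------------------------------------------


def _normal_equations_ancova(y, groups, C):
    """Independent oracle: explicit normal equations for full and reduced
    models, F from residual sums of squares."""
    levels = list(dict.fromkeys(groups))
    D = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    X_full = np.column_stack([np.ones(len(y)), D, C])
    X_red = np.column_stack([np.ones(len(y)), C])

    def sse(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    k = len(levels)
    df_resid = len(y) - X_full.shape[1]
    f = (sse(X_red) - sse(X_full)) / (k - 1) / (sse(X_full) / df_resid)
    return f, (k - 1, df_resid)


def test_ancova_matches_normal_equations_oracle(rng):
    y = rng.normal(size=12)
    groups = np.repeat(["a", "b", "c"], 4)
    C = rng.normal(size=(12, 2))
    fit = cl.ancova_group_effect(y, groups, C)
    f_oracle, df_oracle = _normal_equations_ancova(y, groups, C)
    assert fit.result.statistic == pytest.approx(f_oracle)
    assert fit.result.df == df_oracle


def test_ancova_matches_statsmodels(rng):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = rng.normal(size=60)
    groups = np.repeat(["a", "b", "c"], 20)
    df = pd.DataFrame({"y": y, "g": groups, "c1": rng.normal(size=60), "c2": rng.normal(size=60)})
    fit = cl.ancova_group_effect(y, groups, df[["c1", "c2"]])
    anova = sm.stats.anova_lm(smf.ols("y ~ C(g) + c1 + c2", df).fit(), typ=3)
    assert fit.result.statistic == pytest.approx(anova.loc["C(g)", "F"])
    assert fit.result.p == pytest.approx(anova.loc["C(g)", "PR(>F)"])


def test_ancova_without_covariates_reduces_to_anova(rng):
    y = rng.normal(size=30)
    groups = np.repeat(["a", "b", "c"], 10)
    fit = cl.ancova_group_effect(y, groups, None)
    res = cl.oneway_anova(y, groups)
    assert fit.result.statistic == pytest.approx(res.statistic)


def test_ancova_null_when_outcome_linear_in_covariate(rng):
    tiv = rng.normal(size=45)
    y = 3.0 + 2.0 * tiv
    groups = np.repeat(["a", "b", "c"], 15)
    fit = cl.ancova_group_effect(y, groups, tiv.reshape(-1, 1))
    assert fit.result.statistic == pytest.approx(0.0, abs=1e-12)


def test_ancova_covariate_rescaling_invariance(rng):
    y = rng.normal(size=40)
    groups = np.repeat(["a", "b"], 20)
    C = rng.normal(size=(40, 2))
    f1 = cl.ancova_group_effect(y, groups, C).result.statistic
    f2 = cl.ancova_group_effect(y, groups, 5.0 * C + 3.0).result.statistic
    assert f1 == pytest.approx(f2)


def test_ancova_rank_deficiency_names_columns(rng):
    y = rng.normal(size=20)
    groups = np.repeat(["a", "b"], 10)
    c = rng.normal(size=20)
    C = np.column_stack([c, 2 * c])  # collinear pair
    with pytest.raises(ValueError, match="rank deficient"):
        cl.ancova_group_effect(y, groups, C)


class TestLSD:
    def test_two_groups_reduce_to_ancova_p(self, rng):
        y = rng.normal(size=24)
        groups = np.repeat(["a", "b"], 12)
        C = rng.normal(size=(24, 1))
        fit = cl.ancova_group_effect(y, groups, C)
        pairs = cl.lsd_posthoc(fit)
        assert pairs[("a", "b")].p == pytest.approx(fit.result.p)

    def test_identical_adjusted_means_give_t_zero(self):
        y = np.tile([1.0, 2.0, 3.0], 2)
        groups = np.repeat(["a", "b"], 3)
        fit = cl.ancova_group_effect(y, groups, None)
        res = cl.lsd_posthoc(fit)[("a", "b")]
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_contrast_oracle(self, rng):
        """GLS contrast oracle: t = c'beta / sqrt(c'(X'X)^-1 c MSE)."""
        y = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        C = rng.normal(size=(30, 2))
        fit = cl.ancova_group_effect(y, groups, C)
        pairs = cl.lsd_posthoc(fit)
        X = fit.design
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        # contrast between groups b and c: dummy columns 1 and 2
        c = np.zeros(X.shape[1])
        c[1], c[2] = 1.0, -1.0
        t_oracle = (c @ beta) / np.sqrt(c @ XtX_inv @ c * fit.mse)
        assert pairs[("b", "c")].statistic == pytest.approx(t_oracle)

    def test_adjusted_mean_difference_consistency(self, rng):
        y = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        C = rng.normal(size=(30, 1))
        fit = cl.ancova_group_effect(y, groups, C)
        pairs = cl.lsd_posthoc(fit)
        means = fit.result.group_means
        for (ga, gb), res in pairs.items():
            assert res.extras["diff"] == pytest.approx(means[ga] - means[gb])


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = cl.partial_correlation(x, y, None)
        r, p = stats.pearsonr(x, y)
        assert res.statistic == pytest.approx(r)
        assert res.p == pytest.approx(p)

    def test_perfect_association(self, rng):
        x = rng.normal(size=20)
        z = rng.normal(size=20)
        res = cl.partial_correlation(x, x.copy(), z.reshape(-1, 1))
        assert res.statistic == pytest.approx(1.0)

    def test_matches_recursive_formula(self, rng):
        """8-point fixture against r_xy.z = (r_xy - r_xz r_yz) /
        sqrt((1-r_xz^2)(1-r_yz^2))."""
        x = rng.normal(size=8)
        z = rng.normal(size=8)
        y = 0.6 * x + 0.4 * z + rng.normal(size=8)
        r_xy = stats.pearsonr(x, y)[0]
        r_xz = stats.pearsonr(x, z)[0]
        r_yz = stats.pearsonr(y, z)[0]
        expected = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        res = cl.partial_correlation(x, y, z.reshape(-1, 1))
        assert res.statistic == pytest.approx(expected)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        x = rng.normal(size=50)
        z = rng.normal(size=50)
        y = 0.5 * x + 0.3 * z + rng.normal(size=50)
        res = cl.partial_correlation(x, y, z.reshape(-1, 1))
        out = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        assert res.statistic == pytest.approx(float(out["r"].iloc[0]), abs=1e-10)
        pcol = [c for c in out.columns if c.lower().startswith("p")][0]
        assert res.p == pytest.approx(float(out[pcol].iloc[0]), abs=1e-10)

    def test_constant_residuals_rejected(self):
        z = np.arange(10.0)
        with pytest.raises(ValueError, match="constant"):
            cl.partial_correlation(2 * z + 1, z, z.reshape(-1, 1))


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(cl.fdr_adjust([0.037]), [0.037])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(cl.fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            cl.fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_seventeen_node_example(self):
        ps = [0.001] + [0.9] * 16
        qs = cl.fdr_adjust(ps)
        assert qs[0] == pytest.approx(0.017)
        assert np.all(qs >= np.asarray(ps) - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cl.fdr_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_adjusted_at_least_raw_and_capped(self, ps):
        qs = cl.fdr_adjust(ps)
        assert np.all(qs >= np.asarray(ps) - 1e-12)
        assert np.all(qs <= 1.0)
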