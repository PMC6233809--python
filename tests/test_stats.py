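"""Rank transform, MANOVA/MANCOVA, summary t/F, bootstrap, slope comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tastepe import datasets
from tastepe.stats import (SummaryStat, bmi_change_rate, fisher_z_compare,
                           manova, pooled_anova_f_from_summary,
                           rank_transform_panel, spearman_bootstrap,
                           welch_t_from_summary)


def _summary(x):
    return SummaryStat(len(x), float(np.mean(x)), float(np.std(x, ddof=1)))


class TestWelchFromSummary:
    @pytest.mark.parametrize("scale,expected_t", [
        ("age", -1.078), ("harm_avoidance", -9.362),
        ("reward_dependence", 1.616),
    ])
    def test_reference_cohort_rows(self, scale, expected_t):
        an, ctl, _ = datasets.TABLE1[scale]
        t, df = welch_t_from_summary(ctl, an)
        assert t == pytest.approx(expected_t, abs=0.02)
        assert df > 0

    def test_identical_summaries_null(self):
        s = SummaryStat(20, 5.0, 1.0)
        t, _ = welch_t_from_summary(s, s)
        assert t == 0.0

    def test_matches_full_data_welch(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 2.0, 30)
        c = rng.normal(0.0, 1.0, 25)
        t_sum, df_sum = welch_t_from_summary(_summary(c), _summary(a))
        ref = sps.ttest_ind(c, a, equal_var=False)
        assert t_sum == pytest.approx(ref.statistic, rel=1e-10)
        assert df_sum == pytest.approx(ref.df, rel=1e-10)

    def test_zero_variance_rejected(self):
        s = SummaryStat(10, 1.0, 0.0)
        with pytest.raises(ValueError):
            welch_t_from_summary(s, s)


class TestPooledAnovaFromSummary:
    @pytest.mark.parametrize("roi,expected_f", [
        ("caudate_head_R", 22.972), ("caudate_head_L", 25.772),
        ("nucleus_accumbens_R", 18.939), ("nucleus_accumbens_L", 17.676),
        ("ventral_anterior_insula_R", 8.326),
    ])
    def test_reference_cohort_rois(self, roi, expected_f):
        an, ctl, _, _ = datasets.TABLE2[roi]
        f, _ = pooled_anova_f_from_summary(an, ctl)
        assert f == pytest.approx(expected_f, abs=0.05)

    def test_partial_eta2_formula(self):
        an, ctl, _, eta_pub = datasets.TABLE2["caudate_head_R"]
        f, eta = pooled_anova_f_from_summary(an, ctl)
        assert eta == pytest.approx(f / (f + 106), rel=1e-12)
        assert eta == pytest.approx(eta_pub, abs=0.001)

    def test_equal_groups_null(self):
        s = SummaryStat(20, 5.0, 1.0)
        f, eta = pooled_anova_f_from_summary(s, s)
        assert f == 0.0 and eta == 0.0

    def test_matches_full_data_anova(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 1.5, 40)
        c = rng.normal(0.3, 1.5, 35)
        f_sum, _ = pooled_anova_f_from_summary(_summary(a), _summary(c))
        assert f_sum == pytest.approx(sps.f_oneway(a, c).statistic, rel=1e-10)


class TestRankTransform:
    def test_non_normal_column_becomes_midranks(self):
        rng = np.random.default_rng(2)
        panel = pd.DataFrame({"a": rng.exponential(size=108)})
        out = rank_transform_panel(panel)
        assert out["a"].mean() == pytest.approx(54.5)
        assert sorted(out["a"]) == list(range(1, 109))

    def test_gaussian_column_unchanged(self):
        rng = np.random.default_rng(3)
        panel = pd.DataFrame({"a": rng.standard_normal(100)})
        out = rank_transform_panel(panel)
        assert np.array_equal(out["a"], panel["a"])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(size=60)
        r1 = rank_transform_panel(pd.DataFrame({"a": x}))
        r2 = rank_transform_panel(pd.DataFrame({"a": np.exp(x)}))
        assert np.array_equal(r1["a"], r2["a"])

    def test_ties_get_averaged_ranks(self):
        x = np.r_[np.zeros(30), np.ones(30), np.linspace(5, 9, 10)]
        out = rank_transform_panel(pd.DataFrame({"a": x}))
        assert out["a"][0] == pytest.approx(15.5)

    def test_constant_column_skipped_with_warning(self):
        panel = pd.DataFrame({"a": np.ones(20)})
        with pytest.warns(UserWarning, match="constant"):
            out = rank_transform_panel(panel)
        assert np.array_equal(out["a"], panel["a"])


class TestManova:
    def _toy(self, seed=0, shift=1.0, n=30, p=3):
        rng = np.random.default_rng(seed)
        Y = rng.standard_normal((2 * n, p))
        Y[:n] += shift
        g = np.array(["a"] * n + ["b"] * n)
        return pd.DataFrame(Y, columns=[f"v{j}" for j in range(p)]), g

    def test_wilks_matches_determinant_ratio(self):
        panel, g = self._toy()
        res = manova(panel, g)
        Y = panel.to_numpy()
        grand = Y.mean(0)
        H = sum(len(Y[g == lv]) * np.outer(Y[g == lv].mean(0) - grand,
                                           Y[g == lv].mean(0) - grand)
                for lv in ("a", "b"))
        E = sum((Y[g == lv] - Y[g == lv].mean(0)).T
                @ (Y[g == lv] - Y[g == lv].mean(0)) for lv in ("a", "b"))
        assert res.wilks_lambda == pytest.approx(
            np.linalg.det(E) / np.linalg.det(E + H), rel=1e-10)

    def test_matches_statsmodels(self):
        from statsmodels.multivariate.manova import MANOVA

        panel, g = self._toy(seed=5)
        res = manova(panel, g)
        df = panel.copy()
        df["group"] = g
        sm = MANOVA.from_formula("v0 + v1 + v2 ~ group", data=df)
        tab = sm.mv_test().results["group"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(tab.loc["Wilks' lambda", "Value"]), rel=1e-8)
        assert res.f_approx == pytest.approx(
            float(tab.loc["Wilks' lambda", "F Value"]), rel=1e-6)

    def test_two_group_eta_squared_identity(self):
        panel, g = self._toy(seed=6)
        res = manova(panel, g)
        assert res.partial_eta2 == pytest.approx(1.0 - res.wilks_lambda,
                                                 rel=1e-12)

    def test_univariate_follow_up_matches_summary_form(self):
        panel, g = self._toy(seed=7)
        res = manova(panel, g)
        a, b = panel[g == "a"]["v0"], panel[g == "b"]["v0"]
        f_ref, _ = pooled_anova_f_from_summary(_summary(a), _summary(b))
        assert res.univariate.loc["v0", "F"] == pytest.approx(f_ref, rel=1e-9)

    def test_bonferroni_caps_and_dominates_raw(self):
        panel, g = self._toy(seed=8, shift=0.1)
        res = manova(panel, g)
        uni = res.univariate
        assert (uni["p_bonferroni"] >= uni["p_raw"] - 1e-15).all()
        assert (uni["p_bonferroni"] <= 1.0).all()

    def test_constant_covariates_equal_plain_manova(self):
        panel, g = self._toy(seed=9)
        plain = manova(panel, g)
        with_cov = manova(panel, g, covariates=np.ones((len(panel), 2)))
        assert with_cov.wilks_lambda == pytest.approx(plain.wilks_lambda,
                                                      rel=1e-12)

    def test_covariate_residualization_changes_test(self):
        rng = np.random.default_rng(10)
        panel, g = self._toy(seed=10)
        cov = panel["v0"].to_numpy() + rng.standard_normal(len(panel))
        res = manova(panel, g, covariates=cov)
        plain = manova(panel, g)
        assert res.wilks_lambda != pytest.approx(plain.wilks_lambda)

    def test_null_rejection_rate_near_nominal(self):
        # label-permutation null: ~5% rejections at alpha = .05
        rej = 0
        n_rep = 500
        for seed in range(n_rep):
            panel, g = self._toy(seed=seed, shift=0.0, n=25)
            rej += manova(panel, g).p_value < 0.05
        assert 0.02 <= rej / n_rep <= 0.08

    def test_singular_error_matrix_reported(self):
        panel, g = self._toy(seed=11)
        panel["v1"] = panel["v0"]
        with pytest.raises(np.linalg.LinAlgError):
            manova(panel, g)

    def test_too_few_observations_rejected(self):
        panel, g = self._toy(seed=12, n=2, p=3)
        with pytest.raises(ValueError):
            manova(panel, g)


class TestSpearmanBootstrap:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        res = spearman_bootstrap(x, x ** 3, n_boot=200, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(13)
        x, y = rng.standard_normal((2, 56))
        a = spearman_bootstrap(x, y, seed=42)
        b = spearman_bootstrap(x, y, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_null_correlations_stay_small(self):
        rng = np.random.default_rng(14)
        small = 0
        for _ in range(100):
            x, y = rng.standard_normal((2, 56))
            small += abs(sps.spearmanr(x, y).statistic) < 0.3
        assert small >= 95

    def test_ci_brackets_rho(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(56)
        y = 0.5 * x + rng.standard_normal(56)
        res = spearman_bootstrap(x, y, seed=1)
        assert res.ci_low <= res.rho <= res.ci_high

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_bootstrap(np.ones(10), np.arange(10.0))


class TestFisherZ:
    def test_closed_form_value(self):
        # atanh(-0.45) / sqrt(1/53 + 1/49)
        expected = np.arctanh(-0.45) / np.sqrt(1 / 53 + 1 / 49)
        z = fisher_z_compare(-0.45, 56, 0.0, 52)
        assert z == pytest.approx(expected, rel=1e-12)
        assert z == pytest.approx(-2.446, abs=0.01)

    def test_equal_correlations_give_zero(self):
        assert fisher_z_compare(0.3, 40, 0.3, 50) == 0.0

    def test_antisymmetry(self):
        assert fisher_z_compare(0.5, 30, 0.2, 40) == pytest.approx(
            -fisher_z_compare(0.2, 40, 0.5, 30))

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 30, 0.0, 30)


class TestBMIChangeRate:
    def test_reference_value(self):
        assert round(bmi_change_rate(20.37, 40.01), 2) == 0.51

    @pytest.mark.parametrize("delta,days,expected", [(0.0, 17.0, 0.0),
                                                     (3.2, 1.0, 3.2)])
    def test_simple_cases(self, delta, days, expected):
        assert bmi_change_rate(delta, days) == expected

    def test_nonpositive_days_rejected(self):
        with pytest.raises(ValueError):
            bmi_change_rate(1.0, 0.0)
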