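import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from afconn.scores import (
    behavioral_screen,
    critical_r,
    fit_score,
    icc_2_1,
    score_cohort,
)


class TestFitScore:
    def test_identity_fit(self, rng):
        x = rng.normal(size=50)
        fit = fit_score(x, x)
        assert np.isclose(fit.beta, 1.0) and np.isclose(fit.alpha, 0.0, atol=1e-12)

    def test_exact_affine(self, rng):
        x = rng.normal(size=50)
        fit = fit_score(2 * x + 3, x)
        assert np.isclose(fit.beta, 2.0) and np.isclose(fit.alpha, 3.0)
        assert fit.residual_variance < 1e-20

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=200)
        y = 0.7 * x + rng.normal(scale=0.5, size=200)
        fit = fit_score(y, x)
        X = np.column_stack([np.ones(200), x])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.isclose(fit.alpha, beta_oracle[0], atol=1e-10)
        assert np.isclose(fit.beta, beta_oracle[1], atol=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=100)
        y = rng.normal(size=100)
        fit = fit_score(y, x)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert np.isclose(fit.beta, ref.params[1], atol=1e-10)

    def test_constant_template_raises(self):
        with pytest.raises(ValueError, match="constant"):
            fit_score(np.arange(5.0), np.ones(5))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        scale=st.floats(0.1, 10),
        shift=st.floats(-5, 5),
        seed=st.integers(0, 1000),
    )
    def test_scale_equivariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = fit_score(y, x)
        scaled = fit_score(scale * y + shift, x)
        assert np.isclose(scaled.beta, scale * base.beta, rtol=1e-9)
        assert np.isclose(scaled.alpha, scale * base.alpha + shift, rtol=1e-7, atol=1e-9)

    def test_group_mean_scores_average_to_one(self, rng):
        """Template = group mean: regression slopes average ~1 by construction."""
        vecs = rng.normal(size=(20, 100)) + rng.normal(size=(20, 1)) * np.linspace(
            -1, 1, 100
        )
        scores = score_cohort(vecs)
        template = vecs.mean(axis=0)
        assert np.isclose(fit_score(template, template).beta, 1.0)
        assert abs(scores.mean() - 1.0) < 0.2


class TestICC:
    def test_identical_raters(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        res = icc_2_1(x)
        assert np.isclose(res.icc, 1.0)

    def test_matches_longhand_anova_oracle(self):
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0]])
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        # longhand: SSE = SST - SSR - SSC
        sst = ((x - grand) ** 2).sum()
        ssr = k * ((x.mean(axis=1) - grand) ** 2).sum()
        ssc = n * ((x.mean(axis=0) - grand) ** 2).sum()
        mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        res = icc_2_1(x)
        assert np.isclose(res.icc, expected, atol=1e-12)

    def test_offset_penalized(self, rng):
        base = rng.normal(size=(20, 2))
        base[:, 1] = base[:, 0] + rng.normal(scale=0.1, size=20)
        res0 = icc_2_1(base)
        shifted = base.copy()
        shifted[:, 1] += 1.0
        assert icc_2_1(shifted).icc < res0.icc

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        x = rng.normal(size=(15, 3)) + rng.normal(size=(15, 1))
        res = icc_2_1(x)
        long = pd.DataFrame(
            {
                "target": np.repeat(np.arange(15), 3),
                "rater": np.tile(np.arange(3), 15),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="target", raters="rater", ratings="score")
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])  # label differs by version
        row = ref[mask].iloc[0]
        assert np.isclose(res.icc, row["ICC"], atol=1e-8)
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        lo, hi = row[ci_col]
        assert np.isclose(res.ci_low, lo, atol=0.02)  # pingouin rounds its CI
        assert np.isclose(res.ci_high, hi, atol=0.02)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            icc_2_1(np.ones((5, 2)))

    def test_recovers_variance_ratio(self, rng):
        """ICC(2,1) estimates sigma_b^2 / (sigma_b^2 + sigma_w^2)."""
        sigma_b, sigma_w = 1.0, 0.5
        subj = rng.normal(0, sigma_b, size=(500, 1))
        x = subj + rng.normal(0, sigma_w, size=(500, 2))
        expected = sigma_b**2 / (sigma_b**2 + sigma_w**2)
        assert abs(icc_2_1(x).icc - expected) < 0.05


class TestBehavioralScreen:
    def test_identical_covariate(self, rng):
        s = rng.normal(size=30)
        cov = pd.DataFrame({"same": s})
        rep = behavioral_screen(s, cov)
        assert np.isclose(rep.loc["same", "statistic"], 1.0)
        assert rep.loc["same", "p"] < 1e-20
        assert rep.loc["same", "significant"]

    def test_equal_group_means_give_zero_f(self, rng):
        s = rng.normal(size=30)
        groups = np.array(["a", "b", "c"] * 10)
        for g in "abc":  # center each group: between-group variance exactly 0
            s[groups == g] -= s[groups == g].mean()
        rep = behavioral_screen(s, pd.DataFrame({"grp": groups}))
        assert rep.loc["grp", "kind"] == "categorical"
        assert np.isclose(rep.loc["grp", "statistic"], 0.0, atol=1e-20)
        assert not rep.loc["grp", "significant"]

    def test_anova_matches_longhand_oracle(self, rng):
        groups = np.repeat(["a", "b", "c"], 10)
        s = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(2, 1, 10), rng.normal(4, 1, 10)]
        )
        rep = behavioral_screen(s, pd.DataFrame({"grp": groups}))
        # longhand between/within sums of squares
        grand = s.mean()
        ss_between = sum(
            10 * (s[groups == g].mean() - grand) ** 2 for g in "abc"
        )
        ss_within = sum(
            ((s[groups == g] - s[groups == g].mean()) ** 2).sum() for g in "abc"
        )
        f_expected = (ss_between / 2) / (ss_within / 27)
        assert np.isclose(rep.loc["grp", "statistic"], f_expected, atol=1e-10)

    def test_missing_values_pairwise_deletion(self, rng):
        s = rng.normal(size=20)
        cov = pd.DataFrame({"v": np.where(np.arange(20) < 5, np.nan, s)})
        rep = behavioral_screen(s, cov)
        assert rep.loc["v", "n_used"] == 15

    def test_constant_variable_skipped_with_warning(self, rng):
        s = rng.normal(size=10)
        cov = pd.DataFrame({"const": np.ones(10), "ok": rng.normal(size=10)})
        with pytest.warns(UserWarning, match="const"):
            rep = behavioral_screen(s, cov)
        assert "const" not in rep.index
        assert "ok" in rep.index

    def test_bonferroni_m_defaults_to_tested_count(self, rng):
        s = rng.normal(size=40)
        cov = pd.DataFrame({f"v{i}": rng.normal(size=40) for i in range(5)})
        cov["near"] = s + rng.normal(scale=2.0, size=40)
        rep = behavioral_screen(s, cov, alpha=0.05)
        # the implied threshold is alpha / 6
        for name in rep.index:
            assert rep.loc[name, "significant"] == (rep.loc[name, "p"] < 0.05 / 6)


class TestCriticalR:
    def test_study_scale_value(self):
        # 423 subjects, 735 variables screened: threshold just above 0.19
        assert abs(critical_r(423, 735, 0.05) - 0.193) <= 0.002

    def test_t_quantile_oracle(self):
        t = stats.t.ppf(1 - 0.05 / 2, 23)
        expected = t / np.sqrt(t**2 + 23)
        assert np.isclose(critical_r(25, 1, 0.05), expected, atol=1e-12)
        assert np.isclose(t, 2.0687, atol=5e-4)
        assert np.isclose(expected, 0.396, atol=5e-4)

    def test_monotonicity(self):
        ns = [10, 50, 100, 400]
        vals = [critical_r(n, 1, 0.05) for n in ns]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        ms = [1, 10, 100, 735]
        vals_m = [critical_r(100, m, 0.05) for m in ms]
        assert all(a < b for a, b in zip(vals_m, vals_m[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            critical_r(3, 1, 0.05)
        with pytest.raises(ValueError):
            critical_r(10, 0, 0.05)
        with pytest.raises(ValueError):
            critical_r(10, 1, 1.5)
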