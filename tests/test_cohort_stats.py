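"""Group comparisons, ANCOVA, matching and standardized regression."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from podovat.cohort import (
    MODEL_COVARIATES,
    ancova_emm,
    compare_groups,
    delta_egfr,
    propensity_match,
    residual_diagnostics,
    standardized_regression,
    zscore,
)
from podovat.synthetic import SyntheticCohortSpec, simulate_cohort


class TestDeltaEGFR:
    def test_printed_group_means(self):
        delta, rel = delta_egfr(78.0, 54.0)
        assert delta == pytest.approx(-24.0)
        assert rel == pytest.approx(-30.8, abs=0.05)
        assert round(rel) == -31

    def test_equal_values(self):
        assert delta_egfr(60.0, 60.0) == (0.0, 0.0)

    def test_antisymmetric(self):
        d1, _ = delta_egfr(78.0, 54.0)
        d2, _ = delta_egfr(54.0, 78.0)
        assert d1 == -d2

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            delta_egfr(0.0, 50.0)

    def test_vectorized(self):
        d, r = delta_egfr(np.array([80.0, 50.0]), np.array([60.0, 55.0]))
        assert d == pytest.approx([-20.0, 5.0])
        assert r == pytest.approx([-25.0, 10.0])


class TestCompareGroups:
    def test_identical_flat_groups(self):
        values = np.array([5.0] * 6 + [5.0] * 6)
        group = np.array([0] * 6 + [1] * 6)
        ordinal = compare_groups(values, group, mode="ordinal")
        assert ordinal.p_value == pytest.approx(1.0)

    def test_equal_means_zero_t(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        group = np.array([0, 0, 0, 1, 1, 1])
        res = compare_groups(values, group, mode="continuous")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_pooled_t_matches_closed_form(self):
        # hand-computable 3-point vectors with equal variances
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        res = compare_groups(np.r_[a, b], np.r_[0, 0, 0, 1, 1, 1], mode="continuous")
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2.0  # pooled, equal n
        t_closed = (a.mean() - b.mean()) / math.sqrt(sp2 * (2.0 / 3.0))
        assert res.test_name == "t (pooled)"
        assert res.statistic == pytest.approx(t_closed)
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(abs(t_closed), df=4), rel=1e-12
        )

    def test_levene_gate_switches_to_welch(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 200)
        b = rng.normal(0.0, 8.0, 200)
        res = compare_groups(np.r_[a, b], np.r_[np.zeros(200), np.ones(200)],
                             mode="continuous")
        assert res.levene_p < 0.05
        assert res.test_name == "t (Welch)"

    def test_density_difference_power(self):
        # Table-2-like density means/SDs at n = 17 vs 35 should be
        # detected by the gated t test in >= 80% of replicates
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            a = rng.normal(243.0, 59.0, 17)
            b = rng.normal(194.0, 50.0, 35)
            res = compare_groups(np.r_[a, b], np.r_[np.zeros(17), np.ones(35)],
                                 mode="continuous")
            hits += res.p_value < 0.05
        assert hits / n_rep >= 0.80

    def test_sex_contingency_example(self):
        # 15/17 vs 8/35 female
        female = np.r_[np.ones(15), np.zeros(2), np.ones(8), np.zeros(27)]
        group = np.r_[np.zeros(17), np.ones(35)]
        res = compare_groups(female, group, mode="nominal")
        assert res.p_value < 0.001

    def test_errors(self):
        with pytest.raises(ValueError):
            compare_groups(np.array([1.0, 2.0]), np.array([0, 0]), mode="continuous")
        with pytest.raises(ValueError):
            compare_groups(np.array([1.0, 2.0]), np.array([0, 1]), mode="bogus")


class TestAncova:
    def _balanced(self, effect=0.0, n=40, seed=0):
        rng = np.random.default_rng(seed)
        half = n // 2
        cov = rng.normal(25.0, 2.0, half)
        return pd.DataFrame({
            "vo": np.r_[np.zeros(half), np.ones(half)],
            "bmi": np.r_[cov, cov],  # identical covariates in both groups
            "age": np.r_[np.full(half, 60.0), np.full(half, 60.0)],
            "y": np.r_[rng.normal(2.0, 0.1, half), rng.normal(2.0 + effect, 0.1, half)],
        })

    def test_reduces_to_raw_means_when_balanced(self):
        df = self._balanced(effect=0.6)
        res = ancova_emm(df, "y", "vo")
        raw = df.groupby("vo")["y"].mean()
        for row in res.emms.itertuples():
            assert row.emm == pytest.approx(raw[row.group], abs=1e-9)

    def test_recovers_built_in_group_effect(self):
        df = self._balanced(effect=0.6, n=120, seed=1)
        res = ancova_emm(df, "y", "vo")
        diff = res.emms.emm.iloc[1] - res.emms.emm.iloc[0]
        assert diff == pytest.approx(0.6, abs=0.1)
        assert res.p_group < 0.001

    def test_confounded_null_not_flagged(self):
        # no group effect: y depends on BMI only, BMI differs by group
        rng = np.random.default_rng(2)
        n = 200
        vo = np.r_[np.zeros(n), np.ones(n)]
        bmi = np.where(vo == 1, rng.normal(26.0, 2.0, 2 * n), rng.normal(23.0, 2.0, 2 * n))
        y = 0.2 * bmi + rng.normal(0, 0.3, 2 * n)
        df = pd.DataFrame({"vo": vo, "bmi": bmi, "age": rng.normal(65, 10, 2 * n), "y": y})
        res = ancova_emm(df, "y", "vo")
        assert res.p_group > 0.05
        assert res.p_covariates["bmi"] < 0.001

    def test_collinear_covariate_named(self):
        df = self._balanced()
        df["age"] = df["bmi"] * 2.0
        with pytest.raises(ValueError, match="rank deficient"):
            ancova_emm(df, "y", "vo", covariates=("bmi", "age"))


class TestPropensityMatch:
    def test_identical_distributions_balanced(self):
        bmi = np.linspace(20, 30, 20)
        df = pd.DataFrame({"vo": np.r_[np.zeros(20), np.ones(20)],
                           "bmi": np.r_[bmi, bmi]})
        res = propensity_match(df, seed=0)
        assert len(res.pairs) == 20
        assert res.balance_after.p_value > 0.99

    def test_pair_count_is_min_group_size(self, default_cohort):
        res = propensity_match(default_cohort, seed=0)
        assert len(res.pairs) == 17

    def test_controls_never_reused(self, default_cohort):
        res = propensity_match(default_cohort, seed=3)
        treated = [t for t, _ in res.pairs]
        controls = [c for _, c in res.pairs]
        assert len(set(treated)) == len(treated)
        assert len(set(controls)) == len(controls)

    def test_bmi_difference_attenuated(self):
        df = simulate_cohort(SyntheticCohortSpec(seed=1))
        res = propensity_match(df, seed=1)
        before = abs(res.balance_before.group_summaries["mean"].diff().iloc[-1])
        after = abs(res.balance_after.group_summaries["mean"].diff().iloc[-1])
        assert after <= 0.5 * before

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"vo": [1, 1], "bmi": [24.0, 25.0]})
        with pytest.raises(ValueError):
            propensity_match(df)


class TestStandardizedRegression:
    def test_identity_outcome(self, default_cohort):
        df = default_cohort.assign(self_outcome=default_cohort["glomerular_volume"])
        res = standardized_regression(df, "glomerular_volume", "self_outcome")
        assert res.standardized_beta == pytest.approx(1.0, abs=1e-12)

    def test_unadjusted_beta_equals_pearson_r(self, default_cohort):
        sub = default_cohort.dropna(subset=["egfr_12m"])
        delta = sub["egfr_12m"] - sub["egfr_baseline"]
        r = np.corrcoef(sub["glomerular_volume"], delta)[0, 1]
        res = standardized_regression(default_cohort, "glomerular_volume", "delta_egfr")
        assert res.standardized_beta == pytest.approx(r, abs=1e-10)
        assert res.n == len(sub)

    def test_parameter_recovery(self):
        spec = SyntheticCohortSpec.homogeneous(
            500, effect_beta=-0.43, effect_predictor="nuclear_volume", seed=17)
        df = simulate_cohort(spec)
        res = standardized_regression(df, "nuclear_volume", "delta_egfr")
        assert -0.50 <= res.standardized_beta <= -0.36
        assert res.p_value < 0.001

    def test_null_predictor(self):
        spec = SyntheticCohortSpec.homogeneous(500, effect_beta=0.0, seed=23)
        df = simulate_cohort(spec)
        res = standardized_regression(df, "podocyte_density", "delta_egfr")
        assert abs(res.standardized_beta) < 0.1

    @pytest.mark.parametrize("model", ["1", "2", "3", "4"])
    def test_adjusted_models_run(self, default_cohort, model):
        res = standardized_regression(default_cohort, "glomerular_volume",
                                      "relative_delta_egfr", model)
        assert res.model_id == model
        assert -1.0 <= res.standardized_beta <= 1.0
        assert 0.0 <= res.p_value <= 1.0

    def test_underdetermined_rejected(self, default_cohort):
        tiny = default_cohort.head(6)
        with pytest.raises(ValueError, match="parameters"):
            standardized_regression(tiny, "glomerular_volume", "delta_egfr", "2")

    def test_unknown_model_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="unknown model"):
            standardized_regression(default_cohort, "glomerular_volume",
                                    "delta_egfr", "5")

    def test_model_covariate_sets(self):
        assert MODEL_COVARIATES["unadjusted"] == ()
        assert "log_vat" in MODEL_COVARIATES["1"]
        assert len(MODEL_COVARIATES["4"]) == 5


class TestStandardization:
    def test_zscore_moments(self):
        rng = np.random.default_rng(5)
        z = zscore(rng.normal(50.0, 7.0, 1000))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.full(10, 3.0))


class TestResidualDiagnostics:
    def test_perfect_fit_has_zero_residuals(self):
        import statsmodels.api as sm

        x = np.arange(20.0)
        fit = sm.OLS(2.0 * x + 1.0, sm.add_constant(x)).fit()
        rep = residual_diagnostics(fit)
        assert np.allclose(rep.table["residual"], 0.0, atol=1e-10)
        assert not rep.heteroscedastic

    def test_heteroscedasticity_flagged(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        x = np.linspace(1.0, 10.0, 300)
        y = x + rng.normal(0.0, 0.05 + 0.3 * x, 300)
        rep = residual_diagnostics(sm.OLS(y, sm.add_constant(x)).fit())
        assert rep.tercile_spread_ratio > 2.0
        assert rep.heteroscedastic

    def test_leave_one_out_delta_reported(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        x = np.linspace(0.0, 1.0, 50)
        y = x + rng.normal(0.0, 0.05, 50)
        y[10] += 2.0  # gross outlier
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        rep = residual_diagnostics(fit)
        assert rep.max_residual_index == 10
        assert rep.loo_beta_delta is not None and rep.loo_beta_delta != 0.0
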