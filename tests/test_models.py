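"""GLM fitting with subject-clustered sandwich errors, the familywise gate,
ratio reporting and pooled analysis."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import dietclust as dc
from dietclust.models import _build_design


def sandwich_oracle(x, y, groups):
    """Independent long-hand cluster-robust covariance:
    c * (X'X)^-1 (sum_g X_g' u_g u_g' X_g) (X'X)^-1,
    c = G/(G-1) * (N-1)/(N-p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    u = y - x @ beta
    meat = np.zeros((x.shape[1], x.shape[1]))
    for g in np.unique(groups):
        xg = x[groups == g]
        ug = u[groups == g]
        s = xg.T @ ug
        meat += np.outer(s, s)
    n, p = x.shape
    ng = len(np.unique(groups))
    c = ng / (ng - 1) * (n - 1) / (n - p)
    return beta, c * xtx_inv @ meat @ xtx_inv


def model_data(n=200, effects=(), seed=29, rates=None):
    cfg = dc.GeneratorConfig(n_subjects=n, n_fa_clusters=4, n_spread_clusters=8,
                             effect_table=effects, missing_rates=rates or {}, seed=seed)
    cohort = dc.derive_outcomes(dc.generate_cohort(cfg))
    truth_fa = dc.planted_truth(cohort, "fa")
    truth_sp = dc.planted_truth(cohort, "spread")
    cohort["fa_cluster"] = cohort["subject_id"].map(truth_fa)
    cohort["spread_cluster"] = cohort["subject_id"].map(truth_sp)
    return cohort


class TestFitGlm:
    def test_sandwich_matches_long_hand_oracle(self):
        data = model_data()
        spec = dc.ModelSpec("derived_sbp", "identity", adjust=["age", "waist_hip_ratio"])
        fit = dc.fit_glm(data, spec)
        y, x, _, _ = _build_design(data, spec)
        beta, cov = sandwich_oracle(x.to_numpy(), y, data["subject_id"].to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-10)
        np.testing.assert_allclose(fit.cov.to_numpy(), cov, rtol=1e-8)
        # positive semi-definite
        assert np.linalg.eigvalsh(fit.cov.to_numpy()).min() > -1e-12

    def test_singleton_groups_reduce_to_hc1(self):
        data = model_data(n=150)
        v1 = data[data["visit"] == "age20"].copy()
        spec = dc.ModelSpec("derived_sbp", "identity")
        fit = dc.fit_glm(v1, spec)
        y, x, _, _ = _build_design(v1, spec)
        hc1 = sm.OLS(y, x).fit(cov_type="HC1")
        np.testing.assert_allclose(fit.cov.to_numpy(), hc1.cov_params().to_numpy(), rtol=1e-8)

    def test_duplicated_rows_leave_point_estimates_unchanged(self):
        data = model_data(n=120)
        v1 = data[data["visit"] == "age20"]
        doubled = pd.concat([v1, v1], ignore_index=True)
        spec = dc.ModelSpec("derived_sbp", "identity")
        f1 = dc.fit_glm(v1, spec)
        f2 = dc.fit_glm(doubled, spec)
        np.testing.assert_allclose(f1.params, f2.params, rtol=1e-10)

    def test_planted_effect_recovered(self):
        eff = (dc.EffectSpec("spread", 2, "sbp", 5.0),)
        data = model_data(n=800, effects=eff, seed=41)
        fit = dc.fit_glm(data, dc.ModelSpec("derived_sbp", "identity"))
        col = "spread_cluster[2]"
        est = fit.params[col]
        se = np.sqrt(fit.cov.loc[col, col])
        assert abs(est - 5.0) < 2 * se

    def test_log_scale_outcome(self):
        eff = (dc.EffectSpec("spread", 3, "triglycerides", np.log(1.3)),)
        data = model_data(n=800, effects=eff, seed=43)
        fit = dc.fit_glm(data, dc.ModelSpec("triglycerides", "log"))
        col = "spread_cluster[3]"
        rep = dc.ratio_report(fit.params[col], np.sqrt(fit.cov.loc[col, col]))
        assert rep["ci_lo"] < 1.3 < rep["ci_hi"]

    def test_singular_design_names_columns(self):
        data = model_data(n=100)
        data["copy_age"] = data["age"]
        spec = dc.ModelSpec("derived_sbp", adjust=["age", "copy_age"])
        with pytest.raises(ValueError, match="singular design"):
            dc.fit_glm(data, spec)

    def test_estimates_invariant_to_cluster_relabeling(self):
        data = model_data(n=200)
        relab = data.copy()
        mapping = {0: 3, 1: 2, 2: 1, 3: 0}
        relab["fa_cluster"] = relab["fa_cluster"].map(mapping)
        f1 = dc.fit_glm(data, dc.ModelSpec("derived_sbp", fa_ref=0))
        f2 = dc.fit_glm(relab, dc.ModelSpec("derived_sbp", fa_ref=3))
        for old, new in mapping.items():
            if old == 0:
                continue
            np.testing.assert_allclose(f1.params[f"fa_cluster[{old}]"],
                                       f2.params[f"fa_cluster[{new}]"], rtol=1e-10)


class TestRatioReport:
    def test_zero_is_unity(self):
        rep = dc.ratio_report(0.0, 0.1)
        assert rep["ratio"] == pytest.approx(1.0)
        assert rep["pct_change"] == pytest.approx(0.0)

    def test_reporting_transform_inverts_percent(self):
        rep = dc.ratio_report(np.log(1.264), 0.05)
        assert rep["pct_change"] == pytest.approx(26.4)

    def test_negative_log_ratio(self):
        rep = dc.ratio_report(-np.log(1.25), 0.05)
        assert rep["pct_change"] == pytest.approx(-20.0)
        z = 1.959963984540054
        assert rep["ci_lo"] == pytest.approx(np.exp(-np.log(1.25) - z * 0.05))
        assert rep["ci_hi"] == pytest.approx(np.exp(-np.log(1.25) + z * 0.05))


class TestFamilywiseGate:
    def test_single_level_factor_rejected(self):
        data = model_data(n=100)
        data["fa_cluster"] = 0  # degenerate: reference only
        fit = dc.fit_glm(data, dc.ModelSpec("derived_sbp"))
        with pytest.raises(ValueError, match="no non-reference"):
            dc.familywise_gate(fit, "fa_cluster")

    def test_strong_effect_passes_and_contrasts_inferential(self):
        eff = (dc.EffectSpec("spread", 2, "sbp", 8.0),)
        data = model_data(n=600, effects=eff, seed=47)
        fit = dc.fit_glm(data, dc.ModelSpec("derived_sbp"))
        gate = dc.familywise_gate(fit, "spread_cluster")
        assert gate["passed"] and gate["p"] < 0.001
        assert gate["contrasts"]["inferential"].all()
        assert gate["df"] == 7


class TestRunAnalysis:
    def test_complete_data_stack_equals_single_fit(self):
        data = model_data(n=200)
        spec = dc.ModelSpec("derived_sbp", "identity", name="model1")
        stack = dc.impute(data, dc.ImputationSpec(m=3, seed=0))
        pooled = dc.run_analysis(stack, [spec], sexes=("male",))
        fit = dc.fit_glm(data[data["sex"] == "male"], spec)
        row = pooled[(pooled["factor"] == "spread_cluster") & (pooled["cluster"] == 2)].iloc[0]
        assert row["estimate"] == pytest.approx(fit.params["spread_cluster[2]"], rel=1e-10)

    def test_sex_specific_effect_detected_only_in_males(self):
        eff = (dc.EffectSpec("spread", 2, "sbp", 8.0, "male"),)
        data = model_data(n=1500, effects=eff, seed=53)
        pooled = dc.run_analysis([data], [dc.ModelSpec("derived_sbp")])
        male = pooled[(pooled["sex"] == "male") & (pooled["factor"] == "spread_cluster")]
        female = pooled[(pooled["sex"] == "female") & (pooled["factor"] == "spread_cluster")]
        assert male["gate_p"].iloc[0] < 0.01
        est = male[male["cluster"] == 2].iloc[0]
        assert abs(est["estimate"] - 8.0) < 3 * est["se"]
        assert female[female["cluster"] == 2]["p"].iloc[0] > 0.001  # no planted female effect

    def test_log_outcome_reports_percent_change(self):
        eff = (dc.EffectSpec("spread", 3, "triglycerides", np.log(1.3)),)
        data = model_data(n=800, effects=eff, seed=59)
        pooled = dc.run_analysis([data], [dc.ModelSpec("triglycerides", "log")])
        row = pooled[(pooled["factor"] == "spread_cluster") & (pooled["cluster"] == 3)
                     & (pooled["sex"] == "male")].iloc[0]
        assert row["ci_lo"] < 1.3 < row["ci_hi"]
        assert row["pct_change"] == pytest.approx(100 * (row["ratio"] - 1))
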