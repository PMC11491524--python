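"""Mixed-model engine: scaler, design, and fits checked against independent oracles."""
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla
import statsmodels.api as sm
from scipy.special import expit

from forayfit.mixedmodels import (
    AGE_SEX_LEVELS,
    FitControls,
    FitResult,
    TemperatureScaler,
    build_frame,
    design_matrices,
    fit_offterritory_glmm,
    fit_visits_lmm,
    fitted_values,
)


def make_frame(rng, n_birds=30, n_days=12, n_feeders=4, v_bird=1.0, v_feeder=0.3,
               betas=None, family="binomial", v_resid=1.0):
    """Simulate a modeling frame directly at the linear-predictor level."""
    betas = betas or {}
    intercepts = betas.get("int", {"FJ": -1.0, "FA": -1.5, "MJ": -1.2, "MA": -2.0})
    slopes = betas.get("slope", {"FJ": -0.5, "FA": -0.7, "MJ": 0.2, "MA": 0.0})
    birds = [f"B{i:02d}" for i in range(n_birds)]
    feeders = [f"F{j:02d}" for j in range(n_feeders)]
    age_sex = rng.choice(AGE_SEX_LEVELS, n_birds)
    core = rng.choice(feeders, n_birds)
    b = rng.normal(0, np.sqrt(v_bird), n_birds)
    f = dict(zip(feeders, rng.normal(0, np.sqrt(v_feeder), n_feeders)))
    temp = rng.uniform(0, 3.5, n_days)
    rows = []
    for i in range(n_birds):
        for d in range(n_days):
            eta = intercepts[age_sex[i]] + slopes[age_sex[i]] * temp[d] + b[i] + f[core[i]]
            if family == "binomial":
                y = int(rng.random() < expit(eta))
                rows.append((birds[i], core[i], age_sex[i], temp[d], y, 5.0))
            else:
                y = eta + rng.normal(0, np.sqrt(v_resid))
                rows.append((birds[i], core[i], age_sex[i], temp[d], 0, y))
    return pd.DataFrame(
        rows, columns=["bird", "core", "age_sex", "temp_scaled", "off_territory", "sqrt_visits"]
    )


class TestTemperatureScaler:
    def test_left_zero_at_minimum(self):
        s = TemperatureScaler.fit([-17.1, -5.0, 4.7])
        assert s.transform(-17.1) == 0.0

    def test_one_unit_equals_one_sd(self, rng):
        x = rng.normal(-6, 5.74, 200)
        s = TemperatureScaler.fit(x, multiplier=1)
        assert s.transform(x.min() + s.sd) == pytest.approx(1.0)
        s2 = TemperatureScaler.fit(x, multiplier=2)
        assert s2.transform(x.min() + s.sd) == pytest.approx(0.5)

    def test_round_trip(self, rng):
        x = rng.normal(0, 5, 50)
        s = TemperatureScaler.fit(x)
        np.testing.assert_allclose(s.inverse_transform(s.transform(x)), x, atol=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            TemperatureScaler.fit([1.0, 1.0, 1.0])


class TestBuildFrame:
    def test_sqrt_visits_and_level_constancy(self, small_frame):
        sq = small_frame["sqrt_visits"].to_numpy()
        assert np.allclose(np.round(sq**2), sq**2, atol=1e-9)
        per_bird = small_frame.groupby("bird")["age_sex"].nunique()
        assert (per_bird == 1).all()

    def test_row_count_matches_retained_bird_days(self, small_frame, small_table):
        from forayfit.ingest import apply_mortality_rule

        table = apply_mortality_rule(small_table)
        assert len(small_frame) == int((table.total_visits > 0).sum())


class TestBinomialGLMM:
    def test_zero_variance_matches_plain_logistic(self, rng):
        """Forcing V_bird = V_feeder = 0 must reproduce ordinary logistic ML."""
        frame = make_frame(rng, n_birds=25, n_days=10, v_bird=0.5, v_feeder=0.2)
        fit = fit_offterritory_glmm(
            frame, FitControls(fix_v_bird=0.0, fix_v_feeder=0.0)
        )
        X, names, _, _ = design_matrices(frame)
        sm_fit = sm.Logit(frame["off_territory"].to_numpy(), X).fit(disp=0, tol=1e-12)
        np.testing.assert_allclose(fit.beta, sm_fit.params, atol=1e-6)
        np.testing.assert_allclose(fit.loglik, sm_fit.llf, atol=1e-6)

    def test_null_generating_model_gives_boundary_variance(self, rng):
        frame = make_frame(
            rng, n_birds=40, n_days=10, v_bird=0.0, v_feeder=0.0,
            betas={"int": dict.fromkeys(AGE_SEX_LEVELS, -1.0),
                   "slope": dict.fromkeys(AGE_SEX_LEVELS, 0.0)},
        )
        fit = fit_offterritory_glmm(frame)
        assert fit.varcomp["V_bird"] < 0.05
        assert fit.varcomp["V_resid"] == 1.0
        # slope CrIs cover zero
        se = np.sqrt(np.diag(fit.beta_cov))
        for j, name in enumerate(fit.fixed_names):
            if name.endswith(":temp"):
                assert abs(fit.beta[j]) < 2.5 * se[j]

    def test_matches_lme4_glmer_laplace(self, rng, tmp_path):
        """Independent oracle: lme4::glmer (Laplace) on the identical frame."""
        frame = make_frame(rng, n_birds=30, n_days=15, v_bird=1.0, v_feeder=0.3)
        fit = fit_offterritory_glmm(frame)
        csv = tmp_path / "frame.csv"
        frame.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$age_sex <- factor(d$age_sex, levels=c("FJ","FA","MJ","MA"))
        m <- glmer(off_territory ~ 0 + age_sex + age_sex:temp_scaled + (1|bird) + (1|core),
                   data=d, family=binomial, control=glmerControl(optimizer="bobyqa"))
        cat(fixef(m), as.data.frame(VarCorr(m))$vcov, sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        r_beta, r_vc = np.array(vals[:8]), vals[8:]
        np.testing.assert_allclose(fit.beta, r_beta, atol=0.02)
        np.testing.assert_allclose(
            [fit.varcomp["V_bird"], fit.varcomp["V_feeder"]], r_vc, atol=0.05
        )


class TestGaussianLMM:
    def test_matches_gls_oracle_with_fixed_variances(self, rng):
        """<= 12 rows, variance components fixed at truth: beta must equal dense GLS."""
        frame = make_frame(rng, n_birds=4, n_days=3, n_feeders=2, family="gaussian",
                           v_bird=0.8, v_feeder=0.2, v_resid=0.5)
        vb, vf, ve = 0.8, 0.2, 0.5
        fit = fit_visits_lmm(
            frame, FitControls(fix_v_bird=vb, fix_v_feeder=vf, fix_v_resid=ve)
        )
        X, names, bird_cat, feeder_cat = design_matrices(frame)
        y = frame["sqrt_visits"].to_numpy()
        n = len(y)
        Zb = np.eye(len(bird_cat.categories))[bird_cat.codes]
        Zf = np.eye(len(feeder_cat.categories))[feeder_cat.codes]
        V = ve * np.eye(n) + vb * Zb @ Zb.T + vf * Zf @ Zf.T
        Vi = np.linalg.inv(V)
        beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        np.testing.assert_allclose(fit.beta, beta_gls, atol=1e-8)

    def test_noise_free_linear_response_recovered_exactly(self, rng):
        frame = make_frame(rng, n_birds=20, n_days=8, family="gaussian",
                           v_bird=0.0, v_feeder=0.0, v_resid=1.0)
        ints = {"FJ": -1.0, "FA": -1.5, "MJ": -1.2, "MA": -2.0}
        slopes = {"FJ": -0.5, "FA": -0.7, "MJ": 0.2, "MA": 0.0}
        frame["sqrt_visits"] = [
            ints[a] + slopes[a] * t for a, t in zip(frame["age_sex"], frame["temp_scaled"])
        ]
        fit = fit_visits_lmm(frame)
        assert fit.varcomp["V_resid"] < 1e-6
        truth = [ints[l] for l in AGE_SEX_LEVELS] + [slopes[l] for l in AGE_SEX_LEVELS]
        np.testing.assert_allclose(fit.beta, truth, atol=1e-6)

    def test_matches_statsmodels_mixedlm_crossed_vc(self, rng):
        """Independent oracle: MixedLM with crossed variance components (REML)."""
        frame = make_frame(rng, n_birds=25, n_days=8, family="gaussian",
                           v_bird=1.0, v_feeder=0.3, v_resid=0.8)
        fit = fit_visits_lmm(frame)
        df = frame.assign(g=1)
        model = sm.MixedLM.from_formula(
            "sqrt_visits ~ 0 + C(age_sex) + C(age_sex):temp_scaled",
            groups="g",
            vc_formula={"bird": "0 + C(bird)", "core": "0 + C(core)"},
            data=df,
        )
        res = model.fit(reml=True, method="lbfgs", maxiter=500)
        np.testing.assert_allclose(np.sort(fit.beta), np.sort(res.fe_params.to_numpy()), atol=1e-3)
        np.testing.assert_allclose(fit.varcomp["V_bird"], res.vcomp[0], atol=1e-3)
        np.testing.assert_allclose(fit.varcomp["V_resid"], res.scale, atol=1e-3)

    def test_means_parameterization_invariance(self, rng):
        """Fitted values agree between means and reference/contrast codings."""
        frame = make_frame(rng, n_birds=20, n_days=8, family="gaussian")
        fit = fit_visits_lmm(frame)
        eta_means = fitted_values(fit, frame)
        X, names, bird_cat, feeder_cat = design_matrices(frame)
        T = np.eye(8)
        T[1:4, 0] = 1.0  # reference coding for intercepts
        T[5:8, 4] = 1.0  # and for slopes
        from forayfit.mixedmodels import _fit_lmm_gaussian

        fit2 = _fit_lmm_gaussian(
            frame["sqrt_visits"].to_numpy(), X @ T, names, bird_cat, feeder_cat, FitControls()
        )
        eta_ref = X @ (T @ fit2.beta)
        modes = fit2.blup.set_index(["kind", "group"])["mode"]
        eta_ref = eta_ref + np.array(
            [modes[("bird", b)] for b in frame["bird"]]
        ) + np.array([modes[("feeder", f)] for f in frame["core"]])
        np.testing.assert_allclose(eta_means, eta_ref, atol=1e-6)

    def test_blup_shrinkage_toward_zero_as_v_bird_vanishes(self, rng):
        frame = make_frame(rng, n_birds=15, n_days=8, family="gaussian", v_bird=1.0)
        norms = []
        for vb in [1.0, 0.1, 0.001]:
            fit = fit_visits_lmm(frame, FitControls(fix_v_bird=vb))
            norms.append(np.abs(fit.bird_blups()["mode"]).mean())
        assert norms[0] > norms[1] > norms[2]
        assert norms[2] < 0.01


class TestFitResultRoundTrip:
    def test_json_round_trip(self, rng, tmp_path):
        frame = make_frame(rng, n_birds=10, n_days=5, family="gaussian")
        fit = fit_visits_lmm(frame)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = FitResult.from_json(path)
        np.testing.assert_allclose(back.beta, fit.beta)
        np.testing.assert_allclose(back.beta_cov, fit.beta_cov)
        assert back.varcomp == pytest.approx(fit.varcomp)
        assert list(back.blup["mode"]) == pytest.approx(list(fit.blup["mode"]))
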