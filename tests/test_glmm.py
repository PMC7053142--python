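import subprocess

import numpy as np
import pandas as pd
import pytest

from longbinrct import (GlmmFit, ScenarioConfig, analyze_chisq, analyze_glmm,
                        estimate_effect_at_final_visit, fit_rpl,
                        generate_complete_replicate)
from longbinrct.glmm import reml_random_intercept


class TestContrast:
    def test_estimate_arithmetic(self):
        fit = GlmmFit(beta=np.array([0.0, 0.2, 0.0, 0.1]), sigma_b2=0.5,
                      residual_scale=1.0, cov_beta=np.eye(4) * 1e-4,
                      n_iterations=5, converged=True)
        c = estimate_effect_at_final_visit(fit, final_time=3.0)
        assert c.estimate == pytest.approx(0.5)

    def test_se_from_diagonal_covariance(self):
        cov = np.zeros((4, 4))
        cov[1, 1], cov[3, 3] = 0.04, 0.01
        fit = GlmmFit(beta=np.zeros(4), sigma_b2=0.0, residual_scale=1.0,
                      cov_beta=cov, n_iterations=1, converged=True)
        c = estimate_effect_at_final_visit(fit, final_time=3.0)
        assert c.se == pytest.approx(np.sqrt(0.04 + 9 * 0.01), rel=1e-12)
        assert c.ci_low == pytest.approx(c.estimate - 1.96 * c.se)


class TestInnerReml:
    def test_matches_balanced_anova_closed_form(self):
        # Gaussian identity-link limit: REML variance components of a
        # balanced one-way layout have closed-form ANOVA expressions
        rng = np.random.default_rng(3)
        m, k = 50, 4
        b = rng.normal(0, 1.5, m)
        y = (b[:, None] + rng.normal(0, 0.8, (m, k))).ravel()
        subject = np.repeat(np.arange(m), k)
        X = np.ones((m * k, 1))
        beta, s2, phi, _ = reml_random_intercept(X, y, np.ones(m * k),
                                                 subject)
        grp = y.reshape(m, k).mean(axis=1)
        msb = k * np.sum((grp - y.mean()) ** 2) / (m - 1)
        msw = np.sum((y.reshape(m, k) - grp[:, None]) ** 2) / (m * (k - 1))
        assert beta[0] == pytest.approx(y.mean(), rel=1e-8)
        assert s2 == pytest.approx((msb - msw) / k, rel=1e-6)
        assert phi == pytest.approx(msw, rel=1e-6)

    def test_boundary_variance_is_zero(self):
        # anti-correlated pairs have negative sample ICC -> REML sits on
        # the sigma_b2 = 0 boundary
        rng = np.random.default_rng(0)
        m, k = 200, 2
        u = rng.normal(size=m)
        y = np.column_stack([u, -u]).ravel() + 0.3 * rng.normal(size=m * k)
        subject = np.repeat(np.arange(m), k)
        X = np.ones((m * k, 1))
        _, s2, _, _ = reml_random_intercept(X, y, np.ones(m * k), subject)
        assert s2 == pytest.approx(0.0, abs=1e-8)


class TestFit:
    def test_zero_variance_reduces_to_plain_logistic(self):
        # independent Bernoulli outcomes: the variance estimate hits the
        # zero boundary and the fit must coincide with ordinary logistic
        # regression on the same rows
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        n = 300
        arm = np.repeat([1, 0], n // 2)
        rows = []
        for i in range(n):
            for t in (1, 2, 3):
                p = 0.25 + 0.05 * t * arm[i]
                rows.append((i, arm[i], t, 0.0, int(rng.random() < p), False))
        df = pd.DataFrame(rows, columns=["subject", "arm", "visit", "p", "y",
                                         "missing"])
        fit = fit_rpl(df)
        assert fit.converged
        assert fit.sigma_b2 == pytest.approx(0.0, abs=1e-6)
        X = np.column_stack([np.ones(len(df)), df["arm"], df["visit"],
                             df["arm"] * df["visit"]])
        glm = sm.GLM(df["y"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        assert np.allclose(fit.beta, glm.params, atol=1e-6)

    def test_cross_implementation_oracle(self, small_trial, tmp_path):
        # the scale-estimated fit must agree with an independent PQL
        # implementation (MASS::glmmPQL) on the same fixed dataset
        fit = fit_rpl(small_trial, estimate_scale=True)
        assert fit.converged
        csv = tmp_path / "trial.csv"
        small_trial[["subject", "arm", "visit", "y"]].to_csv(csv, index=False)
        script = (
            'suppressMessages({library(MASS); library(nlme)});'
            f'd <- read.csv("{csv}");'
            'f <- glmmPQL(y ~ arm*visit, random=~1|subject,'
            ' family=binomial, data=d, verbose=FALSE, niter=30);'
            'v <- VarCorr(f);'
            'cat(fixef(f), as.numeric(v[1,1]), as.numeric(v[2,1]), sep="\\n")'
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        vals = [float(x) for x in res.stdout.strip().splitlines()]
        r_beta, r_sigma2, r_phi = np.array(vals[:4]), vals[4], vals[5]
        assert np.allclose(fit.beta, r_beta, atol=0.05)
        assert fit.sigma_b2 == pytest.approx(r_sigma2, rel=0.10)
        assert fit.residual_scale == pytest.approx(r_phi, rel=0.05)

    def test_subject_specific_exceeds_marginal(self):
        # subject-specific log-OR from the mixed model is farther from 0
        # than the marginal 2x2 estimate, on average over replicates
        cfg = ScenarioConfig(prevalence=0.3, rho=0.5, n_total=300, n_reps=1,
                             seed=0)
        diffs = []
        for i in range(25):
            df = generate_complete_replicate(cfg, cfg.beta_params,
                                             np.random.default_rng(i))
            g = analyze_glmm(df)
            c = analyze_chisq(df)
            if not (g.degenerate or c.degenerate):
                diffs.append(g.estimate - c.estimate)
        assert np.mean(diffs) > 0

    def test_partial_information_used_after_dropout(self, medium_replicate):
        from longbinrct import apply_mcar

        dropped = apply_mcar(medium_replicate, 0.5, 0.5,
                             np.random.default_rng(1))
        fit = fit_rpl(dropped)
        assert fit.converged
        # rows at visits 1-2 all retained: estimate should differ from a
        # fit on complete cases only
        cc = dropped.groupby("subject")["missing"].any()
        cc_only = dropped[~dropped["subject"].map(cc)]
        fit_cc = fit_rpl(cc_only)
        assert not np.allclose(fit.beta, fit_cc.beta)

    def test_non_convergence_flagged(self, medium_replicate):
        fit = fit_rpl(medium_replicate, max_iter=1)
        assert not fit.converged
        res = analyze_glmm(medium_replicate, max_iter=1)
        assert res.degenerate and np.isnan(res.estimate)

    def test_wald_pvalue_consistency(self, medium_replicate):
        res = analyze_glmm(medium_replicate)
        from scipy import stats
        z = res.estimate / res.se
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(z)))
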