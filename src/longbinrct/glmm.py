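"""Random-intercept logistic GLMM fitted by restricted pseudo-likelihood.

The model for subject i at visit j is::

    logit Pr(Y_ij = 1 | b_i) = beta1 + beta2 X_i + beta3 t_ij
                               + beta4 t_ij X_i + b_i,     b_i ~ N(0, sigma_b^2)

with X_i the arm indicator and t_ij the visit time treated as continuous
(coded 1, 2, 3, ...).  A single random intercept induces a compound
symmetric within-subject covariance.

Estimation is the doubly iterative pseudo-likelihood scheme of
Breslow-Clayton PQL with REML variance components (the "RSPL" flavour):
the model is linearized around the current (beta, b) via the working
variate ``z = eta + (y - mu)/[mu(1-mu)]`` with weights ``w = mu(1-mu)``,
and the resulting weighted linear mixed pseudo-model

    z = X beta + b_i + e,   e ~ N(0, phi W^{-1}),  b_i ~ N(0, sigma_b^2)

is fitted by REML for the variance components with beta profiled by
generalized least squares; the outer linearization is repeated to a fixed
point.  Following the convention that a Bernoulli response carries no free
scale parameter, the pseudo-model residual scale phi is fixed at 1 by
default; ``estimate_scale=True`` frees it, which reproduces the behaviour
of PQL implementations that always carry a dispersion parameter (such as
``MASS::glmmPQL``).  The choice is consequential when the latent
heterogeneity is extreme.  Because the random effect enters one intercept
per subject, all block operations use the rank-one Woodbury identity and
per-subject sums, so a fit costs a few hundred vectorized passes over the
data.

The treatment effect is the contrast beta2 + t_final * beta4 (the
arm difference in log-odds at the final visit), tested with a Wald z
statistic; as a pseudo-likelihood is maximized, no likelihood-ratio test
is offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .chisq import AnalysisResult, Z_975

__all__ = [
    "GlmmFit",
    "Contrast",
    "fit_rpl",
    "estimate_effect_at_final_visit",
    "analyze_glmm",
    "reml_random_intercept",
]

_ETA_CAP = 20.0  # linear-predictor cap keeping working weights positive
_LOG_THETA_MIN = -30.0  # exp(-30) ~ 1e-13: variance ratio treated as boundary zero
_LOG_THETA_MAX = 8.0


@dataclass
class GlmmFit:
    """Converged state of the pseudo-likelihood fit.

    ``beta`` is (intercept, arm, time, arm x time); ``sigma_b2`` the
    random-intercept variance; ``residual_scale`` the pseudo-model residual
    variance phi; ``cov_beta`` the model-based covariance of ``beta`` from
    the final GLS step.
    """

    beta: np.ndarray
    sigma_b2: float
    residual_scale: float
    cov_beta: np.ndarray
    n_iterations: int
    converged: bool


@dataclass
class Contrast:
    """Linear combination of fixed effects with Wald inference."""

    weights: np.ndarray
    estimate: float
    se: float
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float


class _RandomInterceptREML:
    """REML for ``z = X beta + b_i + e`` with diagonal weights.

    Writes V_i = phi * (W_i^{-1} + theta J) per subject block with
    theta = sigma_b^2 / phi.  beta always profiles out analytically; phi is
    either fixed at 1 (no scale parameter, the default for a Bernoulli
    response) or profiled as well, so the REML criterion is one-dimensional
    in theta either way; all per-subject quantities reduce to weighted sums
    handled by ``np.add.reduceat``.
    """

    def __init__(self, X: np.ndarray, z: np.ndarray, w: np.ndarray,
                 starts: np.ndarray, estimate_scale: bool = False):
        self.estimate_scale = estimate_scale
        self.n, self.p = X.shape
        self.X = X
        wX = w[:, None] * X
        wz = w * z
        self.S = np.add.reduceat(w, starts)            # per-subject sum of w
        self.Sx = np.add.reduceat(wX, starts, axis=0)  # per-subject X'w sums
        self.Sz = np.add.reduceat(wz, starts)
        self.XtWX = X.T @ wX
        self.XtWz = X.T @ wz
        self.ztWz = float(z @ wz)
        self.sum_log_w = float(np.sum(np.log(w)))

    def _gls(self, theta: float):
        """beta, Q = r'Sigma^-1 r, A = X'Sigma^-1 X at a given theta."""
        f = theta / (1.0 + theta * self.S)
        A = self.XtWX - (self.Sx.T * f) @ self.Sx
        c = self.XtWz - self.Sx.T @ (f * self.Sz)
        beta = np.linalg.solve(A, c)
        Q = self.ztWz - float(f @ self.Sz**2) - float(beta @ c)
        return beta, Q, A, f

    def criterion(self, log_theta: float) -> float:
        """-2 REML log-likelihood in theta, up to a constant.

        With a free scale the residual variance is profiled out
        analytically; with phi = 1 the quadratic form enters directly.
        """
        theta = np.exp(log_theta)
        beta, Q, A, _ = self._gls(theta)
        if Q <= 0.0 or not np.isfinite(Q):
            return np.inf
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        logdet_sigma = -self.sum_log_w + float(np.sum(np.log1p(theta * self.S)))
        if self.estimate_scale:
            nmp = self.n - self.p
            return nmp * np.log(Q / nmp) + logdet_sigma + logdet_A + nmp
        return logdet_sigma + logdet_A + Q

    def fit(self, log_theta0: float):
        """Minimize the criterion in log(theta), expanding brackets on demand."""
        lo = max(log_theta0 - 1.5, _LOG_THETA_MIN)
        hi = min(log_theta0 + 1.5, _LOG_THETA_MAX)
        while True:
            res = optimize.minimize_scalar(
                self.criterion, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-11},
            )
            x = float(res.x)
            at_lo = x - lo < 1e-6 and lo > _LOG_THETA_MIN
            at_hi = hi - x < 1e-6 and hi < _LOG_THETA_MAX
            if at_lo:
                hi, lo = lo + 0.5, max(lo - 3.0, _LOG_THETA_MIN)
            elif at_hi:
                lo, hi = hi - 0.5, min(hi + 3.0, _LOG_THETA_MAX)
            else:
                break
        theta = np.exp(x)
        if x <= _LOG_THETA_MIN + 1e-6:
            theta = 0.0  # boundary: no between-subject variance
        beta, Q, A, f = self._gls(theta)
        phi = Q / (self.n - self.p) if self.estimate_scale else 1.0
        cov_beta = phi * np.linalg.inv(A)
        # BLUP of the random intercepts: theta * sum_j w r / (1 + theta S)
        resid_sums = self.Sz - self.Sx @ beta
        b = theta * resid_sums / (1.0 + theta * self.S)
        return beta, theta, phi, cov_beta, b


def reml_random_intercept(
    X: np.ndarray, z: np.ndarray, w: np.ndarray, subject: np.ndarray,
    estimate_scale: bool = True,
) -> tuple[np.ndarray, float, float, np.ndarray]:
    """REML fit of the weighted random-intercept linear model.

    Exposed mainly so the inner engine can be validated on Gaussian data,
    where balanced designs admit closed-form ANOVA answers.  ``subject``
    must be sorted with contiguous blocks.  Returns
    ``(beta, sigma_b2, phi, cov_beta)``.
    """
    starts = _block_starts(subject)
    engine = _RandomInterceptREML(np.asarray(X, float), np.asarray(z, float),
                                  np.asarray(w, float), starts,
                                  estimate_scale=estimate_scale)
    beta, theta, phi, cov_beta, _ = engine.fit(np.log(0.5))
    return beta, theta * phi, phi, cov_beta


def _block_starts(subject: np.ndarray) -> np.ndarray:
    """Start indices of contiguous subject blocks."""
    change = np.empty(subject.size, dtype=bool)
    change[0] = True
    np.not_equal(subject[1:], subject[:-1], out=change[1:])
    return np.flatnonzero(change)


def _logistic_init(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Plain logistic regression by Newton-Raphson, ignoring clustering."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    for _ in range(25):
        eta = np.clip(X @ beta, -_ETA_CAP, _ETA_CAP)
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (w[:, None] * X)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def design_matrix(arm: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Fixed-effects design (1, arm, t, arm*t) with t coded 1, 2, 3, ..."""
    return np.column_stack(
        [np.ones(arm.size), arm, time, arm * time]
    ).astype(float)


def fit_rpl(
    data: pd.DataFrame,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
    sigma_b2_init: float = 0.1,
    estimate_scale: bool = False,
) -> GlmmFit:
    """Fit the random-intercept logistic GLMM by restricted pseudo-likelihood.

    Rows flagged missing are excluded row-wise, so subjects who drop out at
    the final visit still contribute their earlier visits — this is how the
    mixed model uses partial information that the complete-case table
    analysis discards.

    By default the pseudo-model residual scale is fixed at 1 (a Bernoulli
    response has no dispersion parameter); ``estimate_scale=True`` frees it
    and then matches dispersion-carrying PQL implementations such as
    ``MASS::glmmPQL``.

    Convergence is declared when the scaled change
    ``max |delta| / (1 + |old|)`` over (beta, sigma_b^2, phi) falls below
    ``tol``; otherwise ``converged=False`` after ``max_iter`` outer
    linearizations.  ``sigma_b2 = 0`` is an allowed boundary solution.
    """
    rows = data[~data["missing"]]
    rows = rows.sort_values(["subject", "visit"], kind="stable")
    subject = rows["subject"].to_numpy()
    arm = rows["arm"].to_numpy(dtype=float)
    time = rows["visit"].to_numpy(dtype=float)
    y = rows["y"].to_numpy(dtype=float)
    X = design_matrix(arm, time)
    starts = _block_starts(subject)
    # map each row to its block index for expanding per-subject BLUPs
    block_of_row = np.cumsum(np.isin(np.arange(subject.size), starts)) - 1

    beta = _logistic_init(X, y)
    phi = 1.0
    sigma_b2 = sigma_b2_init
    b_rows = np.zeros(subject.size)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = np.clip(X @ beta + b_rows, -_ETA_CAP, _ETA_CAP)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w

        engine = _RandomInterceptREML(X, z, w, starts,
                                      estimate_scale=estimate_scale)
        theta0 = max(sigma_b2 / phi, 1e-8)
        new_beta, theta, new_phi, cov_beta, b = engine.fit(np.log(theta0))
        new_sigma_b2 = theta * new_phi

        old = np.concatenate([beta, [sigma_b2, phi]])
        new = np.concatenate([new_beta, [new_sigma_b2, new_phi]])
        delta = np.max(np.abs(new - old) / (1.0 + np.abs(old)))
        beta, sigma_b2, phi = new_beta, new_sigma_b2, new_phi
        b_rows = b[block_of_row]
        if delta < tol:
            converged = True
            break

    return GlmmFit(
        beta=beta,
        sigma_b2=float(sigma_b2),
        residual_scale=float(phi),
        cov_beta=cov_beta,
        n_iterations=n_iter,
        converged=converged,
    )


def estimate_effect_at_final_visit(
    fit: GlmmFit, final_time: float = 3.0
) -> Contrast:
    """Arm contrast at the final visit: ``beta2 + final_time * beta4``.

    Wald z inference with a normal reference and a 95% interval
    ``estimate +/- 1.96 se``.
    """
    weights = np.array([0.0, 1.0, 0.0, final_time])
    estimate = float(weights @ fit.beta)
    se = float(np.sqrt(weights @ fit.cov_beta @ weights))
    z = estimate / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return Contrast(
        weights=weights,
        estimate=estimate,
        se=se,
        statistic=z,
        p_value=p,
        ci_low=estimate - Z_975 * se,
        ci_high=estimate + Z_975 * se,
    )


def analyze_glmm(data: pd.DataFrame, final_time: float | None = None,
                 **fit_kwargs) -> AnalysisResult:
    """Fit the GLMM on one replicate and test the final-visit arm contrast.

    Non-converged fits yield a degenerate result (NaN estimate) that
    downstream summaries count and exclude.
    """
    if final_time is None:
        final_time = float(data["visit"].max())
    fit = fit_rpl(data, **fit_kwargs)
    if not fit.converged:
        nan = float("nan")
        return AnalysisResult(
            method="glmm", estimate=nan, se=nan, statistic=nan, p_value=nan,
            ci_low=nan, ci_high=nan, converged=False, degenerate=True,
        )
    contrast = estimate_effect_at_final_visit(fit, final_time=final_time)
    return AnalysisResult(
        method="glmm",
        estimate=contrast.estimate,
        se=contrast.se,
        statistic=contrast.statistic,
        p_value=contrast.p_value,
        ci_low=contrast.ci_low,
        ci_high=contrast.ci_high,
        converged=True,
        degenerate=False,
    )
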