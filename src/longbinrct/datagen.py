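"""Generation of complete longitudinal binary RCT replicates.

A two-arm 1:1 trial with ``n_visits`` repeated binary outcomes per subject.
Each subject's baseline event probability ``p_i1`` is drawn from a
Beta(a, b) distribution whose parameters are solved so that
``E[p_i1] = prevalence`` and the within-subject outcome correlation equals
``rho`` (for a subject whose probability stays constant over time the
correlation between any two repeated Bernoulli outcomes is exactly
``Var(p_i1)/[prevalence(1-prevalence)] = 1/(1+a+b)``).

Under the alternative hypothesis the treatment arm's probability increases
by ``delta`` per visit, producing an end-of-study risk difference of
``delta * (n_visits - 1)``; the control arm stays flat.  Under the null both
arms stay flat at ``p_i1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BetaParams",
    "ScenarioConfig",
    "DROPOUT_PATTERNS",
    "solve_beta_params",
    "required_sample_size",
    "generate_complete_replicate",
]

#: dropout pattern name -> (control rate, treatment rate)
DROPOUT_PATTERNS: dict[str, tuple[float, float]] = {
    "equal": (0.30, 0.30),
    "unequal1": (0.20, 0.40),
    "unequal2": (0.40, 0.20),
}

Hypothesis = Literal["alternative", "null"]
Mechanism = Literal["none", "MCAR", "MAR1", "MAR2"]


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of the baseline-probability Beta distribution."""

    a: float
    b: float

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def correlation(self) -> float:
        """Implied within-subject outcome correlation 1/(1+a+b)."""
        return 1.0 / (1.0 + self.a + self.b)


def solve_beta_params(prevalence: float, rho: float) -> BetaParams:
    """Solve Beta(a, b) from the target prevalence and correlation.

    The two moment conditions ``a/(a+b) = prevalence`` and
    ``1/(1+a+b) = rho`` have the closed-form solution
    ``a + b = 1/rho - 1``, ``a = prevalence*(a+b)``.

    Raises
    ------
    ValueError
        If either argument lies outside the open interval (0, 1).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    if not 0.0 < rho < 1.0:
        raise ValueError(f"rho must be in (0, 1), got {rho}")
    total = 1.0 / rho - 1.0
    return BetaParams(a=prevalence * total, b=(1.0 - prevalence) * total)


def required_sample_size(
    p_control: float,
    p_treatment: float,
    power: float = 0.80,
    alpha: float = 0.05,
) -> int:
    """Total sample size for a two-sided two-proportion z test.

    Pooled-variance normal approximation with no continuity correction::

        n/arm = [ z_{1-a/2} sqrt(2 pbar qbar) + z_{power} sqrt(p1 q1 + p2 q2) ]^2
                / (p1 - p2)^2

    rounded up per arm; the total is twice that.  The two canonical design
    cells used throughout this package are 0.1 vs 0.2 -> 398 total and
    0.5 vs 0.6 -> 776 total (80% power, alpha = 0.05).
    """
    for name, v in (("p_control", p_control), ("p_treatment", p_treatment)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {v}")
    if p_control == p_treatment:
        raise ValueError("equal proportions: required sample size is infinite")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must be in (0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    p_bar = 0.5 * (p_control + p_treatment)
    num = (
        z_a * np.sqrt(2.0 * p_bar * (1.0 - p_bar))
        + z_b * np.sqrt(p_control * (1.0 - p_control) + p_treatment * (1.0 - p_treatment))
    ) ** 2
    n_per_arm = int(np.ceil(num / (p_control - p_treatment) ** 2))
    return 2 * n_per_arm


@dataclass
class ScenarioConfig:
    """One cell of the simulation grid.

    Parameters mirror the study design: ``prevalence`` and ``rho`` pick the
    baseline Beta distribution, ``delta`` the per-visit treatment increment
    (0.05 by default, i.e. a 0.10 end-of-study risk difference over 3
    visits), ``mechanism``/``dropout_pattern`` the missingness scenario and
    ``n_reps``/``seed`` the Monte Carlo run.  ``n_total`` defaults to the
    two-proportion sample size for the end-of-study comparison.
    """

    prevalence: float
    rho: float
    hypothesis: Hypothesis = "alternative"
    n_total: int | None = None
    delta: float = 0.05
    n_visits: int = 3
    mechanism: Mechanism = "none"
    dropout_pattern: str = "equal"
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must be in (0, 1)")
        if self.hypothesis not in ("alternative", "null"):
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if self.mechanism not in ("none", "MCAR", "MAR1", "MAR2"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.dropout_pattern not in DROPOUT_PATTERNS:
            raise ValueError(f"unknown dropout pattern {self.dropout_pattern!r}")
        if self.n_visits < 2:
            raise ValueError("n_visits must be >= 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")
        if self.n_total is None:
            end_rd = self.delta * (self.n_visits - 1)
            self.n_total = required_sample_size(
                self.prevalence, self.prevalence + end_rd
            )
        if self.n_total <= 0 or self.n_total % 2:
            raise ValueError("n_total must be a positive even integer (1:1 allocation)")
        if (
            self.hypothesis == "alternative"
            and self.prevalence + self.delta * (self.n_visits - 1) > 1.0
        ):
            raise ValueError("mean treatment-arm probability would exceed 1")

    @property
    def dropout_rates(self) -> tuple[float, float]:
        """(control rate, treatment rate) of the configured pattern."""
        return DROPOUT_PATTERNS[self.dropout_pattern]

    @property
    def beta_params(self) -> BetaParams:
        return solve_beta_params(self.prevalence, self.rho)


def generate_complete_replicate(
    config: ScenarioConfig,
    beta: BetaParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate one complete trial replicate in long format.

    The first ``n_total/2`` subjects are assigned to treatment, the rest to
    control (exchangeable with randomization since subjects are i.i.d.).
    Per subject: ``p_i1 ~ Beta(a, b)``; for later visits
    ``p_ij = p_i(j-1) + delta * X_i`` under the alternative (clipped to
    [0, 1] so the Bernoulli draw stays valid), constant under the null;
    ``y_ij ~ Bernoulli(p_ij)``.

    Returns
    -------
    pandas.DataFrame
        Columns ``subject, arm, visit, p, y, missing`` (one row per
        subject-visit, visit coded 1..n_visits, ``missing`` all False).
        ``df.attrs["clipped_fraction"]`` records the fraction of
        subject-visit probabilities that hit the upper bound.
    """
    n = config.n_total
    n_visits = config.n_visits
    arm = np.zeros(n, dtype=np.int64)
    arm[: n // 2] = 1

    p1 = rng.beta(beta.a, beta.b, size=n)
    p = np.empty((n, n_visits))
    p[:, 0] = p1
    n_clipped = 0
    if config.hypothesis == "alternative":
        for j in range(1, n_visits):
            raw = p[:, j - 1] + config.delta * arm
            n_clipped += int(np.count_nonzero(raw > 1.0))
            p[:, j] = np.clip(raw, 0.0, 1.0)
    else:
        p[:, 1:] = p1[:, None]
    y = (rng.random((n, n_visits)) < p).astype(np.int64)

    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), n_visits),
            "arm": np.repeat(arm, n_visits),
            "visit": np.tile(np.arange(1, n_visits + 1), n),
            "p": p.ravel(),
            "y": y.ravel(),
            "missing": np.zeros(n * n_visits, dtype=bool),
        }
    )
    df.attrs["clipped_fraction"] = n_clipped / (n * n_visits)
    return df
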