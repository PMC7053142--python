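"""Complete-case analysis at the final visit: Pearson chi-squared and log-OR.

Non-missing final-visit outcomes are cross-tabulated by arm into a 2x2
table.  The treatment effect is the log odds ratio (treatment vs control,
event = 1) with the usual Woolf standard error ``sqrt(sum of 1/cell)`` and
a 95% Wald interval.  The hypothesis test is the uncorrected Pearson
chi-squared test on 1 df; its p-value, not the Wald p, defines rejection
for power and type I error.

A replicate with a zero cell is flagged degenerate: no 0.5 continuity
correction is applied, the estimate is NaN and the replicate is excluded
from estimate-based summaries (the Pearson statistic is still computed when
both margins are positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "AnalysisResult",
    "tabulate",
    "pearson_chi2",
    "log_odds_ratio",
    "analyze_chisq",
]

Z_975 = 1.96  # normal quantile for the 95% Wald interval


@dataclass(frozen=True)
class ContingencyTable:
    """Arm x outcome counts at the final visit (complete cases only).

    ``n11``: treatment events, ``n10``: treatment non-events,
    ``n01``: control events, ``n00``: control non-events.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_array(self) -> np.ndarray:
        """2x2 array with rows (treatment, control), columns (event, no event)."""
        return np.array([[self.n11, self.n10], [self.n01, self.n00]])

    @property
    def has_zero_cell(self) -> bool:
        return min(self.n11, self.n10, self.n01, self.n00) == 0

    @property
    def has_zero_margin(self) -> bool:
        a = self.as_array()
        return bool((a.sum(axis=0) == 0).any() or (a.sum(axis=1) == 0).any())


@dataclass
class AnalysisResult:
    """Per-replicate result of one analysis method.

    ``estimate`` is the log odds ratio at the final visit (treatment vs
    control); ``p_value`` is the method's test p-value (Pearson for chisq,
    Wald for the mixed model).  ``degenerate`` marks zero cells or
    non-convergence; such replicates are excluded from estimate-based
    performance measures.
    """

    method: str
    estimate: float
    se: float
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    converged: bool = True
    degenerate: bool = False


def tabulate(data: pd.DataFrame) -> ContingencyTable:
    """Cross-tabulate non-missing final-visit outcomes by arm."""
    last = int(data["visit"].max())
    cc = data[(data["visit"] == last) & ~data["missing"]]
    arm = cc["arm"].to_numpy()
    y = cc["y"].to_numpy()
    return ContingencyTable(
        n11=int(((arm == 1) & (y == 1)).sum()),
        n10=int(((arm == 1) & (y == 0)).sum()),
        n01=int(((arm == 0) & (y == 1)).sum()),
        n00=int(((arm == 0) & (y == 0)).sum()),
    )


def pearson_chi2(table: ContingencyTable) -> tuple[float, float]:
    """Uncorrected Pearson chi-squared statistic and p-value (1 df).

    Returns ``(nan, nan)`` when a margin is zero (expected counts
    undefined).
    """
    if table.has_zero_margin:
        return float("nan"), float("nan")
    stat, p, _, _ = stats.chi2_contingency(table.as_array(), correction=False)
    return float(stat), float(p)


def log_odds_ratio(table: ContingencyTable) -> tuple[float, float, float, float]:
    """Log odds ratio, Woolf SE and 95% Wald interval from a 2x2 table.

    Returns NaNs when any cell is zero (degenerate; no continuity
    correction is applied).
    """
    if table.has_zero_cell:
        nan = float("nan")
        return nan, nan, nan, nan
    est = float(np.log(table.n11 * table.n00 / (table.n10 * table.n01)))
    se = float(np.sqrt(1 / table.n11 + 1 / table.n10 + 1 / table.n01 + 1 / table.n00))
    return est, se, est - Z_975 * se, est + Z_975 * se


def analyze_chisq(data: pd.DataFrame) -> AnalysisResult:
    """Run the complete-case chi-squared analysis on one replicate."""
    table = tabulate(data)
    statistic, p_value = pearson_chi2(table)
    est, se, lo, hi = log_odds_ratio(table)
    return AnalysisResult(
        method="chisq",
        estimate=est,
        se=se,
        statistic=statistic,
        p_value=p_value,
        ci_low=lo,
        ci_high=hi,
        converged=True,
        degenerate=table.has_zero_cell,
    )
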