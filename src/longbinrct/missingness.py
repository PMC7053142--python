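"""Dropout at the final visit under MCAR or MAR.

MCAR deletes an exact per-arm fraction of final-visit outcomes by simple
random sampling.  MAR deletes each subject's final outcome with probability
``expit(gamma1 + gamma2 * y_prev + gamma3 * arm)``, where ``y_prev`` is the
outcome at the penultimate visit.  ``gamma2`` encodes the mechanism's
strength and direction (+1.5: a prior event makes dropout 4.5 times more
likely on the odds scale; -1.5: 0.22 times); ``gamma1`` and ``gamma3`` are
calibrated so the expected per-arm dropout rates hit their targets.

Earlier visits are never touched, so dropout is monotone at the final visit
only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = ["MissingnessModel", "apply_mcar", "calibrate_mar", "apply_mar"]

_GAMMA2 = {"MAR1": 1.5, "MAR2": -1.5}


@dataclass(frozen=True)
class MissingnessModel:
    """Calibrated logistic dropout model for the final visit."""

    gamma1: float
    gamma2: float
    gamma3: float
    target_control_rate: float
    target_treatment_rate: float

    def dropout_probability(self, y_prev: np.ndarray, arm: np.ndarray) -> np.ndarray:
        return expit(self.gamma1 + self.gamma2 * y_prev + self.gamma3 * arm)


def _expected_rate(intercept: float, gamma2: float, pi: float) -> float:
    """Marginal dropout probability when Pr(y_prev = 1) = pi."""
    return (1.0 - pi) * expit(intercept) + pi * expit(intercept + gamma2)


def calibrate_mar(
    gamma2: float,
    prevalence: float,
    delta: float,
    target_control_rate: float,
    target_treatment_rate: float,
) -> MissingnessModel:
    """Solve gamma1 and gamma3 for the target per-arm dropout rates.

    The expected dropout rate in an arm is a mixture over the penultimate
    outcome: ``(1-pi) expit(g) + pi expit(g + gamma2)`` with
    ``pi = prevalence`` in control and ``pi = prevalence + delta`` in
    treatment (the marginal means of the generative model at the
    penultimate visit; pass ``delta=0`` for null-hypothesis data).  Each
    equation is strictly increasing in its intercept, so a bracketing root
    finder applies; the calibration residual is checked to 1e-8.
    """
    for name, r in (
        ("target_control_rate", target_control_rate),
        ("target_treatment_rate", target_treatment_rate),
    ):
        if not 0.0 < r < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {r}")
    pi_c = prevalence
    pi_t = prevalence + delta
    if not 0.0 <= pi_t <= 1.0:
        raise ValueError("treatment-arm penultimate mean outside [0, 1]")

    lo, hi = -40.0, 40.0
    gamma1 = brentq(
        lambda g: _expected_rate(g, gamma2, pi_c) - target_control_rate,
        lo, hi, xtol=1e-13,
    )
    g13 = brentq(
        lambda g: _expected_rate(g, gamma2, pi_t) - target_treatment_rate,
        lo, hi, xtol=1e-13,
    )
    model = MissingnessModel(
        gamma1=gamma1,
        gamma2=gamma2,
        gamma3=g13 - gamma1,
        target_control_rate=target_control_rate,
        target_treatment_rate=target_treatment_rate,
    )
    res_c = abs(_expected_rate(gamma1, gamma2, pi_c) - target_control_rate)
    res_t = abs(_expected_rate(g13, gamma2, pi_t) - target_treatment_rate)
    if max(res_c, res_t) > 1e-8:
        raise RuntimeError(
            f"MAR calibration residual too large: {max(res_c, res_t):.3g}"
        )
    return model


def mar_model_for(mechanism: str, prevalence: float, delta: float,
                  control_rate: float, treatment_rate: float) -> MissingnessModel:
    """Convenience: build the calibrated model for mechanism 'MAR1'/'MAR2'."""
    try:
        gamma2 = _GAMMA2[mechanism]
    except KeyError:
        raise ValueError(f"not a MAR mechanism: {mechanism!r}") from None
    return calibrate_mar(gamma2, prevalence, delta, control_rate, treatment_rate)


def _final_visit(data: pd.DataFrame) -> int:
    return int(data["visit"].max())


def apply_mcar(
    data: pd.DataFrame,
    control_rate: float,
    treatment_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Flag an exact per-arm fraction of final-visit outcomes missing.

    Within each arm, ``round(rate * arm_size)`` subjects are chosen by
    simple random sampling without replacement, so the realized counts are
    exact by construction.  Returns a copy; earlier visits are untouched.
    """
    for name, r in (("control_rate", control_rate), ("treatment_rate", treatment_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    out = data.copy()
    last = _final_visit(out)
    final = out[out["visit"] == last]
    for arm_value, rate in ((0, control_rate), (1, treatment_rate)):
        subjects = final.loc[final["arm"] == arm_value, "subject"].to_numpy()
        k = int(np.floor(rate * subjects.size + 0.5))
        chosen = rng.choice(subjects, size=k, replace=False)
        out.loc[
            (out["visit"] == last) & out["subject"].isin(chosen), "missing"
        ] = True
    return out


def apply_mar(
    data: pd.DataFrame,
    model: MissingnessModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Flag final-visit outcomes missing under the logistic dropout model.

    Each subject's final outcome goes missing independently with probability
    ``expit(gamma1 + gamma2 * y_prev + gamma3 * arm)``.  Returns a copy.
    """
    out = data.copy()
    last = _final_visit(out)
    prev = out[out["visit"] == last - 1].sort_values("subject")
    y_prev = prev["y"].to_numpy()
    arm = prev["arm"].to_numpy()
    prob = model.dropout_probability(y_prev, arm)
    dropped = prev["subject"].to_numpy()[rng.random(prob.size) < prob]
    out.loc[(out["visit"] == last) & out["subject"].isin(dropped), "missing"] = True
    return out
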