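"""Scenario orchestration and Monte Carlo performance measures.

``run_scenario`` executes one simulation cell: for each replicate it
generates a complete trial, analyzes it with the complete-case chi-squared
test and the mixed model, applies the configured dropout mechanism, and
re-analyzes the incomplete data.  ``summarize`` aggregates the
per-replicate results into the standard simulation-study measures — power
or type I error, mean log-OR, relative bias, coverage, model and empirical
SE — each with a Monte Carlo standard error.  The "true" effect theta_T
used for bias and coverage is the mean complete-data estimate of the same
method from the same run, so each method is judged against its own
complete-data benchmark.

``render_tables`` writes delimited summary tables: one file per
(prevalence, rho) cell under the alternative hypothesis, plus a single
type-I-error table across cells.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import chisq, glmm, missingness
from .datagen import ScenarioConfig, generate_complete_replicate
from .missingness import MissingnessModel

__all__ = [
    "PerformanceSummary",
    "run_scenario",
    "summarize",
    "summarize_scenario",
    "render_tables",
    "load_scenario_grid",
    "paper_grid",
]

RESULT_COLUMNS = [
    "rep", "phase", "method", "estimate", "se", "statistic", "p_value",
    "ci_low", "ci_high", "converged", "degenerate", "sigma_b2",
    "residual_scale", "n_iterations", "clipped_fraction",
]


@dataclass
class PerformanceSummary:
    """Aggregated Monte Carlo performance of one method in one cell."""

    method: str
    phase: str  # "complete" or "incomplete"
    n_reps: int
    n_used: int
    n_degenerate: int
    theta_T: float
    mean_log_or: float
    relative_bias_pct: float
    power_or_type1_pct: float
    coverage_pct: float
    model_se: float
    empirical_se: float
    mcse_power: float
    mcse_coverage: float
    mcse_model_se: float
    mcse_empirical_se: float


def _replicate_rngs(seed: int, rep: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent generation and dropout streams for one replicate.

    Seeding by the (scenario seed, replicate index, stream) tuple makes
    every replicate independently reproducible, and keeps the complete
    data identical across missingness mechanisms run with the same seed.
    """
    gen = np.random.default_rng(np.random.SeedSequence((seed, rep, 0)))
    mis = np.random.default_rng(np.random.SeedSequence((seed, rep, 1)))
    return gen, mis


def _dropout_model_for(config: ScenarioConfig) -> MissingnessModel | None:
    if config.mechanism in ("MAR1", "MAR2"):
        control, treatment = config.dropout_rates
        delta = config.delta if config.hypothesis == "alternative" else 0.0
        return missingness.mar_model_for(
            config.mechanism, config.prevalence, delta, control, treatment
        )
    return None


def _result_row(rep: int, phase: str, res: chisq.AnalysisResult,
                sigma_b2: float = np.nan, residual_scale: float = np.nan,
                n_iterations: float = np.nan, clipped: float = np.nan) -> dict:
    return {
        "rep": rep, "phase": phase, "method": res.method,
        "estimate": res.estimate, "se": res.se, "statistic": res.statistic,
        "p_value": res.p_value, "ci_low": res.ci_low, "ci_high": res.ci_high,
        "converged": res.converged, "degenerate": res.degenerate,
        "sigma_b2": sigma_b2, "residual_scale": residual_scale,
        "n_iterations": n_iterations, "clipped_fraction": clipped,
    }


def run_scenario(
    config: ScenarioConfig,
    *,
    methods: Sequence[str] = ("chisq", "glmm"),
    analyze_complete: bool = True,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every replicate of one simulation cell.

    Returns a long DataFrame (one row per replicate x phase x method).
    ``analyze_complete=False`` skips the complete-data analyses (useful
    when only incomplete-data power is needed); with ``mechanism='none'``
    only the complete phase is produced.  Per-replicate failures are
    recorded as degenerate rows, never raised.
    """
    beta = config.beta_params
    model = _dropout_model_for(config)
    if model is not None and progress:
        print(f"  calibrated {config.mechanism}: gamma1={model.gamma1:.6f} "
              f"gamma2={model.gamma2:+.1f} gamma3={model.gamma3:.6f}",
              flush=True)
    final_time = float(config.n_visits)
    rows: list[dict] = []
    t0 = time.time()
    for rep in range(config.n_reps):
        rng_gen, rng_mis = _replicate_rngs(config.seed, rep)
        complete = generate_complete_replicate(config, beta, rng_gen)
        clipped = complete.attrs["clipped_fraction"]
        if analyze_complete:
            for method in methods:
                rows.append(_analyze(rep, "complete", method, complete,
                                     final_time, clipped))
        if config.mechanism == "MCAR":
            control, treatment = config.dropout_rates
            incomplete = missingness.apply_mcar(complete, control, treatment,
                                                rng_mis)
        elif config.mechanism in ("MAR1", "MAR2"):
            incomplete = missingness.apply_mar(complete, model, rng_mis)
        else:
            incomplete = None
        if incomplete is not None:
            for method in methods:
                rows.append(_analyze(rep, "incomplete", method, incomplete,
                                     final_time, clipped))
        if progress and (rep + 1) % 100 == 0:
            print(f"  replicate {rep + 1}/{config.n_reps} "
                  f"({time.time() - t0:.0f}s)", flush=True)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _analyze(rep: int, phase: str, method: str, data: pd.DataFrame,
             final_time: float, clipped: float) -> dict:
    if method == "chisq":
        return _result_row(rep, phase, chisq.analyze_chisq(data),
                           clipped=clipped)
    if method == "glmm":
        fit = glmm.fit_rpl(data)
        if fit.converged:
            c = glmm.estimate_effect_at_final_visit(fit, final_time=final_time)
            res = chisq.AnalysisResult(
                method="glmm", estimate=c.estimate, se=c.se,
                statistic=c.statistic, p_value=c.p_value,
                ci_low=c.ci_low, ci_high=c.ci_high,
                converged=True, degenerate=False,
            )
        else:
            nan = float("nan")
            res = chisq.AnalysisResult(
                method="glmm", estimate=nan, se=nan, statistic=nan,
                p_value=nan, ci_low=nan, ci_high=nan,
                converged=False, degenerate=True,
            )
        return _result_row(rep, phase, res, sigma_b2=fit.sigma_b2,
                           residual_scale=fit.residual_scale,
                           n_iterations=fit.n_iterations, clipped=clipped)
    raise ValueError(f"unknown method {method!r}")


def summarize(
    results: pd.DataFrame,
    method: str,
    phase: str,
    theta_T: float,
    alpha: float = 0.05,
) -> PerformanceSummary:
    """Aggregate one method/phase slice into performance measures.

    Estimate-based measures (mean log-OR, bias, coverage, SEs) use
    non-degenerate replicates only; the rejection rate uses every
    replicate with a defined p-value.  Monte Carlo SEs follow standard
    simulation practice: binomial for proportions, ``s/sqrt(2(n-1))`` for
    the empirical SE, and a delta-method form for the model SE.
    """
    sl = results[(results["method"] == method) & (results["phase"] == phase)]
    n_reps = len(sl)
    ok = sl[~sl["degenerate"] & np.isfinite(sl["estimate"])]
    n_used = len(ok)
    n_degenerate = n_reps - n_used

    with_p = sl[np.isfinite(sl["p_value"])]
    n_p = len(with_p)
    if n_p:
        rej = float((with_p["p_value"] < alpha).mean())
        power = 100.0 * rej
        mcse_power = 100.0 * float(np.sqrt(rej * (1 - rej) / n_p))
    else:
        power = mcse_power = float("nan")

    if n_used:
        est = ok["estimate"].to_numpy()
        se2 = ok["se"].to_numpy() ** 2
        mean_log_or = float(est.mean())
        rel_bias = 100.0 * (mean_log_or - theta_T) / theta_T
        covered = (ok["ci_low"] <= theta_T) & (theta_T <= ok["ci_high"])
        cov = float(covered.mean())
        coverage = 100.0 * cov
        mcse_cov = 100.0 * float(np.sqrt(cov * (1 - cov) / n_used))
        model_se = float(np.sqrt(se2.mean()))
        empirical_se = float(est.std(ddof=1)) if n_used > 1 else float("nan")
        mcse_emp = empirical_se / np.sqrt(2.0 * (n_used - 1)) if n_used > 1 \
            else float("nan")
        # delta method: Var(sqrt(mean(se^2))) ~ Var(se^2)/(n * 4 * mean(se^2))
        mcse_model = float(np.sqrt(se2.var(ddof=1) / n_used)
                           / (2.0 * model_se)) if n_used > 1 else float("nan")
    else:
        mean_log_or = rel_bias = coverage = model_se = empirical_se = \
            mcse_cov = mcse_emp = mcse_model = float("nan")

    return PerformanceSummary(
        method=method, phase=phase, n_reps=n_reps, n_used=n_used,
        n_degenerate=n_degenerate, theta_T=theta_T,
        mean_log_or=mean_log_or, relative_bias_pct=rel_bias,
        power_or_type1_pct=power, coverage_pct=coverage,
        model_se=model_se, empirical_se=empirical_se,
        mcse_power=mcse_power, mcse_coverage=mcse_cov,
        mcse_model_se=mcse_model, mcse_empirical_se=mcse_emp,
    )


def summarize_scenario(
    config: ScenarioConfig,
    results: pd.DataFrame,
    methods: Sequence[str] = ("chisq", "glmm"),
) -> pd.DataFrame:
    """Summaries for every method/phase of one cell, as a DataFrame.

    theta_T for each method is its own complete-data mean estimate; for
    the complete phase relative bias is therefore 0 by construction.
    Calibrated dropout-model coefficients and the mean clipped-probability
    fraction are carried along for auditability.
    """
    model = _dropout_model_for(config)
    clipped = float(results["clipped_fraction"].mean())
    rows = []
    for method in methods:
        comp = results[(results["method"] == method)
                       & (results["phase"] == "complete")
                       & ~results["degenerate"]]
        theta_T = float(comp["estimate"].mean()) if len(comp) else float("nan")
        for phase in ("complete", "incomplete"):
            if not ((results["method"] == method)
                    & (results["phase"] == phase)).any():
                continue
            s = summarize(results, method, phase, theta_T)
            row = {
                "prevalence": config.prevalence, "rho": config.rho,
                "hypothesis": config.hypothesis,
                "mechanism": config.mechanism,
                "dropout_pattern": config.dropout_pattern,
                "n_total": config.n_total, "n_reps": config.n_reps,
                "seed": config.seed,
                "clipped_fraction": clipped,
                "gamma1": model.gamma1 if model else float("nan"),
                "gamma2": model.gamma2 if model else float("nan"),
                "gamma3": model.gamma3 if model else float("nan"),
            }
            row.update(dataclasses.asdict(s))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# grid definition and table rendering

_PATTERN_LABEL = {
    "equal": "Equal dropout (30%/30%)",
    "unequal1": "Unequal dropouts 1 (20% control, 40% treatment)",
    "unequal2": "Unequal dropouts 2 (40% control, 20% treatment)",
}


def paper_grid(n_reps: int = 1000, seed: int = 0) -> list[ScenarioConfig]:
    """The full study grid: 2 prevalences x 2 rho x 10 missingness
    scenarios x 2 hypotheses (complete + 3 MCAR + 6 MAR per cell)."""
    grid = []
    cell_seed = seed
    for prevalence, rho in [(0.1, 0.3), (0.1, 0.7), (0.5, 0.3), (0.5, 0.7)]:
        for hypothesis in ("alternative", "null"):
            scenarios = [("none", "equal")]
            scenarios += [("MCAR", p) for p in ("equal", "unequal1", "unequal2")]
            scenarios += [(m, p) for m in ("MAR1", "MAR2")
                          for p in ("equal", "unequal1", "unequal2")]
            for mechanism, pattern in scenarios:
                grid.append(ScenarioConfig(
                    prevalence=prevalence, rho=rho, hypothesis=hypothesis,
                    mechanism=mechanism, dropout_pattern=pattern,
                    n_reps=n_reps, seed=cell_seed,
                ))
                cell_seed += 1
    return grid


def load_scenario_grid(path: str | Path) -> list[ScenarioConfig]:
    """Read scenario definitions from a YAML config file.

    The file holds a list under ``scenarios:`` (or a bare list); each
    entry maps ScenarioConfig field names to values, with optional
    top-level ``defaults``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict):
        defaults = doc.get("defaults", {})
        entries = doc.get("scenarios", [])
    else:
        defaults, entries = {}, doc
    configs = []
    for entry in entries:
        kwargs = {**defaults, **entry}
        configs.append(ScenarioConfig(**kwargs))
    return configs


def _mechanism_label(mechanism: str, pattern: str) -> str:
    if mechanism == "none":
        return "Complete"
    return f"{mechanism}: {_PATTERN_LABEL[pattern]}"


def render_tables(summaries: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Write delimited tables mirroring the study's presentation.

    One file per (prevalence, rho) under the alternative — rows are
    mechanism x dropout pattern x method with log-OR, relative bias,
    power, coverage and SEs — plus one type-I-error table across all
    cells.  Percentages are rounded to 1 decimal, SEs to 3.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    alt = summaries[summaries["hypothesis"] == "alternative"]
    for (prevalence, rho), cell in alt.groupby(["prevalence", "rho"]):
        rows = []
        # the complete-data benchmark is identical across mechanisms run
        # with the same seed; show it once per method
        complete = cell[cell["phase"] == "complete"].drop_duplicates("method")
        incomplete = cell[cell["phase"] == "incomplete"]
        for _, r in pd.concat([complete, incomplete]).iterrows():
            label = ("Complete" if r["phase"] == "complete"
                     else _mechanism_label(r["mechanism"], r["dropout_pattern"]))
            rows.append({
                "scenario": label,
                "method": r["method"],
                "log_or": round(r["mean_log_or"], 3),
                "relative_bias_pct": round(r["relative_bias_pct"], 1),
                "power_pct": round(r["power_or_type1_pct"], 1),
                "coverage_pct": round(r["coverage_pct"], 1),
                "model_se": round(r["model_se"], 3),
                "empirical_se": round(r["empirical_se"], 3),
                "n_used": int(r["n_used"]),
                "n_degenerate": int(r["n_degenerate"]),
            })
        path = outdir / f"summary_p{prevalence}_rho{rho}.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)

    null = summaries[summaries["hypothesis"] == "null"]
    if len(null):
        rows = []
        complete = null[null["phase"] == "complete"].drop_duplicates(
            ["prevalence", "rho", "method"])
        incomplete = null[null["phase"] == "incomplete"]
        for _, r in pd.concat([complete, incomplete]).iterrows():
            label = ("Complete" if r["phase"] == "complete"
                     else _mechanism_label(r["mechanism"], r["dropout_pattern"]))
            rows.append({
                "prevalence": r["prevalence"], "rho": r["rho"],
                "scenario": label,
                "method": r["method"],
                "type1_error_pct": round(r["power_or_type1_pct"], 1),
                "mcse_pct": round(r["mcse_power"], 2),
                "n_used": int(r["n_used"]),
            })
        path = outdir / "type1_error.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
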