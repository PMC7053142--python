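# longbinrct

Monte Carlo simulation of two-arm randomized controlled trials with
repeated binary outcomes and end-of-study dropout, comparing two analyses
of the final-visit treatment effect:

- the **complete-case Pearson χ² test** with a 2×2-table log odds ratio,
  which discards every subject whose final outcome is missing, and
- a **random-intercept logistic GLMM** fitted by restricted
  pseudo-likelihood (PQL/RPL), which keeps the earlier visits of dropouts
  and therefore uses partial information under a missing-at-random
  mechanism.

The package is aimed at biostatisticians studying how missing-data
mechanisms (MCAR, MAR) and dropout rates affect power, type I error, bias,
and coverage of these two estimators.

## Model

Each subject *i* has a latent baseline event probability
*p*<sub>i1</sub> ~ Beta(*a*, *b*), with *a*, *b* solved from the target
prevalence *p* = *a*/(*a*+*b*) and within-subject outcome correlation
ρ = 1/(1+*a*+*b*). Outcomes are Y<sub>ij</sub> ~ Bernoulli(*p*<sub>ij</sub>)
at visits *j* = 1…3 with

> *p*<sub>ij</sub> = *p*<sub>i(j−1)</sub> + δ·X<sub>i</sub>,  δ = 0.05,

so the treatment arm (X<sub>i</sub>=1) gains a 0.10 risk difference by
visit 3 while the control arm stays flat (under the null, *p*<sub>ij</sub>
is constant in both arms). Dropout removes the visit-3 outcome only:
MCAR by exact-fraction simple random sampling per arm, MAR via

> logit Pr(Y<sub>i3</sub> missing) = γ₁ + γ₂Y<sub>i2</sub> + γ₃X<sub>i</sub>,

with γ₂ = ±1.5 (prior responders 4.5 or 0.22 times the odds of dropping
out) and γ₁, γ₃ calibrated by root-finding so the expected per-arm dropout
rates hit their targets (30%/30%, 20%/40%, or 40%/20%).

The GLMM is
logit Pr(Y<sub>ij</sub>=1|b<sub>i</sub>) = β₁ + β₂X<sub>i</sub> + β₃t<sub>ij</sub> + β₄t<sub>ij</sub>X<sub>i</sub> + b<sub>i</sub>,
b<sub>i</sub> ~ N(0, σ<sub>b</sub>²), fitted by the doubly iterative
working-variate scheme with REML variance components; the treatment effect
is the visit-3 contrast β₂ + 3β₄ with Wald-z inference.

## Worked example

```python
import numpy as np
from longbinrct import (ScenarioConfig, run_scenario, summarize_scenario)

cfg = ScenarioConfig(prevalence=0.1, rho=0.7, mechanism="MCAR",
                     dropout_pattern="unequal2",  # 40% control, 20% treatment
                     n_reps=200, seed=42)
summary = summarize_scenario(cfg, run_scenario(cfg))
cols = ["method", "phase", "mean_log_or", "power_or_type1_pct",
        "coverage_pct", "model_se", "empirical_se"]
print(summary[cols].round(3).to_string(index=False))
```

```
method      phase  mean_log_or  power_or_type1_pct  coverage_pct  model_se  empirical_se
 chisq   complete        0.805              81.500        97.500     0.301         0.290
 chisq incomplete        0.850              66.000        98.000     0.379         0.339
  glmm   complete        0.999              85.294        99.412     0.362         0.290
  glmm incomplete        1.013              75.789        99.474     0.417         0.318
```

Reading: N = 398 (the two-proportion design size for 80% power at a 0.10
risk difference from prevalence 0.1), complete-data power is ~82% for the
χ² test; deleting 40%/20% of final outcomes completely at random costs the
complete-case χ² analysis ~15 points of power but the mixed model — which
keeps dropouts' first two visits — only ~10, and both remain unbiased
relative to their own complete-data means (the GLMM's estimate is larger
because a conditional, subject-specific log-OR exceeds the marginal one;
the gap grows with ρ).

A CLI wraps the same machinery:

```sh
longbinrct run --prevalence 0.1 --rho 0.7 --mechanism MCAR --pattern unequal2 \
    --reps 1000 --seed 42 --out results/
longbinrct render results/summary.tsv --out tables/
longbinrct run --full-grid --reps 1000 --out results/   # the full study grid
```

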