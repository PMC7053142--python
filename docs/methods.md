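# Methods

## Data-generating model

A balanced two-arm trial of `n_total` subjects (first half treatment,
second half control — exchangeable with randomization because subjects are
i.i.d.) observes a binary outcome at visits t = 1, 2, 3. Subject *i*'s
baseline event probability is drawn from a Beta(a, b) distribution whose
parameters solve the two moment conditions

    a/(a+b) = prevalence        1/(1+a+b) = rho,

closed form: `a+b = 1/rho − 1`, `a = prevalence·(a+b)`. For a subject
whose probability is constant over visits the correlation between any two
of their Bernoulli outcomes is Var(p)/[p(1−p)] = 1/(1+a+b), so `rho` is
the exact within-subject outcome correlation in the control arm (and in
both arms under the null hypothesis). Under the alternative, each visit
adds `delta = 0.05` to the treatment arm's probability, giving a 0.10
end-of-study risk difference over 3 visits.

**Default sample sizes.** `n_total` defaults to the pooled-variance
two-proportion normal-approximation size (no continuity correction) for
80% power at α = 0.05 against the end-of-study risk difference: 398 for
prevalence 0.1 vs 0.2, and 776 for 0.5 vs 0.6.

**Clipping.** The additive increment can push p above 1 when the Beta draw
is near 1. Probabilities are clipped to [0, 1] after each increment — the
only definition that keeps the Bernoulli draw valid — and the clipped
fraction is logged per replicate (`df.attrs["clipped_fraction"]`). The
effect is negligible at prevalence 0.1 and at (0.5, ρ=0.3), but material
at (0.5, ρ=0.7), where Beta(3/14, 3/14) is U-shaped with P(p₁ > 0.9) ≈
0.33: the clipped visit-3 treatment mean is ≈0.573 rather than 0.60, so
the realized end-of-study risk difference in that cell is ≈0.073, the
marginal log-OR ≈0.30 rather than ≈0.40, and both analyses lose power
relative to an idealized unclipped trial. Summaries for that cell should
be read as properties of the clipped generator.

**Known limitation of the generator.** At prevalence 0.1 the Beta
distribution is extremely skewed (for ρ = 0.7, Beta(0.043, 0.386) puts
roughly a third of subjects at p ≈ 0, i.e. structural all-zero response
vectors), so the logistic-normal random-intercept model fitted downstream
is strongly misspecified there; the latent logit-scale variance of the
generator is ~19.5 at (0.1, 0.3) and ~552 at (0.1, 0.7). Estimates in
those cells are therefore sensitive to estimation conventions (see below),
which real, less extreme data would not be.

The generator does not emulate covariates other than arm and time,
intermittent missingness, or nonlinear trajectories.

## Missingness

Only the final visit is ever deleted (monotone dropout at end of study).

- **MCAR**: within each arm, exactly `round(rate × arm size)` subjects are
  chosen by simple random sampling without replacement. Exact-count
  deletion removes binomial noise from the realized rate; the distinction
  from i.i.d. Bernoulli deletion is immaterial to every performance
  measure at Monte Carlo error.
- **MAR**: each subject's final outcome is deleted with probability
  expit(γ₁ + γ₂y₂ + γ₃X). γ₂ is fixed (+1.5 or −1.5); γ₁ solves
  `(1−π_c)·expit(γ₁) + π_c·expit(γ₁+γ₂) = control target` with
  π_c = prevalence (the marginal visit-2 mean), and γ₁+γ₃ solves the
  analogous treatment-arm equation with π_t = prevalence + delta
  (prevalence under the null). Both equations are strictly monotone in the
  intercept and are solved by Brent bracketing to |residual| < 1e-8.
  Calibration uses the analytic marginal means of the generative model,
  not per-replicate empirical tuning, so the γ values are fixed,
  replicate-independent quantities; the (tiny) clipping-induced deviation
  of π_t from its analytic value is accepted, not corrected.

## Analyses

**Complete-case χ².** Non-missing visit-3 outcomes are tabulated 2×2 by
arm. The test is the uncorrected Pearson χ² on 1 df; the estimate is
log[(n11·n00)/(n10·n01)] with Woolf SE √(Σ 1/cell) and a ±1.96·SE interval.
Zero-cell tables get no 0.5 correction: the replicate is flagged
degenerate, excluded from estimate-based measures, and counted in the
summary (the Pearson test is still attempted when both margins are
positive). Rejection for power/type-I error uses the Pearson p-value, not
the Wald p.

**Random-intercept logistic GLMM (RPL/PQL).** The model
logit Pr(Y=1|b) = β₁ + β₂X + β₃t + β₄tX + b, b ~ N(0, σ_b²), time
continuous, coded 1, 2, 3. Estimation is the doubly iterative
Breslow–Clayton scheme: linearize at the current (β, b̂) via the working
variate z = η + (y−μ)/[μ(1−μ)] with weights w = μ(1−μ); fit the weighted
linear mixed pseudo-model z = Xβ + b + ε, ε ~ N(0, φW⁻¹), by REML (the
"restricted" in restricted pseudo-likelihood), profile β by GLS, update
the BLUPs, repeat. With a single random intercept every blockwise
operation reduces, via the rank-one Woodbury identity, to per-subject
weighted sums, so the inner REML criterion is one-dimensional in
θ = σ_b²/φ and is minimized by bounded Brent search on log θ (xatol
1e-11, warm-started between outer iterations, brackets expanded on
demand).

Numerical conventions that matter:

- **Residual scale.** By default φ is *fixed at 1*: a Bernoulli response
  has no dispersion parameter, so the pseudo-model's residual variance is
  exactly W⁻¹. `estimate_scale=True` instead profiles φ out of the REML
  criterion, which reproduces dispersion-carrying PQL implementations —
  the package's scale-estimated fit matches `MASS::glmmPQL` on identical
  data to ~3e-3 in β (this is the cross-implementation oracle in the test
  suite). In well-behaved cells the two conventions differ modestly; in
  the misspecified prevalence-0.1 cells described above the
  scale-estimated variant drifts to much larger σ̂_b² (and hence larger
  conditional effect estimates), so the fixed-scale convention is the
  default.
- **Convergence**: scaled change max|Δ|/(1+|old|) over (β, σ_b², φ) below
  1e-8, at most 100 outer linearizations; non-convergence flags the
  replicate degenerate (counted and excluded from estimate-based
  summaries). σ̂_b² = 0 is an allowed boundary solution.
- **Initialization**: β from plain Newton logistic regression ignoring
  clustering, σ_b² = 0.1, b = 0. The linear predictor is capped at ±20 to
  keep working weights positive.
- **Inference**: treatment effect = β₂ + 3β₄ (the arm difference in
  log-odds at visit 3 under the t = 1, 2, 3 coding; an alternative 0, 1, 2
  coding gives the identical estimate with contrast β₂ + 2β₄). Wald z with
  a normal reference — at N ≥ 398 a t reference with containment df would
  be indistinguishable — and a ±1.96·SE interval. No likelihood-ratio
  test, since the maximized quantity is not a true likelihood.

The GLMM estimates a conditional (subject-specific) log-OR, which exceeds
the marginal 2×2 log-OR in absolute value, increasingly so as σ_b² (i.e.
ρ) grows; on complete data this attenuation ordering is a structural
property, not a bias.

## Performance measures

Per cell and method: power/type-I error = % of p-values < 0.05 among
replicates with a defined p-value; mean log-OR; relative bias
100·(θ̄̂ − θ_T)/θ_T; coverage = % of 95% CIs containing θ_T; model SE =
√(mean SE²); empirical SE = SD of estimates. θ_T is the *same method's*
mean complete-data estimate from the same seed-paired run, so each method
is benchmarked against itself and complete-phase bias is identically 0.
Monte Carlo SEs: binomial √(p̂(1−p̂)/n) for proportions, s/√(2(n−1)) for
the empirical SE, and a delta-method form SD(SE²)/(2·modelSE·√n) for the
model SE. Degenerate replicates (zero cells, non-convergence) are excluded
from estimate-based measures, retained in rejection-rate denominators when
a p-value exists, and reported as counts.

## Reproducibility

Each replicate draws from `SeedSequence((cell seed, replicate index,
stream))`, with separate streams for generation and dropout, so any
replicate can be regenerated in isolation and the complete data are
identical across missingness mechanisms run with the same seed (which is
what makes θ_T seed-paired). Reruns are byte-identical.

## Problem sizes

The shipped acceptance script and the heavy end of the test suite use
1000 replicates per cell — the design's own Monte Carlo size, with power
MCSE ≈ 1.1–1.6 percentage points — at the design sample sizes N = 398 and
776; a full four-cell grid at these sizes runs in a few minutes on one
CPU. Property checks that need only marginal moments use single large
replicates (2×10⁵–10⁶ subjects) instead of replicate loops.
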