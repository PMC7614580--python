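# Methods

`seqtrials` estimates per-protocol effects of a sustained binary treatment
on survival from longitudinal observational data with time-dependent
confounding. This note records the models, the synthetic-data mechanism,
the numerical choices, and the design decisions behind the implementation.

## Estimand

Individuals are observed at visits k = 0, 1, ..., K-1, with visit k at
time k; treatment A_k and a confounder L_k are recorded at each visit and
held constant between visits. The target is the marginal risk difference

    RD(tau) = Pr(T^{always} > tau) - Pr(T^{never} > tau),

the difference in counterfactual survival at horizon tau between the
strategies "start treatment at time 0 and continue" and "never start",
standardized to a stated reference population (by default the cohort's
own baseline-confounder distribution). A positive RD means better
survival under sustained treatment. Identification requires the usual
conditions: consistency, positivity, and no unmeasured confounding given
the recorded covariate history.

## The two estimators

**Whole-cohort weighted MSM (`MSMIPTW`).** Person-periods are weighted by
stabilized inverse-probability-of-treatment weights: the cumulative
product over visits of Pr(A_k | limited history) / Pr(A_k | full
confounder history), with unit factors once treatment is absorbed. The
denominator is a pooled logistic model of initiation on the current
confounder (the correct form under the synthetic mechanism); the
numerator has a separate intercept — and, when the hazard model
conditions on L_0, a separate L_0 coefficient — per visit. The weighted
hazard model expresses the counterfactual hazard at time t through the
full treatment history a_{floor(t)}, a_{floor(t)-1}, ..., a_0, one
coefficient per lag, optionally plus L_0. Marginal survival follows
either directly (marginal model) or by cloning-based standardization.

**Sequential trial emulation (`SequentialTrials`).** A trial is emulated
at each visit k among individuals alive and treatment-naive at k
(configurable washout); initiators (A_k = 1) form one arm, non-initiators
the other. Records are artificially censored at the first visit where
observed treatment deviates from the arm, and the informative censoring
so introduced is corrected by inverse-probability-of-artificial-censoring
weights: 1 during each trial's first interval and on the initiator arm
(treatment is absorbing), and otherwise the cumulative product of
stabilized probabilities of remaining untreated, with the numerator
conditioning on the trial-baseline confounder and the denominator on the
current one. A pooled hazard model in the constant arm and the
trial-baseline confounder is fitted across trials on the
time-since-trial-start scale, assuming common coefficients (a Wald test
of trial-by-arm interactions, `test_common_treatment_effect`, probes this
assumption). Marginal curves are standardized by cloning, with each
reference member's trial-baseline value set to their L_0.

Both pipelines accept optional pooled weight truncation (default off; the
95th-percentile variant mirrors the usual robustness check). The
truncation cap is the lower (order-statistic) percentile, so truncation
is exactly idempotent.

### Hazard models

The default hazard MSM is an additive (Aalen) model with time-varying
cumulative coefficients: at every event time the coefficient increment
solves the weighted least-squares normal equations over the at-risk
design matrix, and cumulating increments gives step-function paths
B_j(t). This family is closed under marginalization over independent
covariates, so the whole-cohort and the sequential-trials hazard models
can both be correctly specified under the additive synthetic mechanism —
the property that makes an unbiased head-to-head efficiency comparison
meaningful. A Cox MSM (weighted partial likelihood via lifelines, Efron
tie correction, weighted Breslow cumulative baseline, optional
trial-stratified baseline with the trial-0 baseline used for
standardization) is provided as the proportional-hazards alternative;
because hazard ratios are non-collapsible the two Cox variants cannot
both be exactly correct, so the test suite asserts unbiasedness only for
the additive route.

Survival is evaluated as S(tau) = exp(-H(tau)) on the exact event-time
step function, fitted once over all event times up to the maximum horizon
so that curves are monotone by construction. A product-limit transform
(prod(1 - dH) over distinct event times) is available; it reproduces
discrete weighted survivor proportions exactly and is what makes the
model-based pipeline agree to machine precision with the closed-form
nonparametric estimators in the two-visit binary setting (`causal_tree`).

### Design and numerical choices

- **Interval-dependent lag design.** In the whole-cohort additive MSM the
  lag-j treatment column enters the design only for event times at or
  after interval j; earlier it is identically zero and would make the
  normal equations singular.
- **Singular increments** (scale-aware determinant test) are skipped with
  the cumulative carried forward, counted in `n_skipped`; a strict mode
  raises instead.
- **Negative fitted increments** are retained — clipping would bias the
  cumulative coefficients — and only the final survival value is clamped
  to [0, 1], with a diagnostic count.
- **Probabilities** entering weight ratios are floored at 1e-12 with a
  positivity warning; truly extreme weights are surfaced by the
  max-weight-by-period diagnostics rather than silently capped.
- **Visit grid.** All fitting assumes rows aligned to the unit visit grid
  (tstart integer, tstop <= tstart + 1); irregular visit schedules are out
  of scope.
- **Event-time convention.** Intervals are half-open [k, k+1); an event
  at exactly an integer time belongs to the interval ending there. Lag
  values before baseline are 0 (no treatment before follow-up).
- **Artificial censoring time.** A deviation observed at visit m censors
  the trial record at trial time m - k: the interval starting at the
  deviation visit no longer belongs to the assigned arm.
- **IPACW numerator form.** The stabilizing numerator for remaining
  untreated has a separate intercept and trial-baseline-confounder
  coefficient per deciding visit, fitted across all trials combined; the
  model is a stabilizer only, so its exact form does not affect
  consistency.
- **Ties.** Simulated event times are continuous, so ties have
  probability zero; for user data, tied times share a risk set in the
  additive fit and the Cox fit uses the Efron correction.

## Synthetic-data mechanism

`simulate_cohort` draws, per individual: a frailty U ~ N(0, 0.1) (0.1 is
the variance); L_0 ~ N(U, 1); treatment initiation
logit Pr(A_k = 1 | untreated, L_k) = gamma0 + gammaL * L_k with treatment
absorbing thereafter; confounder updates
L_k ~ N(delta0 + deltaL L_{k-1} + deltaA A_{k-1} + deltaT k + U, 1); and
an event time from the piecewise-constant conditional hazard

    h = alpha0 + alphaA A_k + alphaL L_k + alphaU U   on [k, k+1),

drawn by inversion of the piecewise-exponential survivor function, with
administrative censoring at time K = 5. Negative conditional hazards
(an extreme-tail possibility since alphaA < 0 and L is Normal) are
clipped at zero with a logged count. Defaults (scenario presets):

| parameter | scenario1 | scenario2 | scenario3 | meaning |
|---|---|---|---|---|
| delta0, deltaL, deltaA, deltaT | 0, 0.8, -1, 0.1 | same | same | confounder process |
| gamma0, gammaL | -1, 0.5 | -3, 0.5 | -1, 3 | initiation model |
| alpha0, alphaA, alphaL, alphaU | 0.2, -0.04, 0.015, 0.015 | same | same | conditional hazard |

Scenario 1 yields roughly 57% events over the five units of follow-up and
about 28% treated at the first visit (the initiation model's analytic
baseline treated fraction is 27.8%); scenario 2 makes initiation rare
(about 5% at baseline, 62% events); scenario 3 makes initiation depend
strongly on the confounder, stressing positivity. Treatment is absorbing
in every preset, so the initiation model is never evaluated at treated
histories and needs no coefficient for past treatment.

The generator emulates time-dependent confounding with feedback and a
shared frailty. It does **not** emulate loss to follow-up (an IPCW hook
exists and returns unit weights when no dropout process is present),
irregular or mismeasured visits, multivariate confounders, or
non-absorbing treatment (the estimators support deviation in either
direction; the generator does not produce it). Passing tests therefore
demonstrate correctness of the estimators under this mechanism, not
robustness to those real-data features.

**Ground truth** comes from re-running the identical mechanism with the
treatment path forced ("always" / "never") for one million individuals
and taking empirical survivor functions (equal to Kaplan-Meier in the
absence of censoring before the horizon). Treatment-assignment parameters
do not enter the counterfactual world, so one packaged truth table
(`data/truth_curves.csv`, grid step 0.01) serves all presets; it can be
regenerated with `seqtrials truth`.

**Randomness.** Each cohort uses one seeded numpy Generator with a fixed
draw order (frailty, then per-visit confounder and treatment, then one
exponential deviate per individual), so any seed reproduces the cohort
exactly. Replicated studies derive per-replicate seeds by a counter-based
affine split of the master seed, making any subset of replicates
independently reproducible. The bootstrap splits its master seed the same
way; the resampling unit is always the individual, so all of a person's
rows and trial appearances travel together.

## Inference

Percentile bootstrap over individuals: trial formation, weight-model
fitting, hazard-model fitting and standardization are repeated in every
resample, so intervals reflect weight-estimation uncertainty. Quantiles
use numpy's default linearly interpolated (type-7) definition. Resamples
whose fit fails are dropped and counted; more than 10% failures aborts.
Analytic (sandwich) variances are deliberately not provided.

## Study runner and problem sizes

`run_study` replicates simulate-fit-standardize over both estimators,
reporting per-quantity Monte-Carlo means, empirical SDs, bias against the
truth table, Monte-Carlo errors, and the relative efficiency of the
sequential-trials approach (inverse ratio of empirical risk-difference
variances). The package's own reference configuration is 200 replicates
of n = 5000 per scenario — enough that Monte-Carlo means are stable to
about three decimals — with 1000 replicates available as a configuration
option. The acceptance script (`scripts/acceptance.py`) uses the 200 x
5000 configuration; the test suite uses smaller cohorts for unit-level
checks and n = 50000 for the single-cohort parameter-recovery check.
Coverage of the bootstrap is checked at a reduced scale (100 cohorts of
n = 500 with B = 100).

## Known limitations

- Scalar time-dependent confounder in the simulator and default model
  forms (the fitting machinery accepts arbitrary named design columns).
- No grace periods, no competing risks, no interval censoring, at most
  two regimes in the trial emulation.
- The Cox route's time-varying treatment-effect form f(t; beta) is
  restricted to the proportional (constant) case.
- Risk ratios, survival ratios and restricted-mean contrasts are one-line
  extensions of the survival-curve output but are not implemented as
  first-class estimands.
- The non-absorbing-treatment weight path (separate initiation and
  discontinuation models) exists as an option and is exercised only by
  synthetic tests.
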