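# seqtrials

Causal survival estimation for **time-varying treatments** from
longitudinal observational data, for biostatisticians and
epidemiologists analysing registry-style cohorts. The package implements
and compares two approaches to the same per-protocol estimand — the
marginal risk difference between sustained treatment and no treatment:

* **Whole-cohort weighted MSM** (`MSMIPTW`): a marginal structural hazard
  model in the full treatment history, fitted to person-periods weighted
  by stabilized inverse-probability-of-treatment weights
  `prod_k Pr(A_k | limited history) / Pr(A_k | confounder history)`.
* **Sequential trial emulation** (`SequentialTrials`): a trial is emulated
  at every visit among the treatment-naive, comparing initiators to
  non-initiators, with records artificially censored at deviation from
  the baseline arm and re-weighted by inverse-probability-of-
  artificial-censoring weights.

Both support an additive (Aalen) hazard MSM with time-varying cumulative
coefficients — fitted by weighted least squares at every event time — and
a weighted Cox MSM with a Breslow baseline. Counterfactual survival
curves `S_a(tau) = exp(-H_a(tau))` are standardized to a reference
population by cloning, and uncertainty comes from a nonparametric
bootstrap over individuals. A synthetic-cohort generator with
treatment-confounder feedback, a nonparametric "causal tree" module for
the two-visit binary setting (where the two approaches are provably
identical), and a replicated study runner round out the package. See
`docs/methods.md` for the models and design decisions.

## Worked example

```python
from seqtrials import MSMIPTW, SequentialTrials, simulate_cohort

cohort = simulate_cohort("scenario1", n=5000, seed=42)   # ~57% events
est = SequentialTrials(msm="aalen").fit(cohort)
print(est.risk_difference_.to_frame().round(3))
```

```
   tau     S1     S0     RD
0  1.0  0.857  0.820  0.037
1  2.0  0.749  0.672  0.077
2  3.0  0.654  0.549  0.105
3  4.0  0.573  0.441  0.132
4  5.0  0.502  0.357  0.145
```

`S1` and `S0` are the standardized counterfactual survival probabilities
under "always treated" and "never treated"; `RD` is their difference, so
here sustained treatment raises 5-year survival by about 14 percentage
points (the generator's true value is 0.137; a single replicate of
n = 5000 carries Monte-Carlo noise of roughly ±0.05 at tau = 5).
`MSMIPTW().fit(cohort)` targets the same quantities through the
whole-cohort weighting route, and
`bootstrap_ci(est, cohort, B=1000)` adds percentile confidence
intervals. A `seqtrials` command-line interface wraps simulation, truth
computation, single-cohort fits and replicated studies:

```bash
seqtrials study --scenario scenario1 --n 5000 --reps 200 --out out/
```

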