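# nestedcc

A toolkit for **matched nested case-control analyses** of longitudinal
cohort and trial data, motivated by secondary analyses of neonatal feeding
trials: does exposure to non-breast-milk feeds (formula or fortifier)
raise the odds of necrotising enterocolitis (NEC) in high-risk preterm
infants? The same machinery applies to any cohort with a rare outcome, a
time-dependent exposure recorded as a daily log, and known confounders to
match on.

It is written for biostatisticians and trialists who want to run — or
study the operating characteristics of — this design without hand-rolling
the sampling and likelihood machinery.

## The design and the model

Each time a subject experiences the outcome at day *t* (a **case**), the
**risk set** is every cohort member still under follow-up and event-free
at *t* (incidence-density sampling). From that risk set, *m* controls (4
by default) are selected without replacement: exact-matched on sex, then
closest to the case by **Mahalanobis distance** on gestational age and
birth weight,

d(x, y) = sqrt((x − y)ᵀ Σ⁻¹ (x − y)),

with Σ the sample covariance of the matching covariates over the whole
cohort (the two are strongly collinear, so matching them jointly needs
the covariance-adjusted metric). Subjects may serve as controls for
several cases, and future cases are eligible as controls in earlier risk
sets — both required for unbiased rate-ratio estimation. Exposure for
every member of a matched set is classified **strictly before the case's
event day**, on the gap-filled daily feed log truncated at that day, so
post-outcome feeding changes cannot leak into the exposure.

Each matched set *j* (one case, up to *m* controls, covariates x_k) is a
stratum of a **conditional logistic regression**:

ℓ(β) = Σ_j [ x_case(j)ᵀ β − log Σ_{k ∈ j} exp(x_kᵀ β) ],

maximised by Newton–Raphson with analytic gradient and Hessian; exp(β̂)
estimates the incidence-rate ratio of the outcome for exposed versus
unexposed, adjusted for the matching factors by design and optionally for
trial arm as a covariate. The classical relative efficiency of 1:m
matching versus using the full risk set is m/(m+1) — the reason the
toolkit defaults to four controls per case: a fifth buys only ~4%.

A synthetic-cohort generator (`nestedcc.simulate`) draws preterm cohorts
with correlated gestational age/birth weight, arm-dependent exposure
hazards, a discrete-time logistic outcome hazard with a known exposure
log-odds ratio, and daily feed logs with gaps — so the whole pipeline can
be validated against ground truth.

## Worked example

```python
from nestedcc import (SimulationConfig, simulate_cohort, MatchingSpec,
                      sample_all, build_analysis_table, fit_clogit)

cohort = simulate_cohort(SimulationConfig(n_subjects=398, seed=7))
sets = sample_all(cohort, MatchingSpec(controls_per_case=4), seed=7)
rows = build_analysis_table(sets, cohort)          # 4 default exposures
res = fit_clogit(rows, "any_prior", adjust_for=("trial_arm",))
print(res.summary())
```

```
Conditional logistic regression (matched sets)
  sets: 50 (50 informative)
  cases: 50   controls: 200
  log-likelihood: -77.9018   converged: True (4 iterations)
  term                    coef        se        OR      2.5%     97.5%
  any_prior             0.6209    0.3974    1.8606    0.8539    4.0540
  arm_early             0.3417    0.3496    1.4074    0.7093    2.7927
```

This cohort was generated with a true exposure odds ratio of 2: any prior
non-breast-milk feed carries an estimated OR of 1.86 (95% CI 0.85–4.05) —
consistent with the truth, wide because a 398-infant cohort yields only
50 matched sets. `baseline_table(cohort, sets)` prints the Table-1-style
summary; note how matching equalises sex exactly and gestational
age/birth weight closely between cases and matched controls:

```
                                                  cases  matched_controls          non_cases
n                                                    50               200                348
male sex, n (%)                               26 (52.0)        104 (52.0)         181 (52.0)
...
gestational age (weeks), median (IQR)     30 (28 to 31)     30 (29 to 31)      31 (29 to 32)
birth weight (g), median (IQR)         876 (714 to 974)  871 (732 to 986)  973 (793 to 1185)
Controls: 200 slots, 135 unique, 55 sampled more than once, 10 later became cases.
```

The same pipeline is scriptable from the shell: `ncc simulate`, `ncc
sample`, `ncc analyze`, `ncc report`, all driven by one YAML config (see
`nestedcc.pipeline.RunConfig` for the schema).

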