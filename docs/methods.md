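# Methods

## Cohort model

Time is measured in integer days since delivery (day 0 = delivery day);
the motivating data are daily feed logs, so no sub-day resolution exists.
A subject's follow-up is [0, exit_day], with exit at the first of the
outcome event, death, or the end of the daily log; only a single
`exit_day` is recorded, so death and loss-to-follow-up are not
distinguished. A subject whose event and exit fall on the same day is
treated as exiting *because of* the event. Only first events count:
recurrences are out of scope, and a case never re-enters later risk sets.
`trial_arm` is optional so non-trial cohorts can be analysed; operations
that need it (arm adjustment) fail explicitly when it is absent. Unknown
feed types are preserved as `"unknown"` rather than dropped; the gap
filler and classifier decide their effect.

## Risk sets and eligibility

At a case's event day *t*, eligible controls are subjects with
`exit_day >= t` and no event on or before *t*, excluding prior cases and
the case itself. Two boundary rules are deliberate design choices, not
field conventions:

- a subject exiting (without event) exactly on day *t* **is** at risk —
  the conservative reading of "still at risk";
- a subject with its own event on day *t* is **not** eligible for
  another same-day case; same-day cases are processed in seeded random
  order, and each is excluded from the other's risk set either way.

Future cases are eligible as controls before their own event, and the
same subject may be sampled into several sets (without replacement
within a set) — both properties are required for the conditional-logit
odds ratio to estimate the incidence rate ratio.

## Matching

Controls are exact-matched on sex and ranked by Mahalanobis distance on
(gestational age, birth weight). The covariance Σ is the sample
covariance over the *entire* cohort, estimated once, so the metric is
identical across risk sets; per-risk-set covariances would make
distances incomparable between sets and are noisier. A numerically
singular Σ is ridge-regularised by εI (ε = 1e-8 by default) with a
warning; a zero-variance factor is an error because no ridge makes the
distance meaningful. Squared distances within a relative tolerance of
1e-9 of the m-th smallest are treated as tied at the selection boundary
and broken uniformly at random from the caller's seeded generator;
interior ties never affect membership. Sets with fewer than m eligible
same-sex subjects keep all of them and are flagged short rather than
dropped — the likelihood handles variable set sizes.

## Exposure classification

Gap filling: an interior run of ≤ `max_gap` missing days flanked on both
sides by the same recorded feed type is imputed with that type; runs
flanked by different types, longer runs, and leading days are `unknown`.
The default `max_gap` = 2 days reflects that a one- or two-day hole in
an otherwise constant feeding pattern is almost surely clerical, while
longer holes or holes spanning a change are genuinely ambiguous. The
true gap rule of the motivating study is not public, so this rule is a
declared stand-in, and it is configurable.

Classification at index day *t* (the case's event day, shared by all
members of the set) inspects days strictly before *t* only: a diagnosis
changes subsequent feeding, so "first 14 days" means days [0, min(14, t))
and "any prior" means [0, t). Filling runs on the log truncated at *t*,
so a record on or after the index day can never influence a flag — this
is enforced by a property test that mutates post-index records at
random. `unknown` days never count as exposure, and a change in feed
type requires two *consecutive known* days with different types (the
change attributed to the later day, within the trailing k-day window);
transitions into or out of unknown are not changes. Fortifier counts as
exposure alongside formula: fortified breast milk is a non-exclusive
breast-milk feed.

## Conditional logistic regression

The Breslow-style conditional likelihood for sets with exactly one case
(guaranteed by construction, so no tie-handling variants are needed):

ℓ(β) = Σ_j [ x_case(j)ᵀ β − log Σ_{k∈j} exp(x_kᵀ β) ].

Sets whose members all share one covariate vector contribute −log(set
size) and are counted non-informative but retained (they only shift the
constant). Fitting is Newton–Raphson from β = 0 with step-halving
whenever a step would decrease the likelihood; convergence at gradient
max-norm < 1e-8 or relative log-likelihood change < 1e-10. Group
log-sum-exp terms are max-centred for numerical stability. Standard
errors come from the inverse observed information; intervals are Wald,
exp(β̂ ± 1.96·SE) — profile intervals are out of scope. When the MLE
diverges (exposure perfectly predicting case status across informative
sets), the coefficient runs away; a max |β| > 15 on the log-odds scale
(OR > 3×10⁶) is taken as separation and the result is returned flagged
non-converged with the direction of divergence. Zero informative sets
raise "no discordant sets". The implementation is cross-checked in the
tests against statsmodels' conditional logit (an independent likelihood
implementation and optimizer) to 1e-6, and against the n10/n01 closed
form for 1:1 discordant pairs.

## Synthetic cohort generator

The generator emulates the study conditions the toolkit was designed
for: ~400 growth-restricted preterm infants, randomised 1:1 to early vs
late introduction of milk feeds, followed 56 days.

- **Covariates.** GA ~ Normal(31, 2.5²) weeks clipped to [24, 37];
  BW = −1480 + 80·GA + Normal(0, 205²) g, giving a GA–BW correlation of
  ≈ 0.70 (checked at n = 20000). These are illustrative values loosely
  matched to published preterm growth-restricted samples, not estimates.
- **Feeding.** Two-state daily process: breast → non-breast with
  arm-specific hazard (per-episode type: formula with probability 0.7,
  else fortifier), non-breast → breast with daily probability 0.05, so
  feed-type changes occur. Because the first switch is geometric, the
  14-day exposure probability is exactly 1 − (1 − h)¹⁴; the default
  hazards are the closed-form solutions for the 44% (early) / 23% (late)
  targets: h = 0.040570 and 0.018496. (A root-finder is unnecessary —
  the closed form is exact.)
- **Outcome.** Daily Bernoulli event at days 1..56 with
  logit h_t = logit(h₀) + β_e·[any non-breast feed before t] +
  β_GA·(GA − 31) + β_BW·(BW − BW̄)/100, defaults β_e = log 2,
  β_GA = −0.12/week, β_BW = −0.10/100 g. The discrete-time logistic
  hazard (rather than continuous-time exponential) matches the integer
  day axis, and under rare events its exposure log-odds equals the
  estimand of the conditional-logit analysis, so recovery experiments
  have a known truth. h₀ = 0.001 is calibrated once so the defaults give
  ≈ 9% cumulative incidence.
- **Missingness.** Each log day is deleted independently with
  probability 0.03 — small random gaps only. Real feed logs also have
  structural missingness (sick days, transfers) that this does not
  emulate, so passing tests show the pipeline handles random gaps, not
  informative ones.

`simulate_cohort_fixed_cases` pins the number of cases exactly (events
reassigned to randomly chosen fully-followed subjects with uniform event
days) for design-accounting checks where the case count must be a known
constant.

## Experiment sizes

Recovery and efficiency experiments default to n = 2000 subjects per
replicate with 150–200 replicates — enough that the Monte Carlo standard
error of the mean log-OR is ≈ 0.02 and variance ratios are stable, while
one replicate of the full pipeline runs in ~0.2 s. The 1:1 vs 1:4
variance ratio is computed on *shared* cohorts per replicate (paired
design), which removes most between-cohort noise from the ratio.

## Known limitations

- Greedy per-risk-set matching in event order; no optimal global
  matching, calipers, propensity scores or counter-matching.
- No distinct mortality process: death is folded into a single exit day.
- Wald inference only; exact conditional or profile-likelihood inference
  is not provided.
- The baseline table reports control *slots* (duplicates counted per
  sampling) in its main column, with unique/reuse counts as footnotes;
  percentages are therefore weighted by sampling multiplicity by design.
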