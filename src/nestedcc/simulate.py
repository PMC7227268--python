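"""Synthetic preterm cohorts with known ground truth.

Emulates the kind of cohort the design was built for: growth-restricted
preterm infants with correlated gestational age and birth weight, a trial
arm that shifts the daily hazard of switching from breast milk to
formula/fortifier, a discrete-time logistic hazard of the outcome driven
by prior exposure and the two matching covariates, and daily feed logs
with occasional missing days.

The feed process is two-state per day: a breast-fed infant switches to a
non-breast feed (formula or fortifier, drawn once per episode) with an
arm-specific daily hazard; a non-breast-fed infant reverts to breast with
a small daily probability, so changes in feed type occur.  Because the
first switch is geometric, the probability of any non-breast feed in the
first 14 days is exactly 1 - (1 - h)^14; the default arm hazards are the
exact solutions for the 44% (early) and 23% (late) prevalence targets.

The outcome is a daily Bernoulli event at days 1..followup_days with
logit hazard linear in ever-exposed-before-today, gestational age and
birth weight; exit is the first of the event day or the end of follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clogit import fit_clogit
from .cohort import Cohort, cohort_from_frames
from .exposure import ExposureDefinition, build_analysis_table
from .matching import MatchingSpec, sample_all

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "simulate_cohort_fixed_cases",
    "RecoverySummary",
    "recovery_experiment",
    "paired_variance_experiment",
    "efficiency_table",
]

#: exact solutions of 1 - (1 - h)^14 = p for p = 0.44 / 0.23
SWITCH_HAZARD_EARLY = 0.04056969868538762
SWITCH_HAZARD_LATE = 0.01849572698948565


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults emulate the motivating cohort.

    ``bw_intercept/bw_slope/bw_resid_sd`` define birth weight (g) as a
    linear function of gestational age (weeks) plus noise; the defaults
    give a GA-BW correlation near 0.7.  ``log_or_ga`` is per week above
    ``ga_mean``; ``log_or_bw`` per 100 g above the expected birth weight
    at ``ga_mean``.  ``baseline_event_hazard`` is tuned so the defaults
    produce roughly 9% cumulative incidence over follow-up.
    """

    n_subjects: int = 398
    seed: int = 0
    p_male: float = 0.53
    ga_mean: float = 31.0
    ga_sd: float = 2.5
    bw_intercept: float = -1480.0
    bw_slope: float = 80.0
    bw_resid_sd: float = 205.0
    p_early_arm: float = 0.5
    switch_hazard_early: float = SWITCH_HAZARD_EARLY
    switch_hazard_late: float = SWITCH_HAZARD_LATE
    p_revert: float = 0.05
    p_formula_episode: float = 0.7
    baseline_event_hazard: float = 0.001
    log_or_exposure: float = math.log(2.0)
    log_or_ga: float = -0.12
    log_or_bw: float = -0.10
    followup_days: int = 56
    gap_rate: float = 0.03

    def __post_init__(self):
        probs = {
            "p_male": self.p_male,
            "p_early_arm": self.p_early_arm,
            "switch_hazard_early": self.switch_hazard_early,
            "switch_hazard_late": self.switch_hazard_late,
            "p_revert": self.p_revert,
            "p_formula_episode": self.p_formula_episode,
            "baseline_event_hazard": self.baseline_event_hazard,
            "gap_rate": self.gap_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.ga_sd <= 0 or self.bw_resid_sd <= 0:
            raise ValueError("ga_sd and bw_resid_sd must be positive")
        if self.followup_days < 28:
            raise ValueError("followup_days must be >= 28")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def _logit(p):
    return math.log(p / (1.0 - p))


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> Cohort:
    """Draw one cohort; fully reproducible given config and seed.

    ``seed`` overrides ``config.seed`` when given (convenient for
    replicated experiments).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    T = config.followup_days

    sex = np.where(rng.random(n) < config.p_male, "male", "female")
    ga = np.clip(rng.normal(config.ga_mean, config.ga_sd, size=n), 24.0, 37.0)
    bw = config.bw_intercept + config.bw_slope * ga + rng.normal(
        0.0, config.bw_resid_sd, size=n
    )
    bw = np.clip(bw, 400.0, None)
    early = rng.random(n) < config.p_early_arm
    arm = np.where(early, "early", "late")
    switch_h = np.where(early, config.switch_hazard_early, config.switch_hazard_late)

    # daily feed process over days 0..T; per-episode non-breast type
    feed = np.empty((T + 1, n), dtype=object)
    nonbreast = np.zeros(n, dtype=bool)
    episode_type = np.full(n, "formula", dtype=object)
    switch_u = rng.random((T + 1, n))
    revert_u = rng.random((T + 1, n))
    type_u = rng.random((T + 1, n))
    for t in range(T + 1):
        start_episode = ~nonbreast & (switch_u[t] < switch_h)
        episode_type[start_episode] = np.where(
            type_u[t, start_episode] < config.p_formula_episode,
            "formula",
            "fortifier",
        )
        end_episode = nonbreast & (revert_u[t] < config.p_revert)
        nonbreast = (nonbreast | start_episode) & ~end_episode
        feed[t] = np.where(nonbreast, episode_type, "breast")

    exposed_before = np.zeros((T + 1, n), dtype=bool)  # any non-breast day < t
    nb_day = feed != "breast"
    exposed_before[1:] = np.cumsum(nb_day[:-1], axis=0) > 0

    # discrete-time logistic event hazard at days 1..T
    bw_ref = config.bw_intercept + config.bw_slope * config.ga_mean
    lin0 = (
        _logit(config.baseline_event_hazard)
        + config.log_or_ga * (ga - config.ga_mean)
        + config.log_or_bw * (bw - bw_ref) / 100.0
    )
    event_u = rng.random((T + 1, n))
    event_day = np.full(n, -1, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    for t in range(1, T + 1):
        eta = lin0 + config.log_or_exposure * exposed_before[t]
        hazard = 1.0 / (1.0 + np.exp(-eta))
        hit = alive & (event_u[t] < hazard)
        event_day[hit] = t
        alive &= ~hit

    event = event_day >= 0
    exit_day = np.where(event, event_day, T)

    ids = np.array([f"S{i:05d}" for i in range(n)], dtype=object)
    subjects = pd.DataFrame(
        {
            "id": ids,
            "sex": sex,
            "gestational_age": np.round(ga, 1),
            "birth_weight": np.round(bw, 0),
            "trial_arm": arm,
            "exit_day": exit_day,
            "event": event,
            "event_day": pd.array(
                [d if d >= 0 else pd.NA for d in event_day], dtype="Int64"
            ),
        }
    )

    keep = rng.random((T + 1, n)) >= config.gap_rate
    day_idx, subj_idx = np.nonzero(keep & (np.arange(T + 1)[:, None] <= exit_day))
    feed_log = pd.DataFrame(
        {
            "id": ids[subj_idx],
            "day": day_idx,
            "feed_type": feed[day_idx, subj_idx],
        }
    ).sort_values(["id", "day"], kind="stable")

    return cohort_from_frames(subjects, feed_log)


def simulate_cohort_fixed_cases(
    config: SimulationConfig,
    n_cases: int,
    event_day_range: tuple[int, int] = (3, 40),
    seed: int | None = None,
) -> Cohort:
    """A synthetic cohort with the case count pinned exactly.

    Draws a cohort as usual, clears its events, then designates
    ``n_cases`` subjects (among those followed to the end) as cases with
    event days uniform over ``event_day_range``, truncating their feed
    logs accordingly.  Used to validate design-level accounting (e.g.
    control-slot counts) where the number of cases must be exact.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cohort = simulate_cohort(config, seed=int(rng.integers(2**31 - 1)))
    subjects = cohort.subjects.copy()
    full_follow = subjects.loc[~subjects["event"], "id"].tolist()
    if len(full_follow) < n_cases:
        raise ValueError(
            f"only {len(full_follow)} event-free subjects available for "
            f"{n_cases} forced cases"
        )
    chosen = rng.choice(np.array(full_follow, dtype=object), size=n_cases,
                        replace=False)
    lo, hi = event_day_range
    days = rng.integers(lo, hi + 1, size=n_cases)

    subjects["event"] = False
    subjects["event_day"] = pd.array([pd.NA] * len(subjects), dtype="Int64")
    day_of = dict(zip(chosen.tolist(), days.tolist()))
    is_case = subjects["id"].isin(day_of)
    subjects.loc[is_case, "event"] = True
    subjects.loc[is_case, "event_day"] = subjects.loc[is_case, "id"].map(day_of)
    subjects.loc[is_case, "exit_day"] = subjects.loc[is_case, "id"].map(day_of)

    exit_by_id = subjects.set_index("id")["exit_day"]
    fl = cohort.feed_log
    fl = fl.loc[fl["day"] <= fl["id"].map(exit_by_id)].reset_index(drop=True)
    return cohort_from_frames(subjects, fl)


@dataclass
class RecoverySummary:
    """Replicated-pipeline recovery of the generating log odds ratio."""

    true_log_or: float
    estimates: np.ndarray
    standard_errors: np.ndarray
    n_reps: int
    n_failed: int

    @property
    def mean(self) -> float:
        return float(self.estimates.mean())

    @property
    def sd(self) -> float:
        return float(self.estimates.std(ddof=1))

    @property
    def empirical_var(self) -> float:
        return float(self.estimates.var(ddof=1))

    @property
    def coverage(self) -> float:
        lo = self.estimates - 1.96 * self.standard_errors
        hi = self.estimates + 1.96 * self.standard_errors
        return float(((lo <= self.true_log_or) & (self.true_log_or <= hi)).mean())


def _one_rep(
    config: SimulationConfig,
    m: int,
    sim_seed: int,
    match_seed: int,
    exposure_def: ExposureDefinition,
    adjust_for: tuple[str, ...],
    cohort: Cohort | None = None,
):
    if cohort is None:
        cohort = simulate_cohort(config, seed=sim_seed)
    spec = MatchingSpec(controls_per_case=m)
    sets = sample_all(cohort, spec, seed=match_seed)
    rows = build_analysis_table(sets, cohort, [exposure_def])
    res = fit_clogit(rows, exposure_def.name, adjust_for=adjust_for)
    if not res.converged:
        raise RuntimeError(res.separation or "fit did not converge")
    return res


def recovery_experiment(
    config: SimulationConfig,
    m: int = 4,
    reps: int = 200,
    adjust_for: tuple[str, ...] = (),
) -> RecoverySummary:
    """Simulate -> match -> classify -> fit, ``reps`` times.

    Uses the any-prior exposure, whose generating coefficient is
    ``config.log_or_exposure``.  Per-rep failures (no cases, no discordant
    sets, non-convergence) are counted, not fatal.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=(reps, 2))
    exposure_def = ExposureDefinition("any_prior", "any_prior")
    est, ses, failed = [], [], 0
    for r in range(reps):
        try:
            res = _one_rep(
                config, m, int(seeds[r, 0]), int(seeds[r, 1]), exposure_def,
                adjust_for,
            )
            est.append(res.params[0])
            ses.append(res.bse[0])
        except (ValueError, RuntimeError):
            failed += 1
    return RecoverySummary(
        true_log_or=config.log_or_exposure,
        estimates=np.asarray(est),
        standard_errors=np.asarray(ses),
        n_reps=reps,
        n_failed=failed,
    )


def paired_variance_experiment(
    config: SimulationConfig,
    ms: tuple[int, ...] = (1, 4),
    reps: int = 200,
) -> dict[int, np.ndarray]:
    """Estimates for several control ratios on the *same* simulated cohorts.

    Sharing cohorts across ``m`` values pairs the estimators, so empirical
    variance ratios between control ratios are far less noisy than with
    independent runs.  Reps where any m fails are dropped for all m.
    """
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=(reps, 1 + len(ms)))
    exposure_def = ExposureDefinition("any_prior", "any_prior")
    out: dict[int, list[float]] = {m: [] for m in ms}
    for r in range(reps):
        cohort = simulate_cohort(config, seed=int(seeds[r, 0]))
        try:
            ests = {
                m: _one_rep(
                    config, m, 0, int(seeds[r, 1 + i]), exposure_def, (),
                    cohort=cohort,
                ).params[0]
                for i, m in enumerate(ms)
            }
        except (ValueError, RuntimeError):
            continue
        for m, b in ests.items():
            out[m].append(b)
    return {m: np.asarray(v) for m, v in out.items()}


def efficiency_table(m_values: list[int]) -> pd.DataFrame:
    """Pitman relative efficiency of 1:m matching versus the full cohort.

    The asymptotic efficiency of a 1:m matched analysis relative to using
    the whole risk set is m/(m+1); ``pct_gain_over_prev`` is the percent
    efficiency gain over the previous m in the list.
    """
    if any(m < 1 for m in m_values):
        raise ValueError("all m must be >= 1")
    eff = np.array([m / (m + 1) for m in m_values], dtype=float)
    gain = np.full(len(eff), np.nan)
    gain[1:] = (eff[1:] / eff[:-1] - 1.0) * 100.0
    return pd.DataFrame(
        {"m": m_values, "relative_efficiency": eff, "pct_gain_over_prev": gain}
    )
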