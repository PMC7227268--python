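"""Incidence-density risk sets and Mahalanobis-matched control selection.

Each time a case occurs, the risk set is every subject still under
follow-up and event-free at that day; ``m`` controls are drawn from it
without replacement by exact matching on categorical factors (sex by
default) and smallest Mahalanobis distance on continuous factors
(gestational age and birth weight by default).  Subjects may be reused as
controls across sets, and future cases serve as controls in earlier sets —
both are required for unbiased rate-ratio estimation under
incidence-density sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .cohort import Cohort

__all__ = [
    "MatchingSpec",
    "RiskSet",
    "MatchedSet",
    "estimate_covariance",
    "mahalanobis_distance",
    "build_risk_set",
    "select_controls",
    "sample_all",
    "matched_sets_frame",
]

# relative tolerance declaring two squared distances tied at the selection
# boundary; ties then break uniformly at random
_TIE_RTOL = 1e-9
_TIE_ATOL = 1e-12


@dataclass(frozen=True)
class MatchingSpec:
    """Configuration of the matching algorithm.

    ``covariance`` is the positive-definite matrix used in the Mahalanobis
    distance over ``distance_factors``; when ``None`` it is estimated once
    from the full cohort so the metric is constant across risk sets.
    """

    exact_factors: tuple[str, ...] = ("sex",)
    distance_factors: tuple[str, ...] = ("gestational_age", "birth_weight")
    controls_per_case: int = 4
    covariance: np.ndarray | None = None
    ridge_epsilon: float = 1e-8

    def __post_init__(self):
        if self.controls_per_case < 1:
            raise ValueError("controls_per_case must be >= 1")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
                raise ValueError("covariance must be square")
            if not np.allclose(cov, cov.T):
                raise ValueError("covariance must be symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError("covariance must be positive definite")
            object.__setattr__(self, "covariance", cov)


@dataclass(frozen=True)
class RiskSet:
    """The eligible-control population at one case's event time."""

    case_id: str
    event_day: int
    eligible_ids: frozenset[str]


@dataclass(frozen=True)
class MatchedSet:
    """A case plus its selected controls (order: increasing distance,
    boundary ties in random order)."""

    case_id: str
    event_day: int
    control_ids: tuple[str, ...]
    distances: tuple[float, ...]
    short: bool = False


def estimate_covariance(
    cohort: Cohort,
    factors: tuple[str, ...] = ("gestational_age", "birth_weight"),
    ridge_epsilon: float = 1e-8,
) -> np.ndarray:
    """Sample covariance of ``factors`` over the entire cohort.

    Ridge-regularises by ``ridge_epsilon * I`` (with a warning) if the
    sample covariance is numerically singular; raises on fewer than k+1
    subjects or a zero-variance factor.
    """
    X = cohort.subjects[list(factors)].to_numpy(dtype=float)
    n, k = X.shape
    if n < k + 1:
        raise ValueError(
            f"need at least {k + 1} subjects to estimate a {k}x{k} covariance, got {n}"
        )
    variances = X.var(axis=0, ddof=1)
    for name, v in zip(factors, variances):
        if v == 0:
            raise ValueError(f"zero-variance matching factor: {name}")
    cov = np.cov(X, rowvar=False, ddof=1).reshape(k, k)
    try:
        linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError:
        warnings.warn(
            f"singular covariance for factors {factors}; "
            f"adding ridge {ridge_epsilon} * I"
        )
        cov = cov + ridge_epsilon * np.eye(k)
    return cov


def mahalanobis_distance(x, y, cov) -> float:
    """sqrt((x-y)' cov^{-1} (x-y)) for positive-definite ``cov``."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (d.size, d.size):
        raise ValueError("dimension mismatch between vectors and covariance")
    try:
        c, low = linalg.cho_factor(cov)
    except linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is singular") from exc
    return float(np.sqrt(d @ linalg.cho_solve((c, low), d)))


class _CohortArrays:
    """Column arrays for fast eligibility masking and distance computation."""

    def __init__(self, cohort: Cohort, spec: MatchingSpec):
        s = cohort.subjects
        self.ids = s["id"].to_numpy(dtype=object)
        self.exit_day = s["exit_day"].to_numpy(dtype=np.int64)
        self.event = s["event"].to_numpy(dtype=bool)
        eday = s["event_day"].to_numpy(dtype=object)
        self.event_day = np.array(
            [int(d) if d is not pd.NA and d == d else -1 for d in eday],
            dtype=np.int64,
        )
        self.index_of = {sid: i for i, sid in enumerate(self.ids)}
        # exact factors as tuples per subject for stratum equality
        cols = [s[f].to_numpy(dtype=object) for f in spec.exact_factors]
        self.strata = list(zip(*cols)) if cols else [()] * len(s)
        self.X = s[list(spec.distance_factors)].to_numpy(dtype=float)
        self._cohort = cohort
        self._spec = spec
        self._cho = None  # covariance factor built lazily: eligibility
        # masking alone must work on cohorts too degenerate for a covariance

    def sq_distances(self, case_idx: int, cand_idx: np.ndarray) -> np.ndarray:
        if self._cho is None:
            cov = self._spec.covariance
            if cov is None:
                cov = estimate_covariance(
                    self._cohort, self._spec.distance_factors,
                    self._spec.ridge_epsilon,
                )
            self.cov = np.asarray(cov, dtype=float)
            self._cho = linalg.cho_factor(self.cov)
        D = self.X[cand_idx] - self.X[case_idx]
        return np.einsum(
            "ij,ij->i", D, linalg.cho_solve(self._cho, D.T).T
        ).clip(min=0.0)

    def eligible_mask(
        self, case_idx: int, event_day: int, prior_case_idx: np.ndarray
    ) -> np.ndarray:
        # still under follow-up at event_day; event-free strictly before it
        # (a same-day event disqualifies: cases on the same day are mutually
        # exclusive as case/control); never a prior case; never the case.
        mask = self.exit_day >= event_day
        mask &= ~(self.event & (self.event_day <= event_day))
        mask[prior_case_idx] = False
        mask[case_idx] = False
        return mask


def build_risk_set(
    cohort: Cohort,
    case_id: str,
    event_day: int,
    prior_case_ids: set[str] = frozenset(),
    spec: MatchingSpec | None = None,
) -> RiskSet:
    """All subjects at risk when this case occurs.

    Eligible subjects are under follow-up at ``event_day`` (exit on the
    event day counts as at risk), have no event on or before that day, are
    not prior cases, and are not the case itself.  Future cases remain
    eligible.  An empty risk set is returned with a warning.
    """
    spec = spec or MatchingSpec()
    arrays = _CohortArrays(cohort, spec)
    idx = arrays.index_of[case_id]
    prior_idx = np.array(
        [arrays.index_of[i] for i in prior_case_ids if i in arrays.index_of],
        dtype=np.int64,
    )
    mask = arrays.eligible_mask(idx, event_day, prior_idx)
    eligible = frozenset(arrays.ids[mask].tolist())
    if not eligible:
        warnings.warn(
            f"empty risk set for case {case_id!r} at day {event_day}"
        )
    return RiskSet(case_id=case_id, event_day=event_day, eligible_ids=eligible)


def _select_from_candidates(
    arrays: _CohortArrays,
    case_idx: int,
    cand_idx: np.ndarray,
    m: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Pick the m smallest-distance candidates; boundary ties break at random.

    Returns (selected candidate indices ordered by distance, distances, short).
    """
    d2 = arrays.sq_distances(case_idx, cand_idx)
    if len(cand_idx) <= m:
        order = np.argsort(d2, kind="stable")
        return cand_idx[order], np.sqrt(d2[order]), len(cand_idx) < m
    order = np.argsort(d2, kind="stable")
    boundary = d2[order[m - 1]]
    tied = np.isclose(d2, boundary, rtol=_TIE_RTOL, atol=_TIE_ATOL)
    inside = (d2 < boundary) & ~tied
    n_inside = int(inside.sum())
    tied_pos = np.flatnonzero(tied)
    drawn = rng.choice(tied_pos, size=m - n_inside, replace=False)
    sel = np.concatenate([np.flatnonzero(inside), drawn])
    # order by distance; the drawn tied members land after the interior ones
    sel = sel[np.argsort(d2[sel], kind="stable")]
    return cand_idx[sel], np.sqrt(d2[sel]), False


def select_controls(
    risk_set: RiskSet,
    cohort: Cohort,
    spec: MatchingSpec,
    rng: np.random.Generator,
) -> MatchedSet:
    """Select matched controls for one risk set.

    Controls must equal the case on every exact factor; among those, the
    ``m`` smallest Mahalanobis distances win, with ties at the selection
    boundary broken uniformly at random.  Fewer than ``m`` eligible matches
    yields a short (flagged) set; zero yields an empty flagged set.
    """
    arrays = _CohortArrays(cohort, spec)
    case_idx = arrays.index_of[risk_set.case_id]
    cand_idx = np.array(
        sorted(arrays.index_of[i] for i in risk_set.eligible_ids), dtype=np.int64
    )
    stratum = arrays.strata[case_idx]
    cand_idx = cand_idx[[arrays.strata[i] == stratum for i in cand_idx]]
    if len(cand_idx) == 0:
        warnings.warn(
            f"no eligible same-stratum controls for case {risk_set.case_id!r}"
        )
        return MatchedSet(
            case_id=risk_set.case_id,
            event_day=risk_set.event_day,
            control_ids=(),
            distances=(),
            short=True,
        )
    sel, dist, short = _select_from_candidates(
        arrays, case_idx, cand_idx, spec.controls_per_case, rng
    )
    return MatchedSet(
        case_id=risk_set.case_id,
        event_day=risk_set.event_day,
        control_ids=tuple(arrays.ids[sel].tolist()),
        distances=tuple(float(d) for d in dist),
        short=short,
    )


def sample_all(
    cohort: Cohort, spec: MatchingSpec | None = None, seed: int = 0
) -> list[MatchedSet]:
    """Process every case in event-day order, accumulating prior cases.

    Cases sharing an event day are processed in seeded random order (each
    is excluded from the other's risk set either way).  Output is
    deterministic given cohort, spec and seed.
    """
    spec = spec or MatchingSpec()
    if not cohort.subjects["event"].any():
        raise ValueError("cohort contains no cases")
    rng = np.random.default_rng(seed)
    arrays = _CohortArrays(cohort, spec)
    case_mask = arrays.event
    case_idx = np.flatnonzero(case_mask)
    # stable order: event day, then seeded shuffle within day
    jitter = rng.random(len(case_idx))
    order = np.lexsort((jitter, arrays.event_day[case_idx]))
    case_idx = case_idx[order]

    out: list[MatchedSet] = []
    prior: list[int] = []
    for ci in case_idx:
        event_day = int(arrays.event_day[ci])
        mask = arrays.eligible_mask(ci, event_day, np.array(prior, dtype=np.int64))
        stratum = arrays.strata[ci]
        cand = np.flatnonzero(mask)
        cand = cand[[arrays.strata[i] == stratum for i in cand]]
        case_id = str(arrays.ids[ci])
        if len(cand) == 0:
            warnings.warn(f"no eligible same-stratum controls for case {case_id!r}")
            out.append(
                MatchedSet(case_id, event_day, (), (), short=True)
            )
        else:
            sel, dist, short = _select_from_candidates(
                arrays, ci, cand, spec.controls_per_case, rng
            )
            out.append(
                MatchedSet(
                    case_id,
                    event_day,
                    tuple(arrays.ids[sel].tolist()),
                    tuple(float(d) for d in dist),
                    short,
                )
            )
        prior.append(int(ci))
    return out


def matched_sets_frame(matched_sets: list[MatchedSet]) -> pd.DataFrame:
    """Long-format export: one row per member, cases first within each set."""
    rows = []
    for set_id, ms in enumerate(matched_sets):
        rows.append(
            {
                "set_id": set_id,
                "role": "case",
                "subject_id": ms.case_id,
                "event_day": ms.event_day,
                "distance": np.nan,
                "short_flag": int(ms.short),
            }
        )
        for cid, d in zip(ms.control_ids, ms.distances):
            rows.append(
                {
                    "set_id": set_id,
                    "role": "control",
                    "subject_id": cid,
                    "event_day": ms.event_day,
                    "distance": d,
                    "short_flag": int(ms.short),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["set_id", "role", "subject_id", "event_day", "distance", "short_flag"],
    )
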