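"""Cohort data model: subjects, daily feed logs, readers/writers and validation.

The cohort is a closed group of preterm infants followed from delivery
(day 0) until exit, with a long-format daily feed log recording the type of
milk feed each infant received.  All times are integer day indices since
delivery.  A subject exits at the first of: outcome event, death, or end of
the daily log; only a single ``exit_day`` is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "CohortValidationError",
    "ExclusionRules",
    "read_cohort",
    "write_cohort",
    "cohort_from_frames",
    "exclude_invalid",
    "FEED_TYPES",
    "SEXES",
    "TRIAL_ARMS",
]

FEED_TYPES = ("breast", "formula", "fortifier", "unknown")
SEXES = ("male", "female")
TRIAL_ARMS = ("early", "late")

#: on-disk column names -> internal column names
_SUBJECT_COLS = {
    "id": "id",
    "sex": "sex",
    "gestational_age_weeks": "gestational_age",
    "birth_weight_g": "birth_weight",
    "trial_arm": "trial_arm",
    "exit_day": "exit_day",
    "event": "event",
    "event_day": "event_day",
}
_FEEDLOG_COLS = ("id", "day", "feed_type")


class CohortValidationError(ValueError):
    """Raised when a subjects table or feed log violates a model invariant."""


@dataclass(frozen=True)
class Cohort:
    """A validated cohort: one row per subject plus a long-format feed log.

    Attributes
    ----------
    subjects : pandas.DataFrame
        Columns ``id, sex, gestational_age, birth_weight, trial_arm,
        exit_day, event, event_day``.  ``trial_arm`` may be missing (NA) for
        non-trial cohorts; ``event_day`` is present iff ``event`` is True.
    feed_log : pandas.DataFrame
        Columns ``id, day, feed_type``; at most one record per subject-day,
        and never beyond the subject's exit day.
    """

    subjects: pd.DataFrame
    feed_log: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def case_ids(self) -> list[str]:
        """Ids of subjects whose outcome event occurred, in id order."""
        s = self.subjects
        return sorted(s.loc[s["event"], "id"].tolist())

    def subject_row(self, subject_id: str) -> pd.Series:
        s = self.subjects
        rows = s.loc[s["id"] == subject_id]
        if rows.empty:
            raise KeyError(f"unknown subject id {subject_id!r}")
        return rows.iloc[0]

    def feed_log_for(self, subject_id: str) -> pd.DataFrame:
        fl = self.feed_log
        return fl.loc[fl["id"] == subject_id, ["day", "feed_type"]].sort_values("day")


def _validate_subjects(subjects: pd.DataFrame) -> None:
    dup = subjects["id"][subjects["id"].duplicated()]
    if not dup.empty:
        raise CohortValidationError(
            f"duplicate subject id(s): {sorted(dup.unique().tolist())}"
        )
    bad_sex = subjects.loc[~subjects["sex"].isin(SEXES), "id"]
    if not bad_sex.empty:
        raise CohortValidationError(f"invalid sex for subject(s) {bad_sex.tolist()}")
    arm = subjects["trial_arm"]
    bad_arm = subjects.loc[arm.notna() & ~arm.isin(TRIAL_ARMS), "id"]
    if not bad_arm.empty:
        raise CohortValidationError(
            f"invalid trial_arm for subject(s) {bad_arm.tolist()}"
        )
    for col in ("gestational_age", "birth_weight"):
        bad = subjects.loc[~(subjects[col] > 0), "id"]
        if not bad.empty:
            raise CohortValidationError(
                f"non-positive {col} for subject(s) {bad.tolist()}"
            )
    if (subjects["exit_day"] < 0).any():
        bad = subjects.loc[subjects["exit_day"] < 0, "id"]
        raise CohortValidationError(f"negative exit_day for subject(s) {bad.tolist()}")
    ev = subjects["event"]
    missing_day = subjects.loc[ev & subjects["event_day"].isna(), "id"]
    if not missing_day.empty:
        raise CohortValidationError(
            f"event recorded without event_day for subject(s) {missing_day.tolist()}"
        )
    spurious_day = subjects.loc[~ev & subjects["event_day"].notna(), "id"]
    if not spurious_day.empty:
        raise CohortValidationError(
            f"event_day present without event for subject(s) {spurious_day.tolist()}"
        )
    with_ev = subjects.loc[ev]
    late = with_ev.loc[with_ev["event_day"] > with_ev["exit_day"], "id"]
    if not late.empty:
        raise CohortValidationError(
            f"event_day after exit_day for subject(s) {late.tolist()}"
        )


def _validate_feed_log(feed_log: pd.DataFrame, subjects: pd.DataFrame) -> None:
    unknown = feed_log.loc[~feed_log["id"].isin(subjects["id"]), "id"]
    if not unknown.empty:
        raise CohortValidationError(
            f"feed log references unknown subject(s): {sorted(unknown.unique().tolist())}"
        )
    bad_type = feed_log.loc[~feed_log["feed_type"].isin(FEED_TYPES)]
    if not bad_type.empty:
        raise CohortValidationError(
            f"invalid feed_type value(s): {sorted(bad_type['feed_type'].unique().tolist())}"
        )
    if (feed_log["day"] < 0).any():
        raise CohortValidationError("negative day in feed log")
    dup = feed_log.duplicated(subset=["id", "day"])
    if dup.any():
        pairs = feed_log.loc[dup, ["id", "day"]].itertuples(index=False)
        raise CohortValidationError(
            f"duplicate feed log record(s) for (id, day): {list(pairs)}"
        )
    exit_by_id = subjects.set_index("id")["exit_day"]
    exceeds = feed_log["day"] > feed_log["id"].map(exit_by_id)
    if exceeds.any():
        bad = feed_log.loc[exceeds, ["id", "day"]].itertuples(index=False)
        raise CohortValidationError(
            f"feed log record(s) beyond subject exit_day: {list(bad)}"
        )


def cohort_from_frames(subjects: pd.DataFrame, feed_log: pd.DataFrame) -> Cohort:
    """Build and validate a :class:`Cohort` from in-memory frames.

    Frames use the internal column names; dtypes are normalised (ids to
    string, days to int, ``event`` to bool, ``event_day`` to nullable int).
    """
    subjects = subjects.copy()
    subjects["id"] = subjects["id"].astype(str)
    subjects["sex"] = subjects["sex"].astype(str)
    subjects["gestational_age"] = subjects["gestational_age"].astype(float)
    subjects["birth_weight"] = subjects["birth_weight"].astype(float)
    arm = subjects["trial_arm"]
    subjects["trial_arm"] = arm.where(arm.notna(), pd.NA).astype("string")
    subjects["exit_day"] = subjects["exit_day"].astype(int)
    subjects["event"] = subjects["event"].astype(bool)
    subjects["event_day"] = subjects["event_day"].astype("Int64")
    subjects = subjects[list(_SUBJECT_COLS.values())].reset_index(drop=True)

    feed_log = feed_log.copy()
    if feed_log.empty:
        feed_log = pd.DataFrame(
            {"id": pd.Series(dtype=str), "day": pd.Series(dtype=int),
             "feed_type": pd.Series(dtype=str)}
        )
    else:
        feed_log["id"] = feed_log["id"].astype(str)
        feed_log["day"] = feed_log["day"].astype(int)
        feed_log["feed_type"] = feed_log["feed_type"].astype(str)
    feed_log = feed_log[list(_FEEDLOG_COLS)].reset_index(drop=True)

    _validate_subjects(subjects)
    _validate_feed_log(feed_log, subjects)
    return Cohort(subjects=subjects, feed_log=feed_log)


def read_cohort(subjects_path, feedlog_path) -> Cohort:
    """Read and validate a cohort from the two standard CSV files.

    ``subjects_path`` columns: ``id, sex, gestational_age_weeks,
    birth_weight_g, trial_arm, exit_day, event, event_day`` (booleans as
    0/1; ``event_day`` empty when no event; ``trial_arm`` may be empty).
    ``feedlog_path`` columns: ``id, day, feed_type``.
    """
    subjects_raw = pd.read_csv(
        subjects_path, dtype={"id": str, "sex": str, "trial_arm": str}
    )
    missing = set(_SUBJECT_COLS) - set(subjects_raw.columns)
    if missing:
        raise CohortValidationError(
            f"subjects file missing column(s): {sorted(missing)}"
        )
    subjects = subjects_raw.rename(columns=_SUBJECT_COLS)

    feed_raw = pd.read_csv(feedlog_path, dtype={"id": str, "feed_type": str})
    missing = set(_FEEDLOG_COLS) - set(feed_raw.columns)
    if missing and not feed_raw.empty:
        raise CohortValidationError(f"feed log missing column(s): {sorted(missing)}")
    if feed_raw.empty:
        feed_raw = pd.DataFrame(columns=list(_FEEDLOG_COLS))
    return cohort_from_frames(subjects, feed_raw)


def write_cohort(cohort: Cohort, subjects_path, feedlog_path) -> None:
    """Write a cohort to the standard CSV pair (inverse of :func:`read_cohort`)."""
    out = cohort.subjects.rename(
        columns={v: k for k, v in _SUBJECT_COLS.items()}
    ).copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(subjects_path, index=False)
    cohort.feed_log.to_csv(feedlog_path, index=False)


@dataclass(frozen=True)
class ExclusionRules:
    """Subject-level exclusion rules applied before sampling.

    ``require_feed_log`` drops subjects with no daily feed-log record at
    all; ``withdrawn_ids`` drops subjects whose consent was withdrawn;
    ``exclude_ids`` drops subjects flagged invalid for any other reason
    (e.g. randomised in error, outcome severity unknown).
    """

    require_feed_log: bool = False
    withdrawn_ids: tuple[str, ...] = field(default_factory=tuple)
    exclude_ids: tuple[str, ...] = field(default_factory=tuple)


def exclude_invalid(
    cohort: Cohort, rules: ExclusionRules | None
) -> tuple[Cohort, pd.DataFrame]:
    """Apply exclusion rules; return the retained cohort and a report.

    The report has one row per (subject, reason); a subject failing several
    rules is listed once per reason but excluded only once.  ``rules=None``
    (or all-default rules) leaves the cohort unchanged.
    """
    records: list[tuple[str, str]] = []
    if rules is not None:
        ids = cohort.subjects["id"]
        if rules.require_feed_log:
            logged = set(cohort.feed_log["id"])
            for sid in ids[~ids.isin(logged)]:
                records.append((sid, "no_feed_log_data"))
        for sid in ids[ids.isin(set(rules.withdrawn_ids))]:
            records.append((sid, "consent_withdrawn"))
        for sid in ids[ids.isin(set(rules.exclude_ids))]:
            records.append((sid, "flagged_invalid"))

    report = pd.DataFrame(records, columns=["id", "reason"])
    excluded = set(report["id"])
    keep = ~cohort.subjects["id"].isin(excluded)
    subjects = cohort.subjects.loc[keep].reset_index(drop=True)
    feed_log = cohort.feed_log.loc[
        cohort.feed_log["id"].isin(set(subjects["id"]))
    ].reset_index(drop=True)
    if subjects.empty:
        warnings.warn("all subjects excluded; resulting cohort is empty")
    return Cohort(subjects=subjects, feed_log=feed_log), report
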