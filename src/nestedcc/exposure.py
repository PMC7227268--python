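"""Gap filling of daily feed logs and time-truncated exposure classification.

A diagnosis changes subsequent feeding, so exposure status for every member
of a matched set is evaluated strictly before the set's index day (the
case's event day).  Classification therefore works on the log truncated to
days < index_day, gap-filled afterwards so no record on or after the index
day can leak into a filled value.

Four exposure window kinds are supported:

``first_k_days``
    any exposing feed type on days [0, min(k, index_day))
``any_prior``
    any exposing feed type on days [0, index_day)
``change_within_k``
    a change between two *known* feed types on consecutive days (d-1, d)
    with index_day - k <= d < index_day; unknown days break the chain
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import FEED_TYPES, Cohort
from .matching import MatchedSet

__all__ = [
    "ExposureDefinition",
    "default_definitions",
    "fill_feed_gaps",
    "classify_exposure",
    "build_analysis_table",
]

_KINDS = ("first_k_days", "any_prior", "change_within_k")
DEFAULT_EXPOSED_TYPES = frozenset({"formula", "fortifier"})


@dataclass(frozen=True)
class ExposureDefinition:
    """One predefined exposure window.

    ``exposed_types`` is the set of feed types counting as exposure
    (non-breast-milk feeds by default); it is ignored by the
    ``change_within_k`` kind, which looks for any change between known
    types.
    """

    name: str
    kind: str
    k: int | None = None
    exposed_types: frozenset[str] = DEFAULT_EXPOSED_TYPES

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unsupported exposure kind: {self.kind!r}")
        needs_k = self.kind in ("first_k_days", "change_within_k")
        if needs_k and (self.k is None or self.k < 1):
            raise ValueError(f"kind {self.kind!r} requires positive k")
        if not needs_k and self.k is not None:
            raise ValueError(f"kind {self.kind!r} takes no k")
        bad = set(self.exposed_types) - set(FEED_TYPES)
        if bad:
            raise ValueError(f"unknown feed types in exposed_types: {sorted(bad)}")
        object.__setattr__(self, "exposed_types", frozenset(self.exposed_types))


def default_definitions() -> list[ExposureDefinition]:
    """The four predefined exposures of the motivating study."""
    return [
        ExposureDefinition("first_14", "first_k_days", k=14),
        ExposureDefinition("first_28", "first_k_days", k=28),
        ExposureDefinition("any_prior", "any_prior"),
        ExposureDefinition("change_within_7", "change_within_k", k=7),
    ]


def _fill_day_types(days: np.ndarray, types: np.ndarray, max_gap: int) -> np.ndarray:
    """Array core of gap filling: per-day feed type over days 0..max(days)."""
    last = int(days[-1])
    filled = np.full(last + 1, "unknown", dtype=object)
    filled[days] = types
    for left in range(len(days) - 1):
        gap = days[left + 1] - days[left] - 1
        if 0 < gap <= max_gap and types[left] == types[left + 1]:
            filled[days[left] + 1 : days[left + 1]] = types[left]
    return filled


def fill_feed_gaps(log: pd.DataFrame, max_gap: int = 2) -> pd.DataFrame:
    """Fill small interior gaps in one subject's daily feed log.

    An interior run of <= ``max_gap`` missing days flanked on both sides by
    the *same* recorded feed type is filled with that type.  Runs flanked
    by different types, runs longer than ``max_gap``, and leading missing
    days become ``"unknown"``.  The output covers days 0..last observed
    day (empty input stays empty); observed records are never altered.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if log.empty:
        return pd.DataFrame({"day": pd.Series(dtype=int),
                             "feed_type": pd.Series(dtype=str)})
    log = log.sort_values("day")
    days = log["day"].to_numpy(dtype=int)
    types = log["feed_type"].to_numpy(dtype=object)
    filled = _fill_day_types(days, types, max_gap)
    return pd.DataFrame({"day": np.arange(len(filled)), "feed_type": filled})


def _classify_day_types(
    day_types: np.ndarray, definition: ExposureDefinition, index_day: int
) -> bool:
    """Array core of classification; ``day_types`` covers days < index_day
    (shorter arrays mean trailing unknown days)."""
    kind = definition.kind
    if kind in ("first_k_days", "any_prior"):
        horizon = index_day if kind == "any_prior" else min(definition.k, index_day)
        types = day_types[:horizon]
        return bool(np.isin(types, list(definition.exposed_types)).any())
    if kind == "change_within_k":
        types = day_types[:index_day]
        if len(types) < 2:
            return False
        known = types != "unknown"
        change = known[1:] & known[:-1] & (types[1:] != types[:-1])
        d = np.arange(1, len(types))  # change attributed to the later day
        return bool((change & (d >= index_day - definition.k)).any())
    raise ValueError(f"unsupported exposure kind: {kind!r}")  # pragma: no cover


def classify_exposure(
    filled: pd.DataFrame, definition: ExposureDefinition, index_day: int
) -> bool:
    """Exposure status at ``index_day`` from a gap-filled log.

    Only days strictly before ``index_day`` are inspected; ``unknown`` days
    never count as exposure and never participate in a change.
    """
    if index_day < 0:
        raise ValueError("index_day must be >= 0")
    day_types = np.full(index_day, "unknown", dtype=object)
    if not filled.empty:
        days = filled["day"].to_numpy(dtype=int)
        keep = days < index_day
        day_types[days[keep]] = filled["feed_type"].to_numpy(dtype=object)[keep]
    return _classify_day_types(day_types, definition, index_day)


def build_analysis_table(
    matched_sets: list[MatchedSet],
    cohort: Cohort,
    definitions: list[ExposureDefinition] | None = None,
    max_gap: int = 2,
) -> pd.DataFrame:
    """One row per matched-set member with exposure flags at the index day.

    All members of a set share ``index_day`` = the case's event day, so a
    control's exposure is evaluated at the case's event time; a subject in
    two sets gets two rows whose flags may differ.  Gap filling runs on the
    log truncated strictly before the index day.
    """
    definitions = definitions if definitions is not None else default_definitions()
    arm_of = dict(zip(cohort.subjects["id"], cohort.subjects["trial_arm"]))
    # per-subject (days, types) arrays, sorted by day
    fl = cohort.feed_log.sort_values(["id", "day"], kind="stable")
    all_ids = fl["id"].to_numpy(dtype=object)
    all_days = fl["day"].to_numpy(dtype=int)
    all_types = fl["feed_type"].to_numpy(dtype=object)
    bounds = np.flatnonzero(np.r_[True, all_ids[1:] != all_ids[:-1]])
    logs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s, e in zip(bounds, np.r_[bounds[1:], len(all_ids)]):
        logs[all_ids[s]] = (all_days[s:e], all_types[s:e])

    fill_cache: dict[tuple[str, int], np.ndarray] = {}

    def day_types_for(sid: str, index_day: int) -> np.ndarray:
        key = (sid, index_day)
        if key not in fill_cache:
            days, types = logs.get(sid, (np.empty(0, int), np.empty(0, object)))
            keep = days < index_day
            days, types = days[keep], types[keep]
            if len(days):
                fill_cache[key] = _fill_day_types(days, types, max_gap)
            else:
                fill_cache[key] = np.empty(0, dtype=object)
        return fill_cache[key]

    rows = []
    for set_id, ms in enumerate(matched_sets):
        members = [(ms.case_id, True)] + [(cid, False) for cid in ms.control_ids]
        for sid, is_case in members:
            if sid not in arm_of:
                raise KeyError(f"matched-set member {sid!r} not in cohort")
            day_types = day_types_for(sid, ms.event_day)
            row = {
                "set_id": set_id,
                "subject_id": sid,
                "is_case": is_case,
                "index_day": ms.event_day,
                "trial_arm": arm_of[sid],
            }
            for d in definitions:
                row[d.name] = _classify_day_types(day_types, d, ms.event_day)
            rows.append(row)
    cols = ["set_id", "subject_id", "is_case", "index_day", "trial_arm"] + [
        d.name for d in definitions
    ]
    return pd.DataFrame(rows, columns=cols)
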