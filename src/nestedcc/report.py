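"""Descriptive three-column baseline table: cases / matched controls / non-cases.

The matched-control column counts control *slots* — a subject sampled into
three sets contributes three times — mirroring how matched-control
denominators are conventionally reported; unique-control and reuse counts
are carried as footnotes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .matching import MatchedSet

__all__ = ["BaselineTable", "baseline_table"]


@dataclass
class BaselineTable:
    table: pd.DataFrame
    n_cases: int
    n_control_slots: int
    n_non_cases: int
    n_unique_controls: int
    n_sampled_more_than_once: int
    n_future_cases_as_controls: int

    def to_text(self) -> str:
        lines = [self.table.to_string()]
        lines.append(
            f"Controls: {self.n_control_slots} slots, "
            f"{self.n_unique_controls} unique, "
            f"{self.n_sampled_more_than_once} sampled more than once, "
            f"{self.n_future_cases_as_controls} later became cases."
        )
        return "\n".join(lines)


def _pct(k: int, n: int) -> str:
    return f"{k} ({100.0 * k / n:.1f})" if n else "0"


def _median_iqr(x: pd.Series) -> str:
    q1, med, q3 = np.percentile(x.to_numpy(dtype=float), [25, 50, 75])
    return f"{med:.0f} ({q1:.0f} to {q3:.0f})"


def baseline_table(cohort: Cohort, matched_sets: list[MatchedSet]) -> BaselineTable:
    """Summarise baseline characteristics by analysis role.

    Columns: cases, matched control slots (duplicates counted each time
    sampled), and all event-free subjects (non-cases).  Categorical rows
    are n (%); continuous rows are median (IQR).
    """
    if not matched_sets:
        raise ValueError("matched_sets is empty")
    subj = cohort.subjects.set_index("id")
    case_ids = [ms.case_id for ms in matched_sets]
    control_slots = [cid for ms in matched_sets for cid in ms.control_ids]
    non_case_ids = cohort.subjects.loc[~cohort.subjects["event"], "id"].tolist()

    counts = Counter(control_slots)
    future_cases = set(case_ids)
    n_future = sum(1 for cid in set(control_slots) if cid in future_cases)

    groups = {
        "cases": subj.loc[case_ids].reset_index(),
        "matched_controls": subj.loc[control_slots].reset_index(),
        "non_cases": subj.loc[non_case_ids].reset_index(),
    }
    rows: dict[str, dict[str, str]] = {}

    def add_row(label, fn):
        rows[label] = {col: fn(df) for col, df in groups.items()}

    add_row("n", lambda df: str(len(df)))
    add_row("male sex, n (%)", lambda df: _pct(int((df["sex"] == "male").sum()), len(df)))
    add_row("female sex, n (%)", lambda df: _pct(int((df["sex"] == "female").sum()), len(df)))
    any_arm = cohort.subjects["trial_arm"].notna().any()
    if any_arm:
        add_row(
            "allocated to early arm, n (%)",
            lambda df: _pct(int((df["trial_arm"] == "early").sum()), len(df)),
        )
    add_row(
        "gestational age (weeks), median (IQR)",
        lambda df: _median_iqr(df["gestational_age"]),
    )
    add_row(
        "birth weight (g), median (IQR)",
        lambda df: _median_iqr(df["birth_weight"]),
    )
    table = pd.DataFrame(rows).T[list(groups)]
    return BaselineTable(
        table=table,
        n_cases=len(case_ids),
        n_control_slots=len(control_slots),
        n_non_cases=len(non_case_ids),
        n_unique_controls=len(counts),
        n_sampled_more_than_once=sum(1 for c in counts.values() if c > 1),
        n_future_cases_as_controls=n_future,
    )
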