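import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nestedcc.cohort import cohort_from_frames

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


def make_cohort(subjects, feed_records=()):
    """Build a validated cohort from compact tuples.

    ``subjects``: (id, sex, ga, bw, arm, exit_day, event_day-or-None);
    ``feed_records``: (id, day, feed_type).
    """
    rows = []
    for sid, sex, ga, bw, arm, exit_day, event_day in subjects:
        rows.append(
            {
                "id": sid,
                "sex": sex,
                "gestational_age": ga,
                "birth_weight": bw,
                "trial_arm": arm,
                "exit_day": exit_day,
                "event": event_day is not None,
                "event_day": event_day if event_day is not None else pd.NA,
            }
        )
    subjects_df = pd.DataFrame(rows)
    feed_df = pd.DataFrame(feed_records, columns=["id", "day", "feed_type"])
    return cohort_from_frames(subjects_df, feed_df)


def random_small_cohort(rng, n=20, n_cases=3, followup=30):
    """A small random cohort for brute-force matching oracles."""
    ids = [f"R{i:03d}" for i in range(n)]
    sex = rng.choice(["male", "female"], size=n)
    ga = rng.normal(30, 2.5, size=n).clip(24, 36)
    bw = (-1400 + 78 * ga + rng.normal(0, 200, size=n)).clip(400)
    case_ids = rng.choice(n, size=n_cases, replace=False)
    event_day = {int(i): int(d) for i, d in
                 zip(case_ids, rng.integers(2, followup, size=n_cases))}
    subjects = []
    for i in range(n):
        ed = event_day.get(i)
        exit_day = ed if ed is not None else int(rng.integers(5, followup + 1))
        subjects.append((ids[i], sex[i], float(ga[i]), float(bw[i]),
                         "early" if rng.random() < 0.5 else "late",
                         exit_day, ed))
    return make_cohort(subjects)


@pytest.fixture
def tiny_cohort():
    """Five subjects, one case at day 5, simple feed logs."""
    subjects = [
        ("A01", "male", 29.0, 800.0, "early", 20, None),
        ("A02", "male", 30.0, 900.0, "late", 20, 5),
        ("A03", "male", 28.0, 750.0, "early", 20, None),
        ("A04", "female", 31.0, 1000.0, "late", 20, None),
        ("A05", "male", 29.5, 820.0, "early", 20, None),
    ]
    feed = []
    for sid in ("A01", "A02", "A03", "A04", "A05"):
        for day in range(0, 10):
            feed.append((sid, day, "breast"))
    return make_cohort(subjects, feed)
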