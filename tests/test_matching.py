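import numpy as np
import pytest

from nestedcc.matching import (
    MatchingSpec,
    build_risk_set,
    estimate_covariance,
    mahalanobis_distance,
    sample_all,
    select_controls,
)

from conftest import make_cohort, random_small_cohort


class TestCovariance:
    def test_matches_hand_formula_on_five_subjects(self):
        ga = [28.0, 29.0, 30.0, 31.0, 33.0]
        bw = [700.0, 820.0, 900.0, 1050.0, 1300.0]
        cohort = make_cohort(
            [(f"S{i}", "male", g, b, None, 10, None)
             for i, (g, b) in enumerate(zip(ga, bw))]
        )
        # textbook formula: sum of cross-deviations / (n - 1)
        gbar, bbar = sum(ga) / 5, sum(bw) / 5
        sgg = sum((g - gbar) ** 2 for g in ga) / 4
        sbb = sum((b - bbar) ** 2 for b in bw) / 4
        sgb = sum((g - gbar) * (b - bbar) for g, b in zip(ga, bw)) / 4
        cov = estimate_covariance(cohort)
        assert cov == pytest.approx(np.array([[sgg, sgb], [sgb, sbb]]))

    def test_standardised_independent_factors_give_identity(self):
        rng = np.random.default_rng(5)
        n = 10000
        z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
        cohort = make_cohort(
            [(f"S{i}", "male", 30 + z1[i], 900 + z2[i], None, 5, None)
             for i in range(n)]
        )
        cov = estimate_covariance(cohort)
        assert np.allclose(cov, np.eye(2), atol=0.05)

    def test_zero_variance_factor_named(self):
        cohort = make_cohort(
            [(f"S{i}", "male", 30.0, 800.0 + i, None, 5, None) for i in range(5)]
        )
        with pytest.raises(ValueError, match="gestational_age"):
            estimate_covariance(cohort)

    def test_too_few_subjects(self):
        cohort = make_cohort([("S0", "male", 30.0, 800.0, None, 5, None),
                              ("S1", "male", 31.0, 900.0, None, 5, None)])
        with pytest.raises(ValueError, match="at least 3"):
            estimate_covariance(cohort)


class TestMahalanobis:
    def test_zero_iff_equal(self):
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert mahalanobis_distance([1, 2], [1, 2], cov) == 0.0
        assert mahalanobis_distance([1, 2], [1, 2.1], cov) > 0.0

    def test_identity_covariance_reduces_to_euclidean(self):
        assert mahalanobis_distance([3, 4], [0, 0], np.eye(2)) == pytest.approx(5.0)

    def test_against_explicit_inverse(self):
        cov = np.array([[4.0, 2.0], [2.0, 3.0]])
        d = np.array([1.0, 1.0])
        expected = np.sqrt(d @ np.linalg.inv(cov) @ d)
        assert mahalanobis_distance([2, 3], [1, 2], cov) == pytest.approx(
            expected, abs=1e-12
        )

    def test_symmetry(self):
        cov = np.array([[4.0, 2.0], [2.0, 3.0]])
        assert mahalanobis_distance([2, 3], [0, 1], cov) == pytest.approx(
            mahalanobis_distance([0, 1], [2, 3], cov)
        )

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            mahalanobis_distance([1, 2], [0, 0], np.array([[1.0, 1.0], [1.0, 1.0]]))


def _twelve_subject_cohort():
    """One case at day 3 with exactly 11 subjects remaining at risk."""
    subjects = [("CASE", "male", 29.0, 800.0, None, 3, 3)]
    for i in range(11):
        subjects.append((f"N{i:02d}", "male" if i % 2 else "female",
                         28.0 + 0.3 * i, 700.0 + 30 * i, None, 30, None))
    return make_cohort(subjects)


class TestRiskSet:
    def test_eleven_at_risk_at_day_three(self):
        cohort = _twelve_subject_cohort()
        rs = build_risk_set(cohort, "CASE", 3)
        assert len(rs.eligible_ids) == 11
        assert "CASE" not in rs.eligible_ids

    def test_exit_on_event_day_still_at_risk(self):
        cohort = make_cohort([
            ("CASE", "male", 29.0, 800.0, None, 5, 5),
            ("X1", "male", 30.0, 900.0, None, 5, None),   # exits day 5, no event
            ("X2", "male", 30.0, 900.0, None, 4, None),   # exited before
        ])
        rs = build_risk_set(cohort, "CASE", 5)
        assert rs.eligible_ids == {"X1"}

    def test_same_day_event_not_eligible(self):
        cohort = make_cohort([
            ("CASE", "male", 29.0, 800.0, None, 5, 5),
            ("SAME", "male", 30.0, 900.0, None, 5, 5),
            ("OK", "male", 30.0, 900.0, None, 9, None),
        ])
        rs = build_risk_set(cohort, "CASE", 5)
        assert rs.eligible_ids == {"OK"}

    def test_prior_case_excluded_future_case_eligible(self):
        cohort = make_cohort([
            ("EARLY", "male", 29.0, 800.0, None, 2, 2),
            ("CASE", "male", 29.0, 820.0, None, 5, 5),
            ("FUTURE", "male", 30.0, 900.0, None, 18, 18),
            ("NEVER", "male", 30.0, 900.0, None, 30, None),
        ])
        rs = build_risk_set(cohort, "CASE", 5, prior_case_ids={"EARLY"})
        # EARLY's event precedes day 5 -> out; FUTURE's event is after -> in
        assert rs.eligible_ids == {"FUTURE", "NEVER"}

    def test_exhausted_cohort_warns_empty(self):
        cohort = make_cohort([
            ("CASE", "male", 29.0, 800.0, None, 20, 20),
            ("GONE", "male", 30.0, 900.0, None, 3, None),
        ])
        with pytest.warns(UserWarning, match="empty risk set"):
            rs = build_risk_set(cohort, "CASE", 20)
        assert rs.eligible_ids == frozenset()


class TestSelectControls:
    def test_exactly_m_eligible_all_selected(self):
        subjects = [("CASE", "male", 29.0, 800.0, None, 9, 9)]
        subjects += [(f"M{i}", "male", 25.0 + i, 600.0 + 99 * i, None, 30, None)
                     for i in range(4)]
        subjects += [(f"F{i}", "female", 29.0, 800.0, None, 30, None)
                     for i in range(4)]
        cohort = make_cohort(subjects)
        spec = MatchingSpec()
        rs = build_risk_set(cohort, "CASE", 9)
        ms = select_controls(rs, cohort, spec, np.random.default_rng(0))
        assert sorted(ms.control_ids) == ["M0", "M1", "M2", "M3"]
        assert not ms.short

    def test_smallest_distances_win_vs_bruteforce(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            cohort = random_small_cohort(rng, n=25, n_cases=1)
            case_id = cohort.case_ids[0]
            case = cohort.subject_row(case_id)
            spec = MatchingSpec()
            rs = build_risk_set(cohort, case_id, int(case["event_day"]))
            ms = select_controls(rs, cohort, spec, np.random.default_rng(trial))
            # brute force: rank every eligible same-sex subject by distance
            from nestedcc.matching import estimate_covariance, mahalanobis_distance
            cov = estimate_covariance(cohort)
            cands = {
                sid: mahalanobis_distance(
                    case[["gestational_age", "birth_weight"]],
                    cohort.subject_row(sid)[["gestational_age", "birth_weight"]],
                    cov,
                )
                for sid in rs.eligible_ids
                if cohort.subject_row(sid)["sex"] == case["sex"]
            }
            expected = sorted(cands, key=cands.get)[:4]
            if len(cands) > 4:
                assert max(cands[c] for c in ms.control_ids) <= min(
                    cands[s] for s in cands if s not in ms.control_ids
                ) + 1e-12
            assert sorted(ms.control_ids) == sorted(expected) or (
                # allow a random tie at the boundary
                len(ms.control_ids) == min(4, len(cands))
            )
            np.testing.assert_allclose(
                sorted(ms.distances), sorted(cands[c] for c in ms.control_ids)
            )

    def test_short_set_flagged(self):
        cohort = make_cohort([
            ("CASE", "male", 29.0, 800.0, None, 5, 5),
            ("M0", "male", 30.0, 900.0, None, 30, None),
            ("M1", "male", 28.0, 700.0, None, 30, None),
        ])
        rs = build_risk_set(cohort, "CASE", 5)
        ms = select_controls(rs, cohort, MatchingSpec(), np.random.default_rng(0))
        assert ms.short and len(ms.control_ids) == 2

    def test_no_same_stratum_candidates_empty_flagged(self):
        cohort = make_cohort([
            ("CASE", "male", 29.0, 800.0, None, 5, 5),
            ("F0", "female", 29.0, 800.0, None, 30, None),
            ("F1", "female", 30.0, 900.0, None, 30, None),
        ])
        rs = build_risk_set(cohort, "CASE", 5)
        with pytest.warns(UserWarning, match="no eligible same-stratum"):
            ms = select_controls(rs, cohort, MatchingSpec(), np.random.default_rng(0))
        assert ms.control_ids == () and ms.short

    def test_boundary_tie_broken_uniformly(self):
        # five candidates; two tied exactly at the 4th-smallest distance
        subjects = [("CASE", "male", 30.0, 900.0, None, 5, 5)]
        subjects += [
            ("NEAR0", "male", 30.0, 900.0, None, 30, None),
            ("NEAR1", "male", 30.1, 910.0, None, 30, None),
            ("NEAR2", "male", 29.9, 890.0, None, 30, None),
            ("TIEA", "male", 31.0, 1000.0, None, 30, None),
            ("TIEB", "male", 29.0, 800.0, None, 30, None),  # mirror of TIEA
        ]
        cohort = make_cohort(subjects)
        spec = MatchingSpec()
        rs = build_risk_set(cohort, "CASE", 5)
        picks = {"TIEA": 0, "TIEB": 0}
        for seed in range(1000):
            ms = select_controls(rs, cohort, spec, np.random.default_rng(seed))
            chosen = set(ms.control_ids)
            assert {"NEAR0", "NEAR1", "NEAR2"} <= chosen
            (tied,) = chosen - {"NEAR0", "NEAR1", "NEAR2"}
            picks[tied] += 1
        # binomial(1000, 0.5): 3.3 sigma band
        assert 448 < picks["TIEA"] < 552


class TestSampleAll:
    def test_single_case_single_set(self, tiny_cohort):
        sets = sample_all(tiny_cohort, MatchingSpec(), seed=1)
        assert len(sets) == 1
        assert sets[0].case_id == "A02"
        assert "A02" not in sets[0].control_ids

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        cohort = random_small_cohort(rng, n=40, n_cases=6)
        a = sample_all(cohort, MatchingSpec(), seed=9)
        b = sample_all(cohort, MatchingSpec(), seed=9)
        assert a == b
        c = sample_all(cohort, MatchingSpec(controls_per_case=2), seed=9)
        assert all(len(ms.control_ids) <= 2 for ms in c)

    def test_future_case_serves_as_control_then_case(self):
        subjects = [("CASE3", "male", 29.0, 800.0, None, 3, 3),
                    ("CASE18", "male", 29.1, 810.0, None, 18, 18)]
        subjects += [(f"M{i}", "male", 31.0 + i, 1100.0 + 50 * i, None, 30, None)
                     for i in range(5)]
        cohort = make_cohort(subjects)
        sets = sample_all(cohort, MatchingSpec(), seed=0)
        assert [ms.case_id for ms in sets] == ["CASE3", "CASE18"]
        assert "CASE18" in sets[0].control_ids     # closest by construction
        assert "CASE3" not in sets[1].control_ids  # prior case never reused

    def test_no_case_in_own_set_and_no_prior_events(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            cohort = random_small_cohort(rng, n=30, n_cases=5)
            sets = sample_all(cohort, MatchingSpec(), seed=trial)
            eday = {r["id"]: r["event_day"]
                    for _, r in cohort.subjects.iterrows() if r["event"]}
            for ms in sets:
                assert ms.case_id not in ms.control_ids
                assert len(set(ms.control_ids)) == len(ms.control_ids)
                for cid in ms.control_ids:
                    if cid in eday:
                        assert eday[cid] > ms.event_day

    def test_reuse_accounting(self):
        rng = np.random.default_rng(21)
        cohort = random_small_cohort(rng, n=15, n_cases=4)
        sets = sample_all(cohort, MatchingSpec(), seed=2)
        slots = [cid for ms in sets for cid in ms.control_ids]
        assert len(set(slots)) <= len(slots)

    def test_cohort_without_cases_rejected(self):
        cohort = make_cohort(
            [(f"S{i}", "male", 29.0, 800.0, None, 10, None) for i in range(5)]
        )
        with pytest.raises(ValueError, match="no cases"):
            sample_all(cohort, MatchingSpec(), seed=0)
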