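import dataclasses

import numpy as np
import pytest

import oracles
from conftest import azithro, build_cohort, daily_obs, drug, make_patient
from tvmatch.cohort_model import Cohort, DailyObservation, TreatmentEvent
from tvmatch.matching import (
    Candidate,
    CohortArrays,
    MatchCriteria,
    MatchedPair,
    balance_table,
    enumerate_candidates,
    match_cohort,
    propensity_refine,
    safi_trend_check,
    score_candidates,
)
from tvmatch.synthetic_cohort import default_config, simulate_cohort


def spo2_for(safi, fio2):
    return safi * fio2


def scenario_cohort(control_age=70, control_safi=3.5, control_crp=6.0):
    """One treated patient (index day 1) and one configurable control."""
    statics = [
        make_patient("T1", age=60, discharge=9),
        make_patient("C1", age=control_age, discharge=10),
    ]
    obs = daily_obs(
        "T1", range(10), spo2=spo2_for(3.0, 25.0), fio2=25.0, crp=8.0, xray=2
    ) + daily_obs(
        "C1",
        range(11),
        spo2=spo2_for(control_safi, 25.0),
        fio2=25.0,
        crp=control_crp,
        xray=2,
    )
    treats = (
        azithro("T1", 1)
        + drug("T1", "hydroxychloroquine", 0)
        + drug("C1", "hydroxychloroquine", 0)
    )
    return build_cohort(statics, obs, treats)


class TestEnumerateCandidates:
    def test_feasible_within_all_windows(self):
        cohort = scenario_cohort()  # age diff 10, dSAFI +0.5, dCRP -2
        arrays = CohortArrays(cohort)
        cands = enumerate_candidates("T1", arrays)
        days = {c.control_start_day for c in cands}
        # radiograph only on day 0 (2-day lookback) and co-treatment lag
        # bound the start days
        assert days == {0, 1, 2}
        assert all(c.control_id == "C1" for c in cands)

    def test_age_window_excludes(self):
        cohort = scenario_cohort(control_age=80)  # diff 20 > 15
        assert enumerate_candidates("T1", CohortArrays(cohort)) == []

    def test_safi_lower_window_excludes(self):
        cohort = scenario_cohort(control_safi=1.8)  # dSAFI -1.2 < -1.1
        assert enumerate_candidates("T1", CohortArrays(cohort)) == []

    def test_safi_boundary_inclusive(self):
        cohort = scenario_cohort(control_safi=1.9)  # dSAFI exactly -1.1
        assert enumerate_candidates("T1", CohortArrays(cohort)) != []

    def test_crp_window_excludes(self):
        cohort = scenario_cohort(control_crp=13.0)  # dCRP +5 > +4
        assert enumerate_candidates("T1", CohortArrays(cohort)) == []

    def test_sex_must_match(self):
        cohort = scenario_cohort()
        cohort.statics.loc[cohort.statics.patient_id == "C1", "sex"] = "female"
        assert enumerate_candidates("T1", CohortArrays(cohort)) == []

    def test_cotreatment_set_must_match(self):
        statics = [make_patient("T1", discharge=9), make_patient("C1", discharge=9)]
        obs = daily_obs("T1", range(10)) + daily_obs("C1", range(10))
        treats = azithro("T1", 1) + drug("T1", "tocilizumab", 1)
        cohort = build_cohort(statics, obs, treats)
        assert enumerate_candidates("T1", CohortArrays(cohort)) == []

    def test_corticosteroids_matched_as_class(self):
        statics = [make_patient("T1", discharge=9), make_patient("C1", discharge=9)]
        obs = daily_obs("T1", range(10)) + daily_obs("C1", range(10))
        treats = (
            azithro("T1", 1)
            + drug("T1", "methylprednisolone", 1)
            + drug("C1", "dexamethasone", 1)
        )
        cohort = build_cohort(statics, obs, treats)
        assert enumerate_candidates("T1", CohortArrays(cohort)) != []

    def test_not_exposed_raises(self):
        cohort = scenario_cohort()
        with pytest.raises(ValueError, match="not exposed"):
            enumerate_candidates("C1", CohortArrays(cohort))

    def test_missing_reference_crp_is_infeasible(self):
        cohort = scenario_cohort()
        obs = cohort.observations
        obs.loc[(obs.patient_id == "T1") & (obs.day.isin([0, 1])), "crp"] = np.nan
        cohort = Cohort(cohort.statics, obs, cohort.treatments)
        assert enumerate_candidates("T1", CohortArrays(cohort)) == []

    def test_control_must_be_event_free(self):
        # control discharged day 3: start days beyond 2 are not available
        cohort = scenario_cohort()
        statics = cohort.statics
        statics.loc[statics.patient_id == "C1", "discharge_day"] = 3
        obs = cohort.observations
        obs = obs.loc[~((obs.patient_id == "C1") & (obs.day > 3))]
        cohort = Cohort(statics, obs, cohort.treatments)
        days = {c.control_start_day for c in enumerate_candidates("T1", CohortArrays(cohort))}
        assert days == {0, 1, 2}
        statics.loc[statics.patient_id == "C1", "discharge_day"] = 1
        obs = obs.loc[~((obs.patient_id == "C1") & (obs.day > 1))]
        cohort = Cohort(statics, obs, cohort.treatments)
        days = {c.control_start_day for c in enumerate_candidates("T1", CohortArrays(cohort))}
        assert days == {0}


class TestPropensityRefine:
    def test_identical_snapshot_selected(self):
        # C-identical has the treated patient's exact snapshot; C-far differs
        statics = [
            make_patient("T1", discharge=9),
            make_patient("C1", discharge=10),
            make_patient("C2", discharge=10),
        ]
        obs = (
            daily_obs("T1", range(10), spo2=90.0, crp=8.0)
            + daily_obs("C1", range(11), spo2=90.0, crp=8.0)
            + daily_obs("C2", range(11), spo2=96.0, crp=11.0)
        )
        cohort = build_cohort(statics, obs, azithro("T1", 1))
        arrays = CohortArrays(cohort)
        cands = {"T1": enumerate_candidates("T1", arrays)}
        best = propensity_refine(cands, arrays)["T1"]
        assert best.control_id == "C1"
        assert best.ps_distance == pytest.approx(0.0, abs=1e-9)

    def test_proportionally_dominated_candidate_never_selected(self):
        # C2's snapshot differences from the treated patient are 3x C1's in
        # every covariate; C1 must win under either scoring route
        statics = [
            make_patient("T1", discharge=9),
            make_patient("C1", discharge=10),
            make_patient("C2", discharge=10),
        ]
        base = dict(spo2=90.0, crp=8.0, sbp=120.0, dbp=70.0, hr=80.0)
        obs = (
            daily_obs("T1", range(10), **base)
            + daily_obs("C1", range(11), spo2=91.5, crp=9.0, sbp=122.0, dbp=72.0, hr=82.0)
            + daily_obs("C2", range(11), spo2=94.5, crp=11.0, sbp=126.0, dbp=76.0, hr=86.0)
        )
        cohort = build_cohort(statics, obs, azithro("T1", 1))
        arrays = CohortArrays(cohort)
        cands = {"T1": enumerate_candidates("T1", arrays)}
        assert propensity_refine(cands, arrays)["T1"].control_id == "C1"

    def test_single_candidate_selected_regardless(self):
        cohort = scenario_cohort()
        arrays = CohortArrays(cohort)
        cands = {"T1": enumerate_candidates("T1", arrays)}
        assert propensity_refine(cands, arrays)["T1"] is not None

    def test_no_candidates_gives_none(self):
        cohort = scenario_cohort(control_age=80)
        arrays = CohortArrays(cohort)
        assert propensity_refine({"T1": []}, arrays)["T1"] is None


class TestMatchCohort:
    def test_no_shared_sex_zero_pairs(self):
        statics = [
            make_patient("T1", sex="male", discharge=9),
            make_patient("C1", sex="female", discharge=9),
        ]
        obs = daily_obs("T1", range(10)) + daily_obs("C1", range(10))
        cohort = build_cohort(statics, obs, azithro("T1", 1))
        res = match_cohort(cohort)
        assert res.pairs == [] and res.unmatched_treated == ["T1"]

    def test_two_treated_one_control(self):
        statics = [
            make_patient("T1", discharge=9),
            make_patient("T2", discharge=9),
            make_patient("C1", discharge=10),
        ]
        obs = (
            daily_obs("T1", range(10))
            + daily_obs("T2", range(10))
            + daily_obs("C1", range(11))
        )
        cohort = build_cohort(statics, obs, azithro("T1", 1) + azithro("T2", 1))
        res = match_cohort(cohort)
        assert len(res.pairs) == 1 and len(res.unmatched_treated) == 1
        # ascending-id greedy: T1 takes the only control
        assert res.pairs[0].treated_id == "T1" and res.unmatched_treated == ["T2"]

    def test_controls_never_reused(self, small_cohort):
        res = match_cohort(small_cohort)
        ids = [p.control_id for p in res.pairs]
        assert len(ids) == len(set(ids))

    def test_partially_dosed_patients_excluded_from_both_arms(self):
        statics = [
            make_patient("T1", discharge=9),
            make_patient("P2", discharge=9),  # 2 doses: neither arm
            make_patient("C1", discharge=10),
        ]
        obs = (
            daily_obs("T1", range(10))
            + daily_obs("P2", range(10))
            + daily_obs("C1", range(11))
        )
        cohort = build_cohort(statics, obs, azithro("T1", 1) + azithro("P2", 1, n=2))
        arrays = CohortArrays(cohort)
        assert list(arrays.treated_ids()) == ["T1"]
        assert "P2" not in arrays.control_ids()

    def test_deterministic(self, small_cohort):
        a = match_cohort(small_cohort).to_frame()
        b = match_cohort(small_cohort).to_frame()
        assert a.equals(b)

    def test_optimal_mode_at_least_as_many_pairs(self, small_cohort):
        greedy = match_cohort(small_cohort, method="greedy")
        optimal = match_cohort(small_cohort, method="optimal")
        assert len(optimal.pairs) >= len(greedy.pairs)
        for res in (greedy, optimal):
            ids = [p.control_id for p in res.pairs]
            assert len(ids) == len(set(ids))

    def test_emitted_pairs_satisfy_all_hard_constraints(self, small_cohort):
        res = match_cohort(small_cohort)
        feasible = set(oracles.oracle_candidates(small_cohort))
        for p in res.pairs:
            assert (
                p.treated_id,
                p.treated_index_day,
                p.control_id,
                p.control_start_day,
            ) in feasible

    def test_unknown_method_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            match_cohort(small_cohort, method="magic")


class TestOracleEquivalence:
    """Feasible sets match an independent triple loop on random mini-cohorts."""

    def mini_cohort(self, rng):
        from conftest import random_mini_cohort

        return random_mini_cohort(rng)

    def package_candidates(self, cohort):
        arrays = CohortArrays(cohort)
        out = []
        for tid in sorted(arrays.treated_ids()):
            for c in enumerate_candidates(tid, arrays):
                out.append(
                    (c.treated_id, c.treated_index_day, c.control_id, c.control_start_day)
                )
        return sorted(out)

    def test_feasible_sets_equal_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            cohort = self.mini_cohort(rng)
            assert self.package_candidates(cohort) == oracles.oracle_candidates(cohort)

    def test_greedy_pair_count_bounded_by_max_matching(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            cohort = self.mini_cohort(rng)
            cands = self.package_candidates(cohort)
            edges = {(t, c) for t, _, c, _ in cands}
            res = match_cohort(cohort)
            assert len(res.pairs) <= oracles.max_bipartite_matching(edges)

    def test_tightening_never_adds_candidates(self):
        rng = np.random.default_rng(55)
        wide = MatchCriteria()
        tight = MatchCriteria(
            age_window=8.0, safi_window=(-0.5, 1.0), crp_window=(-3.0, 2.0),
            cotreatment_lag=1,
        )
        for _ in range(20):
            cohort = self.mini_cohort(rng)
            arrays = CohortArrays(cohort)
            for tid in arrays.treated_ids():
                wide_set = {
                    (c.control_id, c.control_start_day)
                    for c in enumerate_candidates(tid, arrays, wide)
                }
                tight_set = {
                    (c.control_id, c.control_start_day)
                    for c in enumerate_candidates(tid, arrays, tight)
                }
                assert tight_set <= wide_set

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            MatchCriteria(age_window=-1).validate()
        with pytest.raises(ValueError):
            MatchCriteria(safi_window=(2.0, -1.1)).validate()
        with pytest.raises(ValueError, match="unknown co-treatment"):
            MatchCriteria(cotreatment_drugs=("aspirin",)).validate()


def constant_pairs(n, t_kw=None, c_kw=None, start_day=1):
    """Hand-built matched pairs over a synthetic two-arm cohort."""
    t_kw = t_kw or {}
    c_kw = c_kw or {}
    statics, obs, pairs = [], [], []
    for i in range(n):
        tid, cid = f"T{i:02d}", f"C{i:02d}"
        t_args = {k: (v(i) if callable(v) else v) for k, v in t_kw.items()}
        c_args = {k: (v(i) if callable(v) else v) for k, v in c_kw.items()}
        t_stat = t_args.pop("static", {})
        c_stat = c_args.pop("static", {})
        statics += [
            make_patient(tid, discharge=8, **t_stat),
            make_patient(cid, discharge=8, **c_stat),
        ]
        obs += daily_obs(tid, range(9), **t_args) + daily_obs(cid, range(9), **c_args)
        pairs.append((tid, cid))
    cohort = build_cohort(statics, obs)
    arrays = CohortArrays(cohort)
    matched = [
        MatchedPair(
            Candidate(
                treated_id=t,
                treated_index_day=start_day,
                control_id=c,
                control_start_day=start_day,
                treated_snapshot=arrays.snapshot(arrays.index[t], start_day),
                control_snapshot=arrays.snapshot(arrays.index[c], start_day),
            ),
            0.0,
        )
        for t, c in pairs
    ]
    return cohort, arrays, matched


class TestBalanceTable:
    def test_identical_covariates_all_p_one(self):
        cohort, arrays, pairs = constant_pairs(10)
        table = balance_table(pairs, cohort, arrays=arrays).set_index("variable")
        for var in ("age", "male", "obesity", "saturation", "crp", "safi"):
            assert table.loc[var, "p"] == pytest.approx(1.0)

    def test_constant_age_shift_detected(self):
        ages_t = lambda i: 58 + (i % 2) * 4
        ages_c = lambda i: 78 + (i % 2) * 4
        cohort, arrays, pairs = constant_pairs(
            29,
            t_kw={"static": lambda i: {"age": ages_t(i)}},
            c_kw={"static": lambda i: {"age": ages_c(i)}},
        )
        table = balance_table(pairs, cohort, arrays=arrays).set_index("variable")
        assert table.loc["age", "p"] < 0.05
        assert table.loc["age", "control"] - table.loc["age", "treated"] == pytest.approx(20.0)

    def test_row_set_covers_expected_covariates(self, small_cohort):
        res = match_cohort(small_cohort)
        table = balance_table(res.pairs, small_cohort)
        expected = {
            "age", "male", "obesity", "chf", "crf", "sahs", "tobacco",
            "hypertension", "diabetes", "copd", "other_cardiopathy",
            "saturation", "sbp", "dbp", "hr", "temperature", "safi",
            "safi_trend", "xray_quadrants", "crp", "hydroxychloroquine",
            "lopinavir_ritonavir", "interferon", "tocilizumab",
            "methylprednisolone", "dexamethasone", "hospital_stay",
        }
        assert set(table["variable"]) == expected

    def test_empty_pairs_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            balance_table([], small_cohort)


class TestSafiTrendCheck:
    def test_flat_trajectories(self):
        cohort, arrays, pairs = constant_pairs(8)
        res = safi_trend_check(pairs, arrays)
        assert res.treated_mean == pytest.approx(0.0)
        assert res.control_mean == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_declining_group_detected(self):
        # treated decline 0.5 SAFI/day (on FiO2 30: 15 saturation points/day)
        spo2_t = {d: 90.0 - 0.5 * 30.0 * (d - 4) for d in range(9)}
        rng = np.random.default_rng(1)
        cohort, arrays, pairs = constant_pairs(
            29,
            t_kw={"spo2": lambda i: {d: min(100, 150 - 15 * d + (i % 3)) for d in range(9)}},
            c_kw={"spo2": lambda i: {d: 90.0 + (i % 3) for d in range(9)}},
            start_day=4,
        )
        res = safi_trend_check(pairs, arrays)
        assert res.treated_mean < res.control_mean
        assert res.p < 0.05

    def test_start_day_zero_excluded(self):
        cohort, arrays, pairs = constant_pairs(5, start_day=0)
        res = safi_trend_check(pairs, arrays)
        assert res.n_pairs_used == 0 and res.n_pairs_excluded == 5
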