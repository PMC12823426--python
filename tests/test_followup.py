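"""Exposure episodes, censoring hierarchy and endpoint ascertainment."""

import numpy as np
import pandas as pd
import pytest

import ttebench as tb
from ttebench.errors import ConfigError
from ttebench.followup import _episode_ends

from conftest import make_bundle

MACE = tb.EndpointDef("mace", {"death": frozenset(),
                               "myocardial_infarction": frozenset({"EV_MI"}),
                               "stroke": frozenset({"EV_STROKE"})}, primary=True)
NONFATAL = tb.EndpointDef("mace_nonfatal",
                          {"myocardial_infarction": frozenset({"EV_MI"}),
                           "stroke": frozenset({"EV_STROKE"})})
SPEC = tb.FollowUpSpec(endpoints=(MACE, NONFATAL))
AS_STARTED = tb.FollowUpSpec(endpoints=(MACE, NONFATAL), contrast="as_started")


class TestExposureEpisode:
    def test_single_fill(self):
        assert tb.exposure_episode([0], 30, 0, 45) == 75

    def test_chained_fills(self):
        # second fill at 40 <= 30 + 45 chains; supply end 70 -> 115
        assert tb.exposure_episode([0, 40], 30, 0, 45) == 115

    def test_gap_breaks_chain(self):
        # 100 > 75: episode ends at 75, later fill ignored
        assert tb.exposure_episode([0, 100], 30, 0, 45) == 75

    def test_boundary_fill_exactly_at_grace_end_chains(self):
        assert tb.exposure_episode([0, 75], 30, 0, 45) == 150

    def test_requires_index_fill(self):
        with pytest.raises(ConfigError):
            tb.exposure_episode([10], 30, 0, 45)

    def test_vectorized_chain_matches_scalar(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(1, 6)
            gaps = rng.integers(1, 120, n - 1) if n > 1 else []
            fills = np.concatenate([[0], np.cumsum(gaps)]).astype(int)
            sups = rng.integers(7, 90, n)
            expected = tb.exposure_episode(fills.tolist(), sups.tolist(), 0, 45)
            got = _episode_ends(np.zeros(n, dtype=int), fills, sups, 45)[0]
            assert got == expected


class TestDetermineExit:
    def _exit(self, events, censors, endpoint=MACE, spec=SPEC):
        base = {"discontinuation": None, "switch": None, "same_class_start": None,
                "disenrollment": None, "study_end": 364}
        base.update(censors)
        return tb.determine_exit(events, base, 0, spec, endpoint)

    def test_event_before_discontinuation(self):
        t, status, comp, reason = self._exit({"myocardial_infarction": 50},
                                             {"discontinuation": 75})
        assert (t, status, comp) == (50, "event", "myocardial_infarction")

    def test_earliest_censor_wins_with_reason(self):
        t, status, comp, reason = self._exit({}, {"disenrollment": 100,
                                                  "discontinuation": 115})
        assert (t, status, reason) == (100, "censored", "disenrollment")

    def test_event_outranks_censoring_on_tie(self):
        t, status, comp, _ = self._exit({"stroke": 60}, {"discontinuation": 60})
        assert (t, status, comp) == (60, "event", "stroke")

    def test_earliest_component_wins(self):
        t, status, comp, _ = self._exit({"myocardial_infarction": 30, "death": 200}, {})
        assert (t, comp) == (30, "myocardial_infarction")

    def test_same_day_components_resolve_by_severity(self):
        t, status, comp, _ = self._exit({"myocardial_infarction": 90, "stroke": 90}, {})
        assert comp == "myocardial_infarction"
        t, status, comp, _ = self._exit({"death": 90, "stroke": 90}, {})
        assert comp == "death"

    def test_death_is_competing_for_nonfatal_composite(self):
        t, status, comp, _ = self._exit({"death": 90}, {}, endpoint=NONFATAL)
        assert (t, status) == (90, "competing_death")

    def test_death_after_censor_not_counted(self):
        t, status, comp, reason = self._exit({"death": 200},
                                             {"discontinuation": 100},
                                             endpoint=NONFATAL)
        assert (t, status, reason) == (100, "censored", "discontinuation")

    def test_as_started_ignores_treatment_censoring(self):
        t, status, _, reason = tb.determine_exit(
            {}, {"discontinuation": 75, "switch": None, "same_class_start": None,
                 "disenrollment": None, "study_end": 364}, 0, AS_STARTED, MACE)
        assert (t, reason) == (364, "study_end")


class TestBuildFollowup:
    def _bundle_and_cohort(self):
        bundle = make_bundle(
            patients=[(1, 1960, "F", "south"), (2, 1960, "M", "west"),
                      (3, 1955, "F", "west")],
            enrollment=[(1, 0, 1400), (2, 0, 500), (3, 0, 1400)],
            dispensings=[(1, "RX_EXPO", 400, 30),
                         (2, "RX_COMP", 400, 30),
                         (3, "RX_EXPO", 400, 30), (3, "RX_COMP", 460, 30)],
            diagnoses=[(1, "EV_MI", 430, "inpatient")],
            deaths=[(3, 490)])
        cohort = pd.DataFrame({
            "patient_id": [1, 2, 3],
            "arm": ["exposure", "comparator", "exposure"],
            "index_day": [400, 400, 400],
        })
        return bundle, cohort

    def test_one_record_per_member_per_endpoint(self):
        bundle, cohort = self._bundle_and_cohort()
        fu = tb.build_followup(bundle, cohort, SPEC)
        for name, rec in fu.items():
            assert sorted(rec["patient_id"]) == [1, 2, 3]
            assert (rec["time"] <= SPEC.max_days).all()
            assert (rec["time"] >= 1).all()

    def test_event_and_censor_resolution(self):
        bundle, cohort = self._bundle_and_cohort()
        rec = tb.build_followup(bundle, cohort, SPEC)["mace"].set_index("patient_id")
        assert rec.loc[1, "status"] == "event"
        assert rec.loc[1, "time"] == 30  # MI at day 430, index 400
        assert rec.loc[2, "status"] == "censored"
        assert rec.loc[2, "censor_reason"] == "discontinuation"
        assert rec.loc[2, "time"] == 75
        # patient 3 switches at day 460 (before death day 490)
        assert rec.loc[3, "censor_reason"] == "switch"
        assert rec.loc[3, "time"] == 60

    def test_as_started_never_shortens_followup(self):
        bundle, cohort = self._bundle_and_cohort()
        at = tb.build_followup(bundle, cohort, SPEC)["mace"].set_index("patient_id")
        ast = tb.build_followup(bundle, cohort, AS_STARTED)["mace"].set_index("patient_id")
        assert (ast["time"] >= at["time"]).all()

    def test_conservation_on_generated_data(self, small_generated_bundle):
        cfg, bundle = small_generated_bundle
        cohort, _ = tb.build_cohort(bundle, tb.EligibilitySpec())
        from ttebench.followup import endpoints_from_scenario
        spec = tb.FollowUpSpec(endpoints=endpoints_from_scenario(cfg))
        fu = tb.build_followup(bundle, cohort, spec)
        for rec in fu.values():
            assert len(rec) == len(cohort)
            assert rec["status"].isin(["event", "censored", "competing_death"]).all()
            n_by_exit = rec.groupby("status").size().sum()
            assert n_by_exit == len(cohort)
            assert (rec["time"].between(1, spec.max_days)).all()

    def test_as_started_dominates_on_generated_data(self, small_generated_bundle):
        cfg, bundle = small_generated_bundle
        cohort, _ = tb.build_cohort(bundle, tb.EligibilitySpec())
        from ttebench.followup import endpoints_from_scenario
        eps = tuple(e for e in endpoints_from_scenario(cfg) if e.name == "mace")
        at = tb.build_followup(bundle, cohort, tb.FollowUpSpec(endpoints=eps))["mace"]
        ast = tb.build_followup(bundle, cohort,
                                tb.FollowUpSpec(endpoints=eps,
                                                contrast="as_started"))["mace"]
        merged = at.merge(ast, on="patient_id", suffixes=("_at", "_ast"))
        assert (merged["time_ast"] >= merged["time_at"]).all()


class TestCensoringSummary:
    def test_all_events_empty_summary(self):
        rec = pd.DataFrame({"status": ["event", "event"],
                            "censor_reason": [None, None]})
        assert tb.censoring_summary(rec).empty

    def test_proportions(self):
        rec = pd.DataFrame({
            "status": ["censored"] * 4 + ["event"],
            "censor_reason": ["discontinuation", "discontinuation", "switch",
                              "disenrollment", None]})
        out = tb.censoring_summary(rec).set_index("censor_reason")
        assert out.loc["discontinuation", "proportion"] == 0.5
        assert out["proportion"].sum() == pytest.approx(1.0)

    def test_discontinuation_modal_in_generated_scenario(self, small_generated_bundle):
        cfg, bundle = small_generated_bundle
        cohort, _ = tb.build_cohort(bundle, tb.EligibilitySpec())
        from ttebench.followup import endpoints_from_scenario
        eps = tuple(e for e in endpoints_from_scenario(cfg) if e.name == "mace")
        rec = tb.build_followup(bundle, cohort, tb.FollowUpSpec(endpoints=eps))["mace"]
        out = tb.censoring_summary(rec)
        assert out.iloc[0]["censor_reason"] == "discontinuation"
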