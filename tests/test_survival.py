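"""Kaplan–Meier, Aalen–Johansen, bootstrap risk differences and Cox HRs."""

import math

import numpy as np
import pandas as pd
import pytest

import ttebench as tb
from ttebench.errors import ConfigError, TTEBenchError
from ttebench.survival import _cox_loglik, _fast_risk_at

from conftest import followup_records


def _records(rows):
    """rows: (time, status) for a single arm."""
    return pd.DataFrame({"time": [t for t, _ in rows],
                         "status": [s for _, s in rows]})


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = tb.kaplan_meier(_records([(5, "censored"), (10, "event"),
                                          (15, "event")]))
        # S(10) = 1 * (1 - 1/2) = 0.5 ; S(15) = 0
        assert curve.risk_at(10) == pytest.approx(0.5)
        assert curve.risk_at(15) == pytest.approx(1.0)
        assert curve.risk_at(9) == 0.0

    def test_no_events_zero_risk(self):
        curve = tb.kaplan_meier(_records([(364, "censored")] * 10))
        assert curve.risk_at(364) == 0.0

    def test_replication_invariance(self):
        rows = [(5, "censored"), (10, "event"), (15, "event")]
        a = tb.kaplan_meier(_records(rows))
        b = tb.kaplan_meier(_records(rows * 2))
        assert np.allclose(a.risk, b.risk)
        assert np.array_equal(a.times, b.times)

    def test_record_order_invariance(self):
        rng = np.random.default_rng(0)
        rec = _records([(int(t), "event" if e else "censored")
                        for t, e in zip(rng.integers(1, 100, 80),
                                        rng.random(80) < 0.5)])
        shuffled = rec.sample(frac=1, random_state=1).reset_index(drop=True)
        assert np.allclose(tb.kaplan_meier(rec).risk,
                           tb.kaplan_meier(shuffled).risk)

    def test_risk_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        rec = _records([(int(t), "event" if e else "censored")
                        for t, e in zip(rng.integers(1, 200, 150),
                                        rng.random(150) < 0.4)])
        curve = tb.kaplan_meier(rec)
        assert (np.diff(curve.risk) >= 0).all()
        assert ((curve.risk >= 0) & (curve.risk <= 1)).all()
        assert (np.diff(curve.at_risk) <= 0).all()

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(2)
        t = rng.integers(1, 300, 400).astype(float)
        e = rng.random(400) < 0.4
        rec = _records(list(zip(t, np.where(e, "event", "censored"))))
        curve = tb.kaplan_meier(rec)
        kmf = KaplanMeierFitter().fit(t, e)
        theirs = (1 - kmf.survival_function_.loc[curve.times, "KM_estimate"]).to_numpy()
        assert np.allclose(curve.risk, theirs)

    def test_empty_input_raises(self):
        with pytest.raises(ConfigError):
            tb.kaplan_meier(_records([]))

    def test_competing_records_rejected(self):
        with pytest.raises(ConfigError):
            tb.kaplan_meier(_records([(5, "competing_death")]))


class TestAalenJohansen:
    def test_hand_computation(self):
        curve = tb.aalen_johansen(_records([(1, "competing_death"), (2, "event"),
                                            (3, "censored")]))
        # S(1) = 2/3; CIF(3) = S(1-) at t=2 * 1/2 = (2/3) * (1/2) = 1/3
        assert curve.risk_at(3) == pytest.approx(1 / 3)

    def test_reduces_to_km_without_competing_events(self):
        rng = np.random.default_rng(3)
        rows = [(int(t), "event" if e else "censored")
                for t, e in zip(rng.integers(1, 120, 100), rng.random(100) < 0.5)]
        km = tb.kaplan_meier(_records(rows))
        aj = tb.aalen_johansen(_records(rows))
        grid = np.unique(np.concatenate([km.times, aj.times]))
        assert np.allclose([km.risk_at(u) for u in grid],
                           [aj.risk_at(u) for u in grid])

    def test_probability_conservation(self):
        rng = np.random.default_rng(4)
        statuses = rng.choice(["event", "competing_death", "censored"], 300,
                              p=[0.3, 0.2, 0.5])
        times = rng.integers(1, 150, 300)
        rec = _records(list(zip(times, statuses)))
        cif_cause = tb.aalen_johansen(rec)
        swapped = rec.replace({"status": {"event": "competing_death",
                                          "competing_death": "event"}})
        cif_death = tb.aalen_johansen(swapped)
        # all-cause survival from KM on any-event indicator
        any_ev = rec.replace({"status": {"competing_death": "event"}})
        km_all = tb.kaplan_meier(any_ev)
        for u in km_all.times:
            total = cif_cause.risk_at(u) + cif_death.risk_at(u) + (1 - km_all.risk_at(u))
            assert total == pytest.approx(1.0)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import AalenJohansenFitter
        rng = np.random.default_rng(5)
        t = np.sort(rng.choice(np.arange(1, 5000), 120, replace=False)).astype(float)
        status = rng.choice([0, 1, 2], 120, p=[0.4, 0.35, 0.25])
        rec = _records(list(zip(
            t, np.array(["censored", "event", "competing_death"])[status])))
        curve = tb.aalen_johansen(rec)
        ajf = AalenJohansenFitter(calculate_variance=False).fit(
            t, status, event_of_interest=1)
        col = ajf.cumulative_density_.columns[0]
        theirs = ajf.cumulative_density_[col]
        for u in curve.times:
            assert curve.risk_at(u) == pytest.approx(
                float(theirs.loc[:u].iloc[-1]), abs=1e-10)


class TestFastRiskAt:
    def test_agrees_with_curves(self):
        rng = np.random.default_rng(6)
        for competing in (False, True):
            statuses = (["event", "censored", "competing_death"] if competing
                        else ["event", "censored"])
            s = rng.choice(statuses, 250)
            t = rng.integers(1, 364, 250)
            rec = _records(list(zip(t, s)))
            est = tb.aalen_johansen(rec) if competing else tb.kaplan_meier(rec)
            times, codes = t.astype(float), pd.Series(s).map(
                {"censored": 0, "event": 1, "competing_death": 2}).to_numpy()
            for h in (30, 180, 364):
                assert _fast_risk_at(times, codes, h, competing) == pytest.approx(
                    est.risk_at(h), abs=1e-12)


class TestRiskDifference:
    def _arms(self, n=150, seed=0, shift=0):
        rng = np.random.default_rng(seed)
        rows = []
        for arm, extra in (("exposure", shift), ("comparator", 0)):
            t = rng.integers(1, 365, n)
            ev = rng.random(n) < (0.2 + extra)
            rows += [(arm, int(ti), "event" if e else "censored")
                     for ti, e in zip(t, ev)]
        return followup_records(rows)

    def test_identical_arms_rd_zero_ci_covers_zero(self):
        rng = np.random.default_rng(7)
        t = rng.integers(1, 365, 100)
        ev = rng.random(100) < 0.3
        rows = [(arm, int(ti), "event" if e else "censored")
                for arm in ("exposure", "comparator")
                for ti, e in zip(t, ev)]
        rd = tb.risk_difference(followup_records(rows), horizon=364,
                                n_bootstrap=100, seed=0)
        assert rd.rd == pytest.approx(0.0, abs=1e-12)
        assert rd.rd_ci[0] <= 0 <= rd.rd_ci[1]

    def test_rd_is_contrast_of_point_estimates(self):
        rec = self._arms(shift=0.2)
        rd = tb.risk_difference(rec, horizon=364, n_bootstrap=50, seed=1)
        e = tb.kaplan_meier(rec[rec["arm"] == "exposure"][["time", "status"]])
        c = tb.kaplan_meier(rec[rec["arm"] == "comparator"][["time", "status"]])
        assert rd.rd == pytest.approx(e.risk_at(364) - c.risk_at(364))

    def test_seeded_reproducibility_and_seed_sensitivity(self):
        rec = self._arms()
        a = tb.risk_difference(rec, 364, n_bootstrap=100, seed=5)
        b = tb.risk_difference(rec, 364, n_bootstrap=100, seed=5)
        c = tb.risk_difference(rec, 364, n_bootstrap=100, seed=6)
        assert a.rd_ci == b.rd_ci
        assert a.rd_ci != c.rd_ci

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ConfigError):
            tb.risk_difference(self._arms(), 364, n_bootstrap=1)


class TestCoxHR:
    def test_identical_arms_hr_one(self):
        rng = np.random.default_rng(8)
        t = rng.integers(1, 200, 60)
        ev = rng.random(60) < 0.5
        rows = [(arm, int(ti), "event" if e else "censored")
                for arm in ("exposure", "comparator")
                for ti, e in zip(t, ev)]
        est = tb.cox_hr(followup_records(rows))
        assert est.log_hr == pytest.approx(0.0, abs=1e-8)

    def test_matches_bruteforce_partial_likelihood_scan(self):
        # 20 patients, distinct event times
        rng = np.random.default_rng(9)
        t = rng.choice(np.arange(1, 400), 20, replace=False).astype(float)
        ev = rng.random(20) < 0.7
        arm = np.where(rng.random(20) < 0.5, "exposure", "comparator")
        rec = followup_records(list(zip(arm, t.astype(int),
                                        np.where(ev, "event", "censored"))))
        est = tb.cox_hr(rec)
        order = np.argsort(t, kind="mergesort")
        x = (arm == "exposure").astype(float)
        grid = np.linspace(-3, 3, 120001)
        lls = [_cox_loglik(b, t[order], ev[order], x[order], "efron")[0]
               for b in grid]
        assert est.log_hr == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(10)
        t = rng.choice(np.arange(1, 2000), 50, replace=False)
        ev = rng.random(50) < 0.6
        arm = np.where(rng.random(50) < 0.5, "exposure", "comparator")
        rec = followup_records(list(zip(arm, t, np.where(ev, "event", "censored"))))
        a = tb.cox_hr(rec, ties="efron")
        b = tb.cox_hr(rec, ties="breslow")
        assert a.log_hr == pytest.approx(b.log_hr, abs=1e-9)
        assert a.se_log_hr == pytest.approx(b.se_log_hr, abs=1e-9)

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(11)
        t = rng.integers(1, 60, 300).astype(float)  # heavy ties
        ev = rng.random(300) < 0.5
        arm = np.where(rng.random(300) < 0.5, "exposure", "comparator")
        rec = followup_records(list(zip(arm, t.astype(int),
                                        np.where(ev, "event", "censored"))))
        est = tb.cox_hr(rec)
        df = pd.DataFrame({"T": t, "E": ev, "x": (arm == "exposure").astype(float)})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert est.log_hr == pytest.approx(cph.params_["x"], abs=1e-6)
        assert est.se_log_hr == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_competing_death_censors_cause_specific_hazard(self):
        rows = [("exposure", 10, "event"), ("exposure", 20, "competing_death"),
                ("comparator", 15, "event"), ("comparator", 30, "censored")]
        est = tb.cox_hr(followup_records(rows))
        rows_censored = [("exposure", 10, "event"), ("exposure", 20, "censored"),
                         ("comparator", 15, "event"), ("comparator", 30, "censored")]
        est2 = tb.cox_hr(followup_records(rows_censored))
        assert est.log_hr == pytest.approx(est2.log_hr)

    def test_zero_event_arm_flagged_monotone(self):
        rows = [("exposure", 10, "event"), ("exposure", 20, "event"),
                ("comparator", 30, "censored"), ("comparator", 40, "censored")]
        est = tb.cox_hr(followup_records(rows))
        assert est.flag == "monotone"
        assert not math.isfinite(est.log_hr)

    def test_no_events_raises(self):
        rows = [("exposure", 10, "censored"), ("comparator", 20, "censored")]
        with pytest.raises(TTEBenchError):
            tb.cox_hr(followup_records(rows))

    def test_invalid_ties_method_rejected(self):
        with pytest.raises(ConfigError):
            tb.cox_hr(followup_records([("exposure", 10, "event")]), ties="exact")
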