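"""Kaplan-Meier estimation and the Peto-Peto weighted log-rank test."""

import numpy as np
import pandas as pd
import pytest

from iitr.survival import (build_records, calibrate, km_estimate,
                           pairwise_peto_peto, peto_peto_test, removal_curve,
                           survival_at)
from iitr.synthetic import RemovalModel, generate_removal_experiment
from reference import km_redistribute, peto_peto_direct


def records(times, events, groups=None):
    df = pd.DataFrame({"time_h": times, "event": events})
    if groups is not None:
        df["group"] = groups
    return df


class TestBuildRecords:
    def test_counting_oracle(self):
        counts = pd.DataFrame({
            "animal_id": ["a"] * 3, "group": ["g"] * 3,
            "time_h": [0.0, 24.0, 48.0], "count": [15, 10, 8]})
        rec = build_records(counts)
        assert len(rec) == 15
        assert ((rec["time_h"] == 24.0) & (rec["event"] == 1)).sum() == 5
        assert ((rec["time_h"] == 48.0) & (rec["event"] == 1)).sum() == 2
        assert ((rec["time_h"] == 48.0) & (rec["event"] == 0)).sum() == 8

    def test_constant_counts_all_censored(self):
        counts = pd.DataFrame({"animal_id": ["a"] * 2, "time_h": [0.0, 48.0],
                               "count": [7, 7]})
        rec = build_records(counts)
        assert (rec["event"] == 0).all() and len(rec) == 7

    def test_midpoint_coding_shifts_event_times(self):
        counts = pd.DataFrame({"animal_id": ["a"] * 2, "time_h": [12.0, 24.0],
                               "count": [5, 3]})
        right = build_records(counts)
        mid = build_records(counts, event_time="midpoint")
        assert (right.loc[right["event"] == 1, "time_h"] == 24.0).all()
        assert (mid.loc[mid["event"] == 1, "time_h"] == 18.0).all()

    def test_rising_count_rejected_with_context(self):
        counts = pd.DataFrame({"animal_id": ["gp3"] * 2, "time_h": [12.0, 24.0],
                               "count": [8, 9]})
        with pytest.raises(ValueError, match="gp3"):
            build_records(counts)


class TestKaplanMeier:
    def test_four_tick_worked_example(self):
        rec = records([1, 2, 3, 3], [1, 1, 0, 0])
        c = km_estimate(rec)
        np.testing.assert_allclose(c.S, [0.75, 0.5])
        assert survival_at(c, 2.0)[0] == 0.5
        assert survival_at(c, 0.5)[0] == 1.0

    def test_greenwood_variance_hand_computation(self):
        rec = records([1, 2, 3, 3], [1, 1, 0, 0])
        c = km_estimate(rec)
        # var S(1) = 0.75^2 * (1/(4*3)); var S(2) = 0.5^2 * (1/12 + 1/(3*2))
        np.testing.assert_allclose(c.var_S, [0.75**2 / 12, 0.25 * (1 / 12 + 1 / 6)])
        assert np.all(np.diff(c.var_S) >= 0)

    def test_all_censored_survival_is_one_with_warning(self):
        with pytest.warns(UserWarning):
            c = km_estimate(records([5, 6], [0, 0]))
        assert c.event_times_h.size == 0
        assert survival_at(c, 10.0)[0] == 1.0

    def test_uncensored_equals_empirical_fraction(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 50))
            t = rng.integers(1, 20, n).astype(float)
            c = km_estimate(records(t, np.ones(n, int)))
            for ti in np.unique(t):
                emp = (t > ti).mean()
                assert survival_at(c, ti)[0] == pytest.approx(emp, abs=1e-12)

    def test_matches_redistribute_to_the_right_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 13))
            t = rng.integers(1, 8, n).astype(float)
            ev = rng.integers(0, 2, n)
            if ev.sum() == 0:
                continue
            c = km_estimate(records(t, ev))
            ot, os_ = km_redistribute(t.tolist(), ev.tolist())
            # oracle reports S at event times observed as events
            for tt, ss in zip(ot, os_):
                assert survival_at(c, tt)[0] == pytest.approx(ss, abs=1e-10)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.integers(1, 30, 60).astype(float)
        ev = rng.integers(0, 2, 60)
        c = km_estimate(records(t, ev))
        kmf = lifelines.KaplanMeierFitter().fit(t, ev)
        for ti, si in zip(c.event_times_h, c.S):
            assert float(kmf.survival_function_at_times(ti).iloc[0]) == pytest.approx(si)

    def test_monotone_and_bounded(self, rng):
        t = rng.integers(1, 30, 80).astype(float)
        ev = rng.integers(0, 2, 80)
        c = km_estimate(records(t, ev))
        assert np.all(np.diff(c.S) <= 1e-12)
        assert np.all((c.S >= 0) & (c.S <= 1))
        assert np.all(c.ci_low <= c.S + 1e-12) and np.all(c.S <= c.ci_high + 1e-12)


class TestRemovalCurve:
    def test_inversion_and_ci_swap(self):
        c = km_estimate(records([1, 2, 3, 3], [1, 1, 0, 0]))
        rc = removal_curve(c)
        np.testing.assert_allclose(rc.R, [25.0, 50.0])
        assert np.all(rc.ci_low <= rc.R + 1e-12)
        assert np.all(rc.R <= rc.ci_high + 1e-12)
        assert np.all(np.diff(rc.R) >= -1e-12)

    def test_no_events_removal_zero(self):
        with pytest.warns(UserWarning):
            rc = removal_curve(km_estimate(records([5], [0])))
        assert rc.R.size == 0


class TestPetoPeto:
    toy = records([1, 2, 3, 4, 5, 6], [1] * 6, ["g1"] * 3 + ["g2"] * 3)

    def test_identical_groups_null(self):
        rec = pd.concat([self.toy.assign(group="a"), self.toy.assign(group="b")])
        res = peto_peto_test(rec)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_relabeling_invariance(self):
        r1 = peto_peto_test(self.toy)
        swapped = self.toy.assign(group=self.toy["group"].map({"g1": "z", "g2": "a"}))
        r2 = peto_peto_test(swapped)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_toy_matches_direct_summation_oracle(self):
        res = peto_peto_test(self.toy)
        oracle = peto_peto_direct(self.toy["time_h"].tolist(),
                                  self.toy["event"].tolist(),
                                  self.toy["group"].tolist())
        assert res.statistic == pytest.approx(oracle, abs=1e-10)
        assert res.df == 1

    def test_random_two_group_data_match_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 25))
            rec = records(rng.integers(1, 10, n).astype(float),
                          rng.integers(0, 2, n),
                          rng.choice(["a", "b"], n))
            if rec["event"].sum() == 0 or rec["group"].nunique() < 2:
                continue
            try:
                res = peto_peto_test(rec)
            except ValueError:
                continue  # a group never at risk
            oracle = peto_peto_direct(rec["time_h"].tolist(), rec["event"].tolist(),
                                      rec["group"].tolist())
            assert res.statistic == pytest.approx(oracle, abs=1e-10)

    def test_weights_decreasing_in_unit_interval(self):
        t = np.array([1, 1, 2, 3, 3, 4, 5, 6], float)
        ev = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        times = np.unique(t[ev == 1])
        n_i = np.array([(t >= ti).sum() for ti in times])
        d_i = np.array([((t == ti) & (ev == 1)).sum() for ti in times])
        w = np.cumprod((n_i - d_i + 1) / (n_i + 1))
        assert np.all((w > 0) & (w <= 1))
        assert np.all(np.diff(w) <= 0)

    def test_unweighted_variant_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import multivariate_logrank_test

        t = rng.integers(1, 15, 40).astype(float)
        ev = rng.integers(0, 2, 40)
        g = rng.choice(["a", "b", "c"], 40)
        res = peto_peto_test(records(t, ev, g), weights="logrank")
        ll = multivariate_logrank_test(t, g, ev)
        assert res.statistic == pytest.approx(float(ll.test_statistic), abs=1e-8)
        assert res.p == pytest.approx(float(ll.p_value), abs=1e-10)
        assert res.df == 2

    def test_permutation_p_agrees_without_censoring(self):
        rng = np.random.default_rng(4)
        t = rng.permutation(np.arange(1.0, 17.0))
        rec = records(t, np.ones(16, int), ["a"] * 8 + ["b"] * 8)
        res = peto_peto_test(rec, method="permutation", reps=4000, seed=9)
        assert abs(res.p - res.p_permutation) < 0.05

    def test_group_never_at_risk_rejected(self):
        rec = records([1.0, 1.0, 5.0], [1, 1, 1], ["a", "a", "b"])
        # group b enters the risk set, so this is fine
        peto_peto_test(rec)
        rec2 = records([5.0, 5.0, 1.0], [0, 0, 1], ["b", "b", "a"])
        # group a at risk at t=1; b also at risk (times 5 >= 1): still valid
        peto_peto_test(rec2)
        with pytest.raises(ValueError, match="2 groups"):
            peto_peto_test(records([1.0], [1], ["a"]))


class TestPairwise:
    def test_pairwise_table_and_holm_ordering(self, rng):
        t = rng.integers(1, 15, 60).astype(float)
        ev = rng.integers(0, 2, 60)
        g = np.repeat(["a", "b", "c"], 20)
        t[g == "c"] = rng.integers(8, 20, 20).astype(float)  # group c later
        tab = pairwise_peto_peto(records(t, ev, g), adjust="holm")
        assert len(tab) == 3
        assert (tab["p_adjusted"] >= tab["p"] - 1e-15).all()
        assert (tab["p_adjusted"] <= 1.0).all()
        unadj = pairwise_peto_peto(records(t, ev, g))
        assert (unadj["p_adjusted"] == unadj["p"]).all()


class TestCalibration:
    def test_alpha_one_rejects_everything(self):
        rate = calibrate(1, [RemovalModel("a", 0.05), RemovalModel("b", 0.05)],
                         10, reps=100, alpha=1.0)
        assert rate == 1.0

    def test_reps_floor(self):
        with pytest.raises(ValueError):
            calibrate(1, [RemovalModel("a", 0.05), RemovalModel("b", 0.05)], 10, reps=10)
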