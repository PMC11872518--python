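"""Trend test, Cox regression, Kaplan-Meier and RMST."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from _oracles import km_hand, rmst_step_integral

from palbopk import (
    TrendTable,
    cox_univariable,
    dichotomized_analysis,
    km_curve,
    rmst_difference,
    trend_test,
)
from palbopk.outcomes import OutcomeRecord, quartile_event_table


class TestTrendTest:
    # reference chi2/p from R prop.trend.test on the printed quartile counts
    R_ORACLE = [
        ((25, 39, 36, 44), (83, 87, 85, 86), 6.308835, 0.01201378),
        ((20, 41, 40, 43), (83, 87, 85, 86), 10.24411, 0.001371217),
        ((35, 39, 40, 41), (86, 85, 85, 86), 0.8479358, 0.357137),
        ((31, 38, 46, 40), (86, 85, 85, 86), 2.877344, 0.08983407),
        ((43, 50, 52, 46), (86, 85, 85, 86), 0.2856302, 0.5930345),
        ((45, 52, 46, 48), (86, 85, 85, 85), 0.05202425, 0.8195776),
    ]

    @pytest.mark.parametrize("events,totals,chi2,p", R_ORACLE)
    def test_matches_r_prop_trend_oracle(self, events, totals, chi2, p):
        out = trend_test(TrendTable(events=events, totals=totals))
        assert out["chi2"] == pytest.approx(chi2, rel=1e-6)
        assert out["p"] == pytest.approx(p, rel=1e-6)

    def test_identical_proportions_no_trend(self):
        out = trend_test(TrendTable(events=(10, 10, 10, 10),
                                    totals=(20, 20, 20, 20)))
        assert out["chi2"] == 0.0
        assert out["p"] == 1.0

    def test_two_group_equals_pearson_chi2(self):
        events, totals = (12, 30), (50, 60)
        out = trend_test(TrendTable(events=events, totals=totals))
        table = np.array([[12, 38], [30, 30]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert out["chi2"] == pytest.approx(chi2, rel=1e-10)
        assert out["p"] == pytest.approx(p, rel=1e-10)

    def test_affine_score_invariance(self):
        events, totals = (5, 9, 13, 20), (40, 40, 40, 40)
        a = trend_test(TrendTable(events, totals, scores=(1, 2, 3, 4)))
        b = trend_test(TrendTable(events, totals, scores=(10, 30, 50, 70)))
        assert a["chi2"] == pytest.approx(b["chi2"], rel=1e-10)

    @pytest.mark.parametrize("events", [(0, 0, 0, 0), (20, 20, 20, 20)])
    def test_degenerate_tables_warn(self, events):
        with pytest.warns(RuntimeWarning):
            out = trend_test(TrendTable(events=events,
                                        totals=(20, 20, 20, 20)))
        assert out["p"] == 1.0

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            TrendTable(events=(5, 5), totals=(4, 10))
        with pytest.raises(ValueError):
            TrendTable(events=(5,), totals=(10,))


class TestCoxUnivariable:
    @staticmethod
    def toy_data():
        # 6 subjects, distinct times, no censoring
        return pd.DataFrame({
            "pfs_time": [5.0, 8.0, 11.0, 14.0, 20.0, 30.0],
            "pfs_event": [True] * 6,
            "x": [3.0, 2.5, 1.0, 2.0, 0.5, 0.2],
        })

    def test_beta_matches_partial_likelihood_grid(self):
        """No ties, no censoring: the Cox coefficient maximizes
        sum_i [b x_i - log sum_{j in risk set} exp(b x_j)]."""
        df = self.toy_data()
        res = cox_univariable(df, "x")
        t = df.pfs_time.to_numpy()
        x = df.x.to_numpy()
        order = np.argsort(t)

        def pl(b):
            val = 0.0
            for k, i in enumerate(order):
                risk = order[k:]
                val += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
            return val

        grid = np.linspace(-3, 3, 6001)
        b_star = grid[int(np.argmax([pl(b) for b in grid]))]
        assert res.beta == pytest.approx(b_star, abs=1e-3)

    def test_unit_rescaling_identity(self):
        df = self.toy_data()
        per1 = cox_univariable(df, "x", unit_scale=1.0)
        per10 = cox_univariable(df, "x", unit_scale=10.0)
        assert per10.hr == pytest.approx(per1.hr**10, rel=1e-9)

    def test_null_simulation_hr_near_one(self):
        rng = np.random.default_rng(1234)
        n = 2000
        df = pd.DataFrame({
            "pfs_time": rng.exponential(500.0, n),
            "pfs_event": rng.random(n) < 0.7,
            "x": rng.normal(60.0, 15.0, n),
        })
        res = cox_univariable(df, "x", unit_scale=10.0)
        assert 0.9 < res.hr < 1.1

    def test_ci_ordering_invariant(self):
        res = cox_univariable(self.toy_data(), "x", ci_level=0.90)
        assert 0 < res.ci_low <= res.hr <= res.ci_high

    def test_time_scale_invariance(self):
        df = self.toy_data()
        a = cox_univariable(df, "x")
        df2 = df.assign(pfs_time=df.pfs_time * 365.25)
        b = cox_univariable(df2, "x")
        assert a.beta == pytest.approx(b.beta, rel=1e-6)

    def test_constant_exposure_rejected(self):
        df = self.toy_data().assign(x=1.0)
        with pytest.raises(ValueError, match="constant"):
            cox_univariable(df, "x")

    def test_too_few_events_rejected(self):
        df = self.toy_data().assign(pfs_event=[True] + [False] * 5)
        with pytest.raises(ValueError, match="events"):
            cox_univariable(df, "x")


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        curve = km_curve([5.0, 8.0, 10.0], [False, False, False])
        assert curve.at(9.0) == 1.0

    def test_all_events_distinct_times(self):
        curve = km_curve([1.0, 2.0, 3.0, 4.0], [True] * 4)
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])

    def test_mixed_censoring_matches_hand_calculation(self):
        times = [1.0, 2.0, 2.0, 3.0, 4.0]
        events = [True, True, False, True, False]
        curve = km_curve(times, events)
        for t, s in km_hand(times, events):
            assert curve.at(t) == pytest.approx(s, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])


class TestRmst:
    @staticmethod
    def two_group_frame():
        return pd.DataFrame({
            "pfs_time": [2.0, 4.0, 6.0, 9.0, 3.0, 5.0, 7.0, 10.0],
            "pfs_event": [True, True, False, True] * 2,
            "g": ["a"] * 4 + ["b"] * 4,
        })

    def test_no_events_rmst_equals_tau(self):
        df = pd.DataFrame({
            "pfs_time": [10.0, 12.0, 9.0, 11.0],
            "pfs_event": [False] * 4,
            "g": ["a", "a", "b", "b"],
        })
        out = rmst_difference(df, "g", tau=8.0)
        assert out["rmst_a"] == pytest.approx(8.0)
        assert out["diff"] == pytest.approx(0.0)

    def test_identical_groups_zero_difference(self):
        out = rmst_difference(self.two_group_frame().assign(
            pfs_time=[2, 4, 6, 9] * 2, pfs_event=[True, True, False, True] * 2),
            "g", tau=8.0)
        assert out["diff"] == pytest.approx(0.0)

    def test_matches_step_integration_oracle(self):
        df = self.two_group_frame()
        tau = 8.0
        out = rmst_difference(df, "g", tau=tau)
        for key, g in (("rmst_a", "a"), ("rmst_b", "b")):
            sub = df[df.g == g]
            assert out[key] == pytest.approx(
                rmst_step_integral(sub.pfs_time, sub.pfs_event, tau),
                rel=1e-9)

    def test_tau_beyond_followup_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            rmst_difference(self.two_group_frame(), "g", tau=50.0)


class TestDichotomized:
    def test_median_split_balanced(self):
        rng = np.random.default_rng(55)
        n = 101
        df = pd.DataFrame({
            "pfs_time": rng.exponential(300.0, n),
            "pfs_event": rng.random(n) < 0.8,
            "x": rng.permutation(np.linspace(10, 100, n)),
        })
        res = dichotomized_analysis(df, "x", cut="median")
        assert res.n == n
        above = (df.x >= np.quantile(df.x, 0.5)).sum()
        assert abs(above - (n - above)) <= 1

    def test_recovers_generating_hazard_ratio(self):
        """Two-group exponential simulation with true HR = 2."""
        rng = np.random.default_rng(77)
        n = 1000
        group = rng.random(n) < 0.5
        lam = np.where(group, 2.0 / 300.0, 1.0 / 300.0)
        t = rng.exponential(1.0 / lam)
        c = rng.exponential(600.0, n)
        df = pd.DataFrame({
            "pfs_time": np.minimum(t, c),
            "pfs_event": t <= c,
            # exposure encodes the group with distinct values so the median
            # split reproduces the group structure
            "x": np.where(group, 80.0, 40.0) + rng.uniform(0, 1, n),
        })
        res = dichotomized_analysis(df, "x", cut="median")
        assert res.hr == pytest.approx(2.0, rel=0.15)

    def test_null_ci_coverage(self):
        """Identical survival in both strata: the 90% CI should cover
        HR = 1 in at least 85% of 100 seeded replicates."""
        rng = np.random.default_rng(88)
        covered = 0
        for _ in range(100):
            n = 120
            df = pd.DataFrame({
                "pfs_time": rng.exponential(300.0, n),
                "pfs_event": rng.random(n) < 0.8,
                "x": rng.uniform(20, 100, n),
            })
            res = dichotomized_analysis(df, "x", cut="median",
                                        ci_level=0.90)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 85

    def test_bad_cut_rejected(self):
        with pytest.raises(ValueError):
            dichotomized_analysis(TestCoxUnivariable.toy_data(), "x",
                                  cut="q3")


class TestQuartileEventTable:
    def test_counts_by_quartile(self):
        q = [1, 1, 2, 2, 3, 3, 4, 4, None]
        flags = [True, False, True, True, False, False, True, True, True]
        table = quartile_event_table(q, flags)
        assert table.events == (1, 2, 0, 2)
        assert table.totals == (2, 2, 2, 2)

    def test_outcome_record_validation(self):
        with pytest.raises(ValueError):
            OutcomeRecord("s", "third", 10.0, True)
        with pytest.raises(ValueError):
            OutcomeRecord("s", "first", -1.0, True)
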