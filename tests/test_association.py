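"""Correlations, group comparisons, Kaplan-Meier splits and the log-rank oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bulktime as bt
from bulktime.association import survival_split_at


def hand_logrank(time_a, event_a, time_b, event_b):
    """Independent log-rank enumeration over event times (oracle).

    At each distinct event time: O = observed events in group A,
    E = n_a * d / n, V = hypergeometric variance; the statistic is
    (sum O - sum E)^2 / sum V.
    """
    times = np.concatenate([time_a, time_b])
    events = np.concatenate([event_a, event_b])
    in_a = np.concatenate([np.ones(len(time_a), bool), np.zeros(len(time_b), bool)])
    O = E = V = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & in_a).sum()
        O += d_a
        E += n_a * d / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V if V > 0 else 0.0


class TestCorrelate:
    def test_linear_gives_r_one(self):
        z = np.linspace(-2, 2, 30)
        res = bt.correlate(2 * z + 1, z, method="pearson")
        assert res.r == pytest.approx(1.0)

    def test_monotone_nonlinearity(self):
        z = np.linspace(-2, 2, 50)
        y = np.exp(z)
        assert bt.correlate(y, z, method="spearman").r == pytest.approx(1.0)
        assert bt.correlate(y, z, method="pearson").r < 1.0

    def test_bivariate_normal_mean_estimate(self):
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(500):
            u = rng.standard_normal(100)
            v = 0.5 * u + np.sqrt(1 - 0.25) * rng.standard_normal(100)
            rs.append(stats.pearsonr(u, v)[0])
        assert 0.45 < np.mean(rs) < 0.55

    def test_missing_pairs_dropped(self):
        z = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        y = np.array([2.0, 4.0, np.nan, 8.0, 10.0])
        res = bt.correlate(y, z)
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            bt.correlate(np.ones(10), np.arange(10.0))


class TestBonferroni:
    def test_elementwise_formula(self):
        np.testing.assert_allclose(bt.adjust_bonferroni([0.01] * 5), [0.05] * 5)
        np.testing.assert_allclose(bt.adjust_bonferroni([0.5] * 10), [1.0] * 10)
        np.testing.assert_allclose(bt.adjust_bonferroni([0.3]), [0.3])

    def test_adjusted_significance_never_exceeds_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        adj = bt.adjust_bonferroni(p)
        assert (adj < 0.05).sum() <= (p < 0.05).sum()

    def test_correlate_table_adjusts_across_rows(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=60)
        tab = pd.DataFrame(
            rng.normal(size=(4, 60)),
            index=[f"v{j}" for j in range(4)],
            columns=[f"s{i}" for i in range(60)],
        )
        res = bt.correlate_table(tab, z)
        np.testing.assert_allclose(
            res["p_bonferroni"], np.minimum(1.0, 4 * res["p_value"])
        )


class TestCompareGroups:
    def test_identical_groups(self):
        z = np.concatenate([np.arange(5.0), np.arange(5.0)])
        labels = ["a"] * 5 + ["b"] * 5
        stat, p, _ = bt.compare_groups(z, labels, test="ttest")
        assert stat == 0.0
        assert p == 1.0

    def test_power_for_unit_shift(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(200):
            a = rng.standard_normal(100)
            b = rng.standard_normal(100) + 1.0
            _, p, _ = bt.compare_groups(
                np.concatenate([a, b]), ["a"] * 100 + ["b"] * 100, test="ttest"
            )
            hits += p < 0.05
        assert hits / 200 >= 0.99

    @pytest.mark.parametrize("test", ["ttest", "wilcoxon"])
    def test_pairwise_tests_reject_three_groups(self, test):
        z = np.arange(9.0)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        with pytest.raises(ValueError, match="exactly 2"):
            bt.compare_groups(z, labels, test=test)

    @pytest.mark.parametrize("test", ["anova", "kruskal"])
    def test_multigroup_tests_run(self, test):
        rng = np.random.default_rng(4)
        z = np.concatenate([rng.normal(m, 1, 30) for m in (0, 1, 2)])
        labels = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
        stat, p, summary = bt.compare_groups(z, labels, test=test)
        assert p < 0.01
        assert list(summary["group"]) == ["a", "b", "c"]

    def test_missing_labels_dropped(self):
        z = np.arange(10.0)
        labels = ["a"] * 4 + ["b"] * 4 + [None, None]
        _, _, summary = bt.compare_groups(z, labels, test="ttest")
        assert summary["n"].sum() == 8


class TestSurvival:
    def test_km_without_censoring_is_empirical_survivor(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(100, size=40)
        z = rng.normal(size=40)
        split = survival_split_at(z, t, np.ones(40), cutoff=float(np.median(z)))
        for cur, grp_t in [
            (split.curves["early"], t[z <= np.median(z)]),
            (split.curves["late"], t[z > np.median(z)]),
        ]:
            for _, row in cur.iterrows():
                emp = np.mean(grp_t > row["time"])
                assert row["survival"] == pytest.approx(emp, abs=1e-12)

    def test_six_subject_logrank_matches_enumeration(self):
        t = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        e = np.ones(6)
        z = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0])
        split = survival_split_at(z, t, e, cutoff=0.0)
        oracle = hand_logrank(t[:3], e[:3], t[3:], e[3:])
        assert split.statistic == pytest.approx(oracle, rel=1e-9)

    def test_logrank_invariances(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(50, 30)
        e = (rng.random(30) < 0.8).astype(float)
        z = rng.normal(size=30)
        s1 = survival_split_at(z, t, e, 0.0)
        s2 = survival_split_at(-z, t, e, -1e-12)  # relabel groups
        assert s1.statistic == pytest.approx(s2.statistic, rel=1e-9)
        s3 = survival_split_at(z, t + 1000.0, e, 0.0)  # shift all times
        assert s1.statistic == pytest.approx(s3.statistic, rel=1e-9)

    def test_cutoff_split_detects_hazard_gradient(self, cohort_a):
        _, clin, truth = cohort_a
        split = bt.km_split(
            truth.z_true, clin.table["surv_time"], clin.table["surv_event"]
        )
        assert split.p_value < 0.05
        # the high-pseudotime group must fare worse
        early, late = split.curves["early"], split.curves["late"]
        horizon = min(early["time"].max(), late["time"].max())
        s_e = early[early["time"] <= horizon]["survival"].iloc[-1]
        s_l = late[late["time"] <= horizon]["survival"].iloc[-1]
        assert s_l < s_e
        assert "anti-conservative" in split.annotation

    def test_requires_events_and_size(self):
        z = np.arange(30.0)
        t = np.ones(30)
        with pytest.raises(ValueError, match="events"):
            bt.km_split(z, t, np.zeros(30))
        with pytest.raises(ValueError, match="20 samples"):
            bt.km_split(z[:5], t[:5], np.ones(5))
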