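"""Survival, ROC and clinical-formula statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sig2screen import outcomes, simulate


class TestZscore:
    def test_hand_example(self):
        vals = pd.DataFrame({"g": [1.0, 2.0, 3.0]})
        z = outcomes.zscore_signature(vals, ["g"])
        np.testing.assert_allclose(z, [-1, 0, 1])

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(5, 2, size=(20, 3)), columns=["a", "b", "c"])
        z1 = outcomes.zscore_signature(vals, ["a", "b"])
        z2 = outcomes.zscore_signature(vals + 10, ["a", "b"])
        np.testing.assert_allclose(z1, z2)

    def test_constant_gene_dropped_all_constant_errors(self):
        vals = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="flat"):
            z = outcomes.zscore_signature(vals, ["flat", "ok"])
        np.testing.assert_allclose(z, [-1, 0, 1])
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                outcomes.zscore_signature(vals, ["flat"])


class TestROC:
    def test_perfect_separation(self):
        assert outcomes.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]).auc == 1.0

    def test_all_ties_half(self):
        assert outcomes.roc_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == 0.5

    def test_four_point_example(self):
        """3 of 4 class-pairs concordant: AUC = 0.75 by enumeration."""
        res = outcomes.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)
        assert res.tpr[0] == 0 and res.tpr[-1] == 1

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_negation_symmetry_and_u_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = rng.normal(0, 1, n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a1 = outcomes.roc_auc(scores, labels).auc
        a2 = outcomes.roc_auc(-scores, labels).auc
        assert a1 + a2 == pytest.approx(1.0)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert a1 == pytest.approx(u / ((labels == 1).sum() * (labels == 0).sum()))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            outcomes.roc_auc([1, 2], [1, 1])


class TestKM:
    def test_no_events_flat(self):
        t = pd.DataFrame({"time": [1, 2, 3], "event": [0, 0, 0], "group": "a"})
        curve = outcomes.km_estimate(t)["a"]
        assert len(curve.times) == 0

    def test_three_event_toy(self):
        t = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 1], "group": "a"})
        curve = outcomes.km_estimate(t)["a"]
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_moving_censor_time_past_last_event_leaves_curve_unchanged(self):
        """A subject censored after the last event contributes the same risk
        sets wherever its censor time lies beyond that event."""
        t1 = pd.DataFrame({"time": [1, 2, 3, 3.5], "event": [1, 1, 1, 0], "group": "a"})
        t2 = pd.DataFrame({"time": [1, 2, 3, 9.0], "event": [1, 1, 1, 0], "group": "a"})
        np.testing.assert_allclose(
            outcomes.km_estimate(t1)["a"].survival, outcomes.km_estimate(t2)["a"].survival
        )

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(5, 40)
        t = pd.DataFrame({"time": times, "event": 1, "group": "a"})
        curve = outcomes.km_estimate(t)["a"]
        emp = [(times > et).mean() for et in curve.times]
        np.testing.assert_allclose(curve.survival, emp, atol=1e-12)


def brute_force_logrank(time, event, is_a):
    """Term-by-term hypergeometric oracle over pooled event times."""
    time, event, is_a = map(np.asarray, (time, event, is_a))
    o_e, v = 0.0, 0.0
    for t in sorted(set(time[event == 1])):
        at = time >= t
        n, na = at.sum(), (at & is_a).sum()
        d = ((time == t) & (event == 1)).sum()
        da = ((time == t) & (event == 1) & is_a).sum()
        o_e += da - d * na / n
        if n > 1:
            v += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return (o_e**2 / v, stats.chi2.sf(o_e**2 / v, 1)) if v > 0 else (0.0, 1.0)


class TestLogrank:
    def test_identical_groups_null(self):
        base = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 0, 1]})
        t = pd.concat(
            [base.assign(group="a"), base.assign(group="b")], ignore_index=True
        )
        res = outcomes.logrank(t)
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_hand_computable_toy(self):
        """Group A events at {1,2}, group B at {3,4}: matches the term-by-term oracle."""
        t = pd.DataFrame(
            {"time": [1, 2, 3, 4], "event": [1, 1, 1, 1], "group": ["a", "a", "b", "b"]}
        )
        res = outcomes.logrank(t)
        chi2, p = brute_force_logrank(t["time"], t["event"], t["group"] == "a")
        assert res["chi2"] == pytest.approx(chi2)
        assert res["p_value"] == pytest.approx(p)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_small_tables_match_oracle(self, seed):
        """Random tables with <= 8 subjects (ties and censoring) match the oracle."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        t = pd.DataFrame(
            {
                "time": rng.integers(1, 5, n).astype(float),
                "event": rng.integers(0, 2, n),
                "group": rng.choice(["a", "b"], n),
            }
        )
        if t["group"].nunique() < 2 or t["event"].sum() == 0:
            return
        res = outcomes.logrank(t)
        chi2, p = brute_force_logrank(t["time"], t["event"], (t["group"] == "a").to_numpy())
        assert res["chi2"] == pytest.approx(chi2)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        table, _ = simulate.gen_survival(120, 1.8, seed=7)
        res = outcomes.logrank(table)
        a = table[table["group"] == "high"]
        b = table[table["group"] == "low"]
        ll = logrank_test(a["time"], b["time"], event_observed_A=a["event"],
                          event_observed_B=b["event"])
        assert res["chi2"] == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res["p_value"] == pytest.approx(ll.p_value, rel=1e-9)

    def test_zero_events_rejected(self):
        t = pd.DataFrame({"time": [1, 2], "event": [0, 0], "group": ["a", "b"]})
        with pytest.raises(ValueError, match="events"):
            outcomes.logrank(t)


class TestBestCutoff:
    def test_recovers_separating_cutoff(self):
        table, _ = simulate.gen_survival(120, 3.0, seed=9, score_gap=3.0)
        res = outcomes.best_cutoff(table)
        assert -1.0 < res["cutoff"] < 1.0  # inside the gap between score modes
        assert res["optimized_p"] is True

    def test_null_data_overrejects_without_adjustment(self):
        """Minimized p is anti-conservative under the null, hence the flag."""
        hits = 0
        for i in range(40):
            table, _ = simulate.gen_survival(60, 1.0, seed=100 + i, score_gap=0.0)
            table["score"] = np.random.default_rng(i).normal(size=len(table))
            res = outcomes.best_cutoff(table)
            if res["p_at_cutoff"] < 0.05:
                hits += 1
        assert hits / 40 > 0.05

    def test_permutation_p_attached(self):
        table, _ = simulate.gen_survival(60, 2.5, seed=11)
        res = outcomes.best_cutoff(table, n_permutations=20, seed=0)
        assert 0 < res["permutation_p"] <= 1

    def test_subject_order_invariance(self):
        table, _ = simulate.gen_survival(80, 2.0, seed=12)
        res1 = outcomes.best_cutoff(table)
        res2 = outcomes.best_cutoff(table.sample(frac=1, random_state=1))
        assert res1["cutoff"] == res2["cutoff"]
        assert res1["p_at_cutoff"] == pytest.approx(res2["p_at_cutoff"])

    def test_constant_scores_rejected(self):
        table, _ = simulate.gen_survival(30, 1.0, seed=13)
        table["score"] = 1.0
        with pytest.raises(ValueError, match="candidate"):
            outcomes.best_cutoff(table)


class TestClinicalFormulas:
    @pytest.mark.parametrize(
        "fractions,expected",
        [([0, 0, 0, 100], 300.0), ([40, 30, 20, 10], 100.0), ([100, 0, 0, 0], 0.0)],
    )
    def test_h_score(self, fractions, expected):
        assert outcomes.h_score(fractions) == expected

    def test_h_score_must_sum_to_100(self):
        with pytest.raises(ValueError, match="sum"):
            outcomes.h_score([50, 10, 10, 10])

    def test_tumor_volume(self):
        assert outcomes.tumor_volume(5, 10) == 125.0
        assert outcomes.tumor_volume(4, 4) == 32.0  # L^3/2 at width = length

    def test_tumor_volume_swaps_with_warning(self):
        with pytest.warns(UserWarning, match="swap"):
            assert outcomes.tumor_volume(10, 5) == 125.0

    def test_tumor_volume_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            outcomes.tumor_volume(0, 5)
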