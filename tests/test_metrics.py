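"""Evaluation metrics against independent oracles: all-pairs AUC, hand
product-limit computations, and O/E/V log-rank tabulation."""

import numpy as np
import pytest

from pathomil.metrics import (
    UndefinedMetricError,
    dichotomize,
    horizon_auc,
    km_estimate,
    logrank,
    roc_auc,
)


def all_pairs_auc(scores, labels):
    """Oracle: Mann-Whitney over every (positive, negative) pair, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == 1.0

    def test_hand_case(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]).auc == pytest.approx(0.75)

    def test_all_ties_half(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        assert roc_auc(np.exp(s), y).auc == pytest.approx(roc_auc(s, y).auc)

    def test_matches_all_pairs_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = int(rng.integers(4, 41))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.normal(size=n), 1)  # rounding forces score ties
            assert roc_auc(s, y).auc == pytest.approx(all_pairs_auc(s, y), abs=1e-12)


class TestHorizonAuc:
    def test_perfectly_ordered_risk(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        risks = -times  # shorter survival = higher risk
        events = np.ones(6)
        for horizon in (2.5, 3.5, 4.5):
            assert horizon_auc(risks, times, events, horizon) == 1.0

    def test_one_case_one_control(self):
        assert horizon_auc([2.0, 1.0], [1.0, 9.0], [1, 0], 5.0) == 1.0

    def test_censored_before_horizon_excluded(self):
        # subject 2 censored at t=3 < horizon: retained set is the other five
        risks = np.array([3.0, 2.5, 9.9, 2.0, 1.0, 0.5])
        times = np.array([2.0, 4.0, 3.0, 8.0, 9.0, 10.0])
        events = np.array([1, 1, 0, 0, 1, 0])
        keep = np.array([0, 1, 3, 4, 5])
        cases = (events[keep] == 1) & (times[keep] <= 6.0)
        expected = all_pairs_auc(risks[keep], cases.astype(float))
        assert horizon_auc(risks, times, events, 6.0) == pytest.approx(expected)

    def test_no_cases_rejected(self):
        with pytest.raises(UndefinedMetricError):
            horizon_auc([1.0, 2.0], [9.0, 8.0], [1, 1], 5.0)


class TestDichotomize:
    def test_even_split_on_train_set(self):
        groups = dichotomize([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert (groups == "high").sum() == 2
        assert (groups == "low").sum() == 2

    def test_ties_go_low(self):
        assert list(dichotomize([1.0, 1.0, 1.0], [1.0, 1.0])) == ["low", "low"]

    def test_hand_case(self):
        assert list(dichotomize([1.0, 2.0, 3.0], [0.0, 2.5])) == ["low", "high"]


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.times.size == 0

    def test_two_events_hand_case(self):
        curve = km_estimate([1.0, 2.0], [1, 1])
        assert np.allclose(curve.times, [1.0, 2.0])
        assert np.allclose(curve.survival, [0.5, 0.0])
        assert np.array_equal(curve.at_risk, [2, 1])

    def test_censor_shrinks_risk_set_without_step(self):
        curve = km_estimate([1.0, 2.0], [0, 1])
        assert np.allclose(curve.times, [2.0])
        assert np.allclose(curve.survival, [0.0])

    def test_all_events_untied_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(size=25) + 0.01
        curve = km_estimate(times, np.ones(25))
        sorted_t = np.sort(times)
        for t, s in zip(curve.times, curve.survival):
            ecdf = (sorted_t <= t).mean()
            assert s == pytest.approx(1.0 - ecdf, abs=1e-12)

    def test_survival_nonincreasing(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(size=40) + 0.01
        e = rng.integers(0, 2, size=40)
        curve = km_estimate(t, e)
        assert np.all(np.diff(curve.survival) <= 1e-12)


def logrank_oracle(times, events, groups):
    """Oracle: per-event-time O/E/V tabulation of the two-sample statistic."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    in_a = np.asarray(groups) == np.asarray(groups)[np.argsort(np.asarray(groups))[0]]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & in_a).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_chi_square_zero(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 0, 1, 1, 0]
        groups = ["a", "a", "a", "b", "b", "b"]
        chi2, p = logrank(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_four_subject_hand_tabulation(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        groups = ["A", "A", "B", "B"]
        chi2, _ = logrank(times, events, groups)
        assert chi2 == pytest.approx(logrank_oracle(times, events, groups), rel=1e-9)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(6, 30))
            times = rng.exponential(size=n) + 0.01
            events = rng.integers(0, 2, size=n)
            groups = rng.integers(0, 2, size=n)
            if events.sum() == 0 or len(np.unique(groups)) < 2:
                continue
            chi2, _ = logrank(times, events, groups)
            assert chi2 == pytest.approx(logrank_oracle(times, events, groups), rel=1e-8)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(12)
        times = rng.exponential(size=20) + 0.01
        events = rng.integers(0, 2, size=20)
        events[:2] = 1
        groups = rng.integers(0, 2, size=20)
        groups[:2] = [0, 1]
        chi2_a, _ = logrank(times, events, groups)
        chi2_b, _ = logrank(times, events, 1 - groups)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(UndefinedMetricError):
            logrank([1.0, 2.0], [0, 0], ["a", "b"])
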