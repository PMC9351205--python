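import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lunggraph import evaluation as ev


class TestStratifiedSplit:
    def test_reference_cohort_sizes(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(1705) < 0.218).astype(int)
        split = ev.stratified_split(labels, seed=1)
        assert split.sizes == (1278, 213, 214)

    def test_small_balanced_cohort_keeps_classes_in_train(self):
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        for seed in range(20):
            split = ev.stratified_split(labels, seed=seed)
            train_labels = labels[np.asarray(split.train)]
            assert set(train_labels) == {0, 1}

    def test_all_train_ratios(self):
        labels = np.array([0, 1] * 5)
        split = ev.stratified_split(labels, ratios=(1.0, 0.0, 0.0), seed=0)
        assert split.sizes == (10, 0, 0)

    def test_bad_ratio_sum(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ev.stratified_split(np.array([0, 1] * 5), ratios=(0.5, 0.2, 0.2))

    def test_disjoint_and_complete(self):
        rng = np.random.default_rng(3)
        labels = (rng.random(200) < 0.3).astype(int)
        split = ev.stratified_split(labels, seed=5)
        all_ids = split.train + split.val + split.test
        assert sorted(all_ids) == list(range(200))

    def test_label_rates_within_two_points(self):
        rng = np.random.default_rng(4)
        labels = (rng.random(400) < 0.25).astype(int)
        overall = labels.mean()
        split = ev.stratified_split(labels, seed=2)
        for part in (split.train, split.val, split.test):
            rate = labels[np.asarray(part)].mean()
            assert abs(rate - overall) < 0.02

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            ev.stratified_split(np.array([0] * 10 + [1]))

    def test_custom_ids(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        ids = np.array(["a", "b", "c", "d", "e", "f"])
        split = ev.stratified_split(labels, seed=0, ids=ids)
        assert sorted(split.train + split.val + split.test) == sorted(ids)


def _brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert ev.auc_point([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores(self):
        assert ev.auc_point([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.auc_point([0.1, 0.2], [1, 1])

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=25, deadline=None)
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert ev.auc_point(scores, labels) == pytest.approx(
            _brute_force_auc(scores, labels)
        )

    def test_ci_contains_point_and_is_ordered(self):
        rng = np.random.default_rng(0)
        scores = rng.random(80)
        labels = (scores + rng.normal(0, 0.3, 80) > 0.5).astype(int)
        res = ev.roc_auc(scores, labels, n_bootstrap=200, seed=0)
        assert res.ci_low <= res.auc <= res.ci_high

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        assert ev.auc_point(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores)
        )


class TestF2Score:
    def test_perfect(self):
        assert ev.f2_score([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0

    def test_half_precision_full_recall(self):
        # P = 0.5, R = 1.0 -> 5 * 0.5 * 1 / (4 * 0.5 + 1) = 0.8333...
        scores = [0.9, 0.9, 0.9, 0.9]
        labels = [1, 1, 0, 0]
        assert ev.f2_score(scores, labels) == pytest.approx(5 * 0.5 / 3.0)

    def test_no_predicted_positives(self):
        assert ev.f2_score([0.1, 0.2], [1, 0]) == 0.0

    def test_matches_sklearn(self):
        from sklearn.metrics import fbeta_score

        rng = np.random.default_rng(2)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        ours = ev.f2_score(scores, labels, threshold=0.5)
        ref = fbeta_score(labels, scores >= 0.5, beta=2, zero_division=0)
        assert ours == pytest.approx(ref)


class TestStratifyRisk:
    def test_even_split_distinct_scores(self):
        groups = ev.stratify_risk(np.arange(10) / 10)
        assert groups.sum() == 5

    def test_all_equal_warns_all_low(self):
        with pytest.warns(UserWarning, match="low-risk"):
            groups = ev.stratify_risk(np.full(6, 0.3))
        assert groups.sum() == 0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.random(31)
        assert np.array_equal(
            ev.stratify_risk(scores), ev.stratify_risk(np.exp(3 * scores))
        )


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        records = ev.records_from_arrays([5, 10, 15], [0, 0, 0])
        est = ev.kaplan_meier(records)
        assert est.times.size == 0
        assert est.evaluate(20.0) == 1.0

    def test_all_events_equals_empirical_survivor(self):
        times = [2.0, 4.0, 6.0, 8.0]
        est = ev.kaplan_meier(ev.records_from_arrays(times, [1, 1, 1, 1]))
        for t in times:
            empirical = np.mean(np.asarray(times) > t)
            assert est.evaluate(t) == pytest.approx(empirical)

    def test_six_record_hand_computed(self):
        # (time, event): (1,1),(2,0),(3,1),(4,1),(5,0),(6,1)
        # S(1)=5/6, S(3)=5/6*3/4=0.625, S(4)=0.625*2/3, S(6)=0
        records = ev.records_from_arrays([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        est = ev.kaplan_meier(records)
        assert est.times.tolist() == [1, 3, 4, 6]
        assert est.survival == pytest.approx([5 / 6, 0.625, 0.625 * 2 / 3, 0.0])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(5)
        times = rng.exponential(10, 40)
        events = rng.integers(0, 2, 40)
        est = ev.kaplan_meier(ev.records_from_arrays(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        for t in est.times:
            assert est.evaluate(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0])
            )

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=20, deadline=None)
    def test_no_censoring_equals_one_minus_ecdf(self, seed):
        rng = np.random.default_rng(seed)
        times = rng.integers(1, 20, size=15).astype(float)
        est = ev.kaplan_meier(ev.records_from_arrays(times, [1] * 15))
        for t in np.unique(times):
            assert est.evaluate(t) == pytest.approx(np.mean(times > t))


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        times = [3.0, 5.0, 7.0, 9.0]
        events = [1, 0, 1, 1]
        records = ev.records_from_arrays(times + times, events + events)
        groups = [0] * 4 + [1] * 4
        chi2, p = ev.log_rank(groups, records)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_one_empty_group(self):
        records = ev.records_from_arrays([1, 2, 3], [1, 1, 0])
        with pytest.raises(ValueError, match="two nonempty"):
            ev.log_rank([0, 0, 0], records)

    def test_power_with_planted_hr3(self):
        hits = 0
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = 150
            t0 = rng.exponential(1 / 0.01, n)
            t1 = rng.exponential(1 / 0.03, n)
            times = np.concatenate([t0, t1])
            events = (times <= 80).astype(int)
            times = np.minimum(times, 80)
            groups = np.array([0] * n + [1] * n)
            _, p = ev.log_rank(groups, ev.records_from_arrays(times, events))
            hits += p < 0.01
        assert hits >= 95

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(9)
        times = rng.exponential(10, 60)
        events = rng.integers(0, 2, 60)
        groups = rng.integers(0, 2, 60)
        groups[:2] = [0, 1]
        chi2, p = ev.log_rank(groups, ev.records_from_arrays(times, events))
        ref = logrank_test(
            times[groups == 0], times[groups == 1],
            events[groups == 0], events[groups == 1],
        )
        assert chi2 == pytest.approx(ref.test_statistic)
        assert p == pytest.approx(ref.p_value)


class TestCoxHr:
    def test_four_record_manual_derivatives(self):
        # records (t, e, x): (1,1,1),(2,1,0),(3,0,1),(4,1,0); at beta = 0:
        # U = 1/6, I = 17/36, first Newton step -> beta = 6/17
        x = np.array([1.0, 0.0, 1.0, 0.0])
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 0, 1])
        ll, u, i = ev.cox_score_info(0.0, x, times, events)
        assert u == pytest.approx(1 / 6)
        assert i == pytest.approx(17 / 36)
        assert ll == pytest.approx(-np.log(4) - np.log(3))
        fit = ev.cox_hr(x.astype(int), ev.records_from_arrays(times, events))
        assert fit.history[1][0] == pytest.approx(6 / 17)

    def test_recovers_true_hr2(self):
        rng = np.random.default_rng(2)
        n = 500
        t0 = rng.exponential(1 / 0.01, n)
        t1 = rng.exponential(1 / 0.02, n)
        times = np.concatenate([t0, t1])
        events = (times <= 100).astype(int)
        times = np.minimum(times, 100)
        x = np.array([0] * n + [1] * n)
        fit = ev.cox_hr(x, ev.records_from_arrays(times, events))
        assert 1.7 <= fit.hazard_ratio <= 2.4
        assert fit.ci_low < fit.hazard_ratio < fit.ci_high

    def test_null_ci_covers_one(self):
        rng = np.random.default_rng(1)
        covered = 0
        for _ in range(50):
            n = 100
            times = rng.exponential(50, 2 * n)
            events = (times <= 80).astype(int)
            times = np.minimum(times, 80)
            x = np.array([0] * n + [1] * n)
            fit = ev.cox_hr(x, ev.records_from_arrays(times, events))
            covered += fit.ci_low <= 1.0 <= fit.ci_high
        assert covered >= 45

    def test_no_events_in_group_rejected(self):
        records = ev.records_from_arrays([1, 2, 3, 4], [1, 1, 0, 0])
        with pytest.raises(ValueError, match="no events"):
            ev.cox_hr([0, 0, 1, 1], records)

    def test_matches_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 80
        x = rng.integers(0, 2, n)
        times = rng.exponential(30 / (1 + x), n)
        events = (times <= 40).astype(int)
        times = np.minimum(times, 40)
        events[x == 0] = np.maximum(events[x == 0], [1] + [0] * (int((x == 0).sum()) - 1))
        fit = ev.cox_hr(x, ev.records_from_arrays(times, events))
        df = pd.DataFrame({"t": times, "e": events, "x": x})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert fit.beta == pytest.approx(float(ref.params_["x"]), abs=1e-5)
        assert fit.se == pytest.approx(float(ref.standard_errors_["x"]), abs=1e-5)


class TestWilcoxon:
    def test_shifted_samples_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 100)
        b = rng.normal(1, 1, 100)
        _, p = ev.wilcoxon_rank_sum(a, b)
        assert p < 0.001


class TestClassifierMetrics:
    def test_all_fields_in_unit_interval(self):
        rng = np.random.default_rng(0)
        scores = rng.random(60)
        labels = (scores + rng.normal(0, 0.4, 60) > 0.5).astype(int)
        m = ev.classifier_metrics(scores, labels, n_bootstrap=100)
        for v in [m.auc, m.sensitivity, m.specificity, m.precision, m.f2]:
            assert 0.0 <= v <= 1.0
        assert m.auc_ci[0] <= m.auc <= m.auc_ci[1]
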