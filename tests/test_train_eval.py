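"""Splits, metrics, cross-validation, baselines, correlation analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression

from iopscreen.train_eval import (
    EarlyStopping,
    compute_metrics,
    crossval_5fold,
    dropout_schedule,
    fit_baselines,
    pearson_corr,
    split_dataset,
    total_loss,
)


class TestLossAndSchedule:
    def test_l1_term_examples(self):
        assert total_loss(1.0, [np.array([1.0, -2.0, 3.0])], 0.5) == 4.0
        assert total_loss(2.5, [np.zeros(7)], 0.9) == 2.5
        assert total_loss(2.5, [np.ones(4)], 0.0) == 2.5

    def test_dropout_decay(self):
        assert dropout_schedule(0.5, 0.1, 0) == 0.5
        assert dropout_schedule(0.5, 0.1, 10) == pytest.approx(0.25)
        assert dropout_schedule(0.3, 0.0, 99) == 0.3
        ts = np.arange(20)
        ps = [dropout_schedule(0.5, 0.2, t) for t in ts]
        assert np.all(np.diff(ps) < 0)

    def test_early_stopping_fires_iff_flat_for_patience(self):
        es = EarlyStopping(patience=3)
        decisions = [es.update(v) for v in (0.5, 0.6, 0.6, 0.6, 0.6)]
        assert decisions == [False, False, False, False, True]
        es = EarlyStopping(patience=3)
        # improvement resets the counter
        assert [es.update(v) for v in (0.5, 0.5, 0.5, 0.6, 0.6, 0.6, 0.6)] == [
            False, False, False, False, False, False, True
        ]


class TestSplit:
    def test_unique_patients_hit_exact_ratio_sizes(self):
        labels = np.array(["high"] * 100 + ["normal"] * 680)
        plan = split_dataset(labels, np.arange(780), seed=3)
        assert (len(plan.train), len(plan.val), len(plan.test)) == (624, 78, 78)
        assert plan.class_counts["train"] == {"high": 80, "normal": 544}

    def test_patient_exclusivity_and_partition(self, rng):
        labels = rng.choice(["normal", "high"], size=200, p=[0.85, 0.15])
        pids = rng.integers(0, 90, size=200)
        plan = split_dataset(labels, pids, seed=1)
        parts = [set(plan.train), set(plan.val), set(plan.test)]
        assert sum(len(p) for p in parts) == 200
        assert set().union(*parts) == set(range(200))
        for a, b in ((0, 1), (0, 2), (1, 2)):
            shared = {pids[i] for i in parts[a]} & {pids[i] for i in parts[b]}
            assert shared == set()

    def test_stratification_close_to_global_fraction(self):
        labels = np.array(["high"] * 100 + ["normal"] * 680)
        plan = split_dataset(labels, np.arange(780), seed=8)
        for part in (plan.train, plan.val, plan.test):
            frac = np.mean(labels[part] == "high")
            assert abs(frac * len(part) - 100 / 780 * len(part)) <= 1

    def test_seed_determinism(self, rng):
        labels = rng.choice(["normal", "high"], size=120, p=[0.8, 0.2])
        pids = rng.integers(0, 70, size=120)
        p1 = split_dataset(labels, pids, seed=5)
        p2 = split_dataset(labels, pids, seed=5)
        assert np.array_equal(p1.train, p2.train) and np.array_equal(p1.test, p2.test)

    def test_oversized_patient_group_warns(self):
        labels = np.array(["normal"] * 10)
        pids = np.array([0] * 9 + [1])
        with pytest.warns(UserWarning):
            split_dataset(labels, pids, seed=0)


class TestMetrics:
    def test_perfect_and_null_predictions(self):
        assert compute_metrics([1, 1, 0, 0], [1, 1, 0, 0]).mcc == 1.0
        rep = compute_metrics(np.repeat([1, 1, 0, 0], 25), np.tile([1, 0, 1, 0], 25))
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (25, 25, 25, 25)
        assert rep.mcc == 0.0

    def test_known_confusion_counts(self):
        y_true = np.array([1] * 60 + [0] * 40)
        y_pred = np.concatenate([np.ones(50), np.zeros(10), np.ones(5), np.zeros(35)])
        rep = compute_metrics(y_true, y_pred)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (50, 5, 10, 35)
        assert rep.precision == pytest.approx(50 / 55)
        assert rep.recall == pytest.approx(50 / 60)
        assert rep.specificity == pytest.approx(35 / 40)
        p, r = 50 / 55, 50 / 60
        assert rep.f1 == pytest.approx(2 * p * r / (p + r))
        mcc = (50 * 35 - 5 * 10) / np.sqrt(55 * 60 * 40 * 45)
        assert rep.mcc == pytest.approx(mcc)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 60))
    def test_matches_brute_force_counting_oracle(self, seed, n):
        rng_ = np.random.default_rng(seed)
        y_true = rng_.integers(0, 2, n)
        y_pred = rng_.integers(0, 2, n)
        rep = compute_metrics(y_true, y_pred, positive=1)
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
        tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (tp, tn, fp, fn)
        assert rep.accuracy == (tp + tn) / n

    def test_independent_predictions_have_near_zero_mcc(self):
        rng_ = np.random.default_rng(123)
        y_true = rng_.integers(0, 2, 10000)
        y_pred = rng_.integers(0, 2, 10000)
        assert abs(compute_metrics(y_true, y_pred).mcc) < 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])


class TestCrossValidation:
    def test_folds_partition_data_and_are_deterministic(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.array([0, 1] * 30)
        factory = lambda: LogisticRegression()
        r1 = crossval_5fold(factory, X, y, seed=2)
        r2 = crossval_5fold(factory, X, y, seed=2)
        all_idx = np.sort(np.concatenate(r1.fold_test_indices))
        assert np.array_equal(all_idx, np.arange(60))
        for a, b in zip(r1.fold_test_indices, r2.fold_test_indices):
            assert np.array_equal(a, b)

    def test_median_of_known_values(self):
        from iopscreen.train_eval import CrossValResult, MetricsReport

        reports = [
            MetricsReport(0, 0, 0, 0, acc, 0, 0, 0, 0, 0)
            for acc in (0.6, 0.7, 0.8, 0.9, 1.0)
        ]
        assert CrossValResult(reports, []).median_report["accuracy"] == 0.8

    def test_too_few_samples_per_class_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.array([0] * 6 + [1] * 2)
        with pytest.raises(ValueError, match="stratification"):
            crossval_5fold(lambda: LogisticRegression(), X, y)


class TestBaselines:
    def test_separable_table_classified_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 1, (40, 6)), rng.normal(8, 1, (40, 6))])
        y = np.array([0] * 40 + [1] * 40)
        res = fit_baselines(X, y, seed=0)
        assert set(res) == {"svm", "random_forest", "logistic_regression"}
        for r in res.values():
            assert r.median_report["accuracy"] == 1.0

    def test_label_shuffled_table_gives_null_mcc(self, rng):
        X = rng.normal(size=(2000, 6))
        y = rng.permutation([0, 1] * 1000)
        res = fit_baselines(X, y, seed=1)
        for name, r in res.items():
            assert abs(r.median_report["mcc"]) < 0.1, name

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_baselines(rng.normal(size=(20, 6)), np.zeros(20))


class TestPearson:
    def test_exact_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_corr(x, x) == pytest.approx(1.0)
        assert pearson_corr(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_phantom_cohort_reproduces_configured_targets(self, phantom_config):
        from iopscreen.phantom import sample_clinical

        pairs = sample_clinical(phantom_config, 10000, seed=17)
        thick = [r.pupil_center_thickness for r, _ in pairs]
        depth = [r.anterior_chamber_depth for r, _ in pairs]
        iop = [r.iop for r, _ in pairs]
        assert pearson_corr(thick, iop) == pytest.approx(0.41, abs=0.05)
        assert pearson_corr(depth, iop) == pytest.approx(-0.17, abs=0.05)
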