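"""Resampling design, accuracy curves, per-class metrics, confidence
intervals, predictor-set tiers and fixed-panel evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumortyper.evaluation import (accuracy_curve, ci_halfwidth,
                                   classwise_metrics, evaluate_fixed_panel,
                                   make_split_plan, predictor_set_tiers)
from tumortyper.rankers import FeatureRanking, svm_rfe_rank
from tumortyper.synthetic import SyntheticConfig, generate_dataset
from conftest import dataset_from_array


class TestMakeSplitPlan:
    def test_balanced_toy_holdout(self):
        labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        plan = make_split_plan(labels, holdout_frac=0.25, n_repeats=3,
                               train_frac=0.5, seed=0)
        assert len(plan.holdout) == 2
        assert sorted(labels[plan.holdout]) == [1, 2]

    def test_fifty_repeats_satisfy_invariants(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 5, 120)
        plan = make_split_plan(labels, n_repeats=50, seed=1)
        assert len(plan.repeats) == 50
        plan.validate(len(labels))  # disjointness + coverage assertions

    def test_largest_remainder_rounding_on_imbalanced_dev_set(self):
        # class sizes (7,3), train_frac 4/5: quotas 5.6 and 2.4 -> the
        # spare slot goes to the larger remainder -> train counts (6,2)
        labels = np.array([1] * 7 + [2] * 3)
        plan = make_split_plan(labels, holdout_frac=1e-9, n_repeats=5,
                               train_frac=0.8, seed=3)
        for tr, te in plan.repeats:
            counts = np.bincount(labels[tr], minlength=3)
            assert counts[1] == 6 and counts[2] == 2
            assert len(te) == 2

    def test_stratification_proportional_within_one(self):
        rng = np.random.default_rng(7)
        labels = rng.choice([1, 2, 3, 4], size=200, p=[0.5, 0.3, 0.15, 0.05])
        plan = make_split_plan(labels, seed=2, n_repeats=4)
        for c in (1, 2, 3, 4):
            n_c = int(np.sum(labels == c))
            h_c = int(np.sum(labels[plan.holdout] == c))
            assert abs(h_c - 0.25 * n_c) <= 1

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            make_split_plan(np.array([1, 1, 2]), seed=0)

    def test_deterministic_given_seed(self):
        labels = np.random.default_rng(0).integers(1, 4, 60)
        a = make_split_plan(labels, seed=5, n_repeats=4)
        b = make_split_plan(labels, seed=5, n_repeats=4)
        assert np.array_equal(a.holdout, b.holdout)
        for (t1, e1), (t2, e2) in zip(a.repeats, b.repeats):
            assert np.array_equal(t1, t2) and np.array_equal(e1, e2)


class TestCiHalfwidth:
    def test_identical_values_give_zero(self):
        assert ci_halfwidth([0.5] * 50) == 0.0

    def test_unit_sd_formula(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=50)
        v = (v - v.mean()) / v.std(ddof=1)  # exact sample sd 1
        assert ci_halfwidth(v) == pytest.approx(1.96 / math.sqrt(50), abs=1e-10)

    def test_half_zeros_half_ones(self):
        v = [0.0] * 25 + [1.0] * 25
        sd = np.std(v, ddof=1)
        assert ci_halfwidth(v) == pytest.approx(1.96 * sd / math.sqrt(50), abs=1e-12)
        assert ci_halfwidth(v) == pytest.approx(0.13999, abs=1e-4)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            ci_halfwidth([1.0])


class TestClasswiseMetrics:
    def test_hand_counted_example(self):
        m = classwise_metrics([1, 1, 2], [1, 2, 2])
        assert m.precision[1] == 1.0 and m.recall[1] == 0.5
        assert m.precision[2] == 0.5 and m.recall[2] == 1.0
        assert m.accuracy == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        m = classwise_metrics([1, 2, 3], [1, 2, 3])
        assert all(v == 1.0 for v in m.precision.values())
        assert all(v == 1.0 for v in m.recall.values())
        assert m.accuracy == 1.0

    def test_never_predicted_class_has_undefined_precision(self):
        m = classwise_metrics([1, 2], [1, 1])
        assert m.undefined_precision() == [2]
        assert math.isnan(m.precision[2])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            classwise_metrics([1, 2], [1, 3], classes=[1, 2])

    @given(st.lists(st.tuples(st.integers(1, 6), st.integers(1, 6)),
                    min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_micro_average_identity(self, pairs):
        """Support-weighted recall equals overall accuracy exactly."""
        y_true = [t for t, _ in pairs]
        y_pred = [p for _, p in pairs]
        m = classwise_metrics(y_true, y_pred)
        total = sum(m.support[c] * m.recall[c]
                    for c in m.classes if m.support[c] > 0)
        assert total / len(pairs) == pytest.approx(m.accuracy, abs=1e-12)


class TestAccuracyCurve:
    def _toy(self, seed=0):
        cfg = SyntheticConfig(n_classes=3, samples_per_class=(20,) * 3,
                              informative_per_class=2, n_background_spm=6,
                              n_background_cna=6, p_signal=1.0,
                              p_background=0.0, signal_split=0.5, seed=seed)
        ds, truth = generate_dataset(cfg)
        plan = make_split_plan(ds.labels, n_repeats=5, seed=seed)
        rankings = [svm_rfe_rank(ds.subset_samples(tr)) for tr, _ in plan.repeats]
        return ds, plan, rankings, truth

    def test_full_size_equals_no_selection_accuracy(self):
        ds, plan, rankings, _ = self._toy()
        p = ds.matrix.n_features
        curve = accuracy_curve(rankings, [p], plan, ds)
        full_ids = [f.feature_id for f in ds.matrix.features]
        no_sel = [FeatureRanking(full_ids, [0.0] * p, "none")
                  for _ in plan.repeats]
        ref = accuracy_curve(no_sel, [p], plan, ds)
        assert curve.means[0] == pytest.approx(ref.means[0])

    def test_separable_data_reach_perfect_accuracy_at_planted_size(self):
        ds, plan, rankings, truth = self._toy()
        n = len(truth.all_informative)
        curve = accuracy_curve(rankings, [n], plan, ds)
        assert curve.means[0] == 1.0

    def test_mean_and_ci_match_hand_arithmetic(self):
        ds, plan, rankings, _ = self._toy(seed=3)
        curve = accuracy_curve(rankings, [4], plan, ds)
        per = curve.per_repeat[0]
        assert curve.means[0] == pytest.approx(float(np.mean(per)))
        assert curve.ci_halfwidths[0] == pytest.approx(
            1.96 * np.std(per, ddof=1) / math.sqrt(len(per)))

    def test_oversized_request_truncated_with_warning(self):
        ds, plan, rankings, _ = self._toy()
        with pytest.warns(UserWarning, match="truncated"):
            curve = accuracy_curve(rankings, [10 ** 4], plan, ds)
        assert curve.sizes == [ds.matrix.n_features]


class TestPredictorSetTiers:
    def test_nine_feature_ranking(self):
        r = FeatureRanking(list(range(1, 10)), [0.0] * 9, "toy")
        top, second, third = predictor_set_tiers(r, 3)
        assert (top, second, third) == ([1, 2, 3], [4, 5, 6], [7, 8, 9])

    def test_n_equal_one(self):
        r = FeatureRanking([5, 7, 9], [0.0] * 3, "toy")
        assert predictor_set_tiers(r, 1) == ([5], [7], [9])

    @given(st.integers(1, 10), st.integers(0, 10))
    @settings(max_examples=30, deadline=None)
    def test_tiers_partition_top_3n_prefix(self, n, extra):
        ids = list(range(3 * n + extra))
        r = FeatureRanking(ids, [0.0] * len(ids), "toy")
        top, second, third = predictor_set_tiers(r, n)
        assert not (set(top) & set(second)) and not (set(second) & set(third))
        assert top + second + third == ids[:3 * n]

    def test_short_ranking_rejected(self):
        r = FeatureRanking([1, 2], [0.0, 0.0], "toy")
        with pytest.raises(ValueError):
            predictor_set_tiers(r, 1)


class TestEvaluateFixedPanel:
    def _separable(self):
        cfg = SyntheticConfig(n_classes=3, samples_per_class=(16,) * 3,
                              informative_per_class=2, n_background_spm=4,
                              n_background_cna=4, p_signal=1.0,
                              p_background=0.0, signal_split=0.5, seed=4)
        ds, truth = generate_dataset(cfg)
        plan = make_split_plan(ds.labels, n_repeats=3, seed=4)
        return ds, plan, truth

    def test_full_panel_on_separable_data(self):
        ds, plan, _ = self._separable()
        panel = [f.feature_id for f in ds.matrix.features]
        m = evaluate_fixed_panel(panel, ds, plan)
        assert m.accuracy == 1.0

    def test_uninformative_panel_behaves_like_majority_rule(self):
        # one all-zero feature: the model degenerates to intercepts only
        labels = np.array([1] * 20 + [2] * 8 + [3] * 8)
        X = np.zeros((36, 2), dtype=np.uint8)
        X[:, 1] = np.random.default_rng(0).random(36) < 0.5
        ds = dataset_from_array(X, labels)
        plan = make_split_plan(labels, n_repeats=2, seed=0)
        m = evaluate_fixed_panel([0], ds, plan)
        majority_share = np.mean(labels[plan.holdout] == 1)
        assert m.accuracy == pytest.approx(majority_share)

    def test_class_subset_with_all_classes_is_identity(self):
        ds, plan, _ = self._separable()
        panel = [f.feature_id for f in ds.matrix.features][:8]
        full = evaluate_fixed_panel(panel, ds, plan)
        subset = evaluate_fixed_panel(panel, ds, plan, class_subset=[1, 2, 3])
        assert full.accuracy == subset.accuracy
        assert full.precision == subset.precision

    def test_missing_panel_features_dropped_with_warning(self):
        ds, plan, _ = self._separable()
        panel = [f.feature_id for f in ds.matrix.features][:4] + [9999]
        with pytest.warns(UserWarning, match="absent"):
            evaluate_fixed_panel(panel, ds, plan)

    def test_empty_effective_panel_rejected(self):
        ds, plan, _ = self._separable()
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                evaluate_fixed_panel([9999], ds, plan)

    def test_holdout_never_influences_rankings(self):
        """Corrupting holdout labels must leave every ranking unchanged."""
        ds, plan, _ = self._separable()
        rankings = [svm_rfe_rank(ds.subset_samples(tr)).feature_ids
                    for tr, _ in plan.repeats]
        corrupted = ds.labels.copy()
        corrupted[plan.holdout] = np.roll(corrupted[plan.holdout], 1)
        ds_bad = dataset_from_array(ds.matrix.values, corrupted)
        rankings_bad = [svm_rfe_rank(ds_bad.subset_samples(tr)).feature_ids
                        for tr, _ in plan.repeats]
        assert rankings == rankings_bad
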