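"""Cluster folds, classification metrics and the nested-CV protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import f1_score, matthews_corrcoef, precision_score, recall_score

from hotspots.evaluation import (
    ClassificationCounts,
    FoldPlan,
    Metrics,
    make_cluster_folds,
    mcc,
    nested_cv,
    precision_recall_f1,
    score_ddg_correlation,
)
from hotspots.models import TrainingConfig
from hotspots.synthetic import SyntheticFeatureSpec, generate_feature_dataset

FAST = TrainingConfig(C_grid=(0.1, 1.0, 10.0), class_weight_grid=(1.0, 2.0))


class TestFoldPlans:
    def test_leave_one_cluster_out(self):
        plan = make_cluster_folds([f"c{i}" for i in range(6)], k_outer=6)
        assert plan.k_outer == 6
        assert all(len(test) == 1 for _, test in plan.outer)

    def test_outer_tests_partition_all_clusters(self):
        clusters = [f"c{i}" for i in range(10)]
        plan = make_cluster_folds(clusters, k_outer=4, seed=3)
        tests = [test for _, test in plan.outer]
        assert set().union(*tests) == set(clusters)
        assert sum(len(t) for t in tests) == len(clusters)

    def test_same_seed_gives_identical_plan(self):
        a = make_cluster_folds([f"c{i}" for i in range(8)], 4, 3, seed=9)
        b = make_cluster_folds([f"c{i}" for i in range(8)], 4, 3, seed=9)
        assert a == b

    def test_too_many_outer_folds_is_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_cluster_folds(["c0", "c1"], k_outer=3)

    def test_inner_folds_never_touch_outer_test(self):
        plan = make_cluster_folds([f"c{i}" for i in range(9)], 3, 3, seed=1)
        for (train, test), inner in zip(plan.outer, plan.inner):
            for itrain, itest in inner:
                assert not (itrain | itest) & test
                assert itrain | itest <= train

    def test_invalid_plans_are_rejected_at_construction(self):
        with pytest.raises(ValueError, match="both sides"):
            FoldPlan(
                outer=((frozenset({"c0"}), frozenset({"c0"})),),
                inner=(((frozenset({"c0"}), frozenset({"c1"})),),),
                k_outer=1, k_inner=2, seed=0,
            )


class TestMetrics:
    def test_hand_evaluated_precision_recall_f1(self):
        p, r, f1 = precision_recall_f1(ClassificationCounts(tp=3, fp=2, fn=1, tn=4))
        assert (p, r) == (0.6, 0.75)
        assert f1 == pytest.approx(2 / 3)

    def test_perfect_and_degenerate_conventions(self):
        assert precision_recall_f1(ClassificationCounts(5, 0, 0, 0)) == (1, 1, 1)
        assert precision_recall_f1(ClassificationCounts(0, 0, 4, 0)) == (0, 0, 0)
        assert mcc(ClassificationCounts(5, 0, 0, 5)) == 1.0
        assert mcc(ClassificationCounts(3, 3, 3, 3)) == 0.0

    def test_mcc_hand_value(self):
        # (3*4 - 2*1)/sqrt(5*4*6*5) evaluated independently
        assert mcc(ClassificationCounts(3, 2, 1, 4)) == pytest.approx(
            10 / np.sqrt(600))

    @pytest.mark.parametrize("seed", range(4))
    def test_metrics_agree_with_confusion_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(250):
            c = ClassificationCounts(*(int(v) for v in rng.integers(0, 20, 4)))
            if c.total == 0:
                continue
            y_true = [1] * c.tp + [-1] * c.fp + [1] * c.fn + [-1] * c.tn
            y_pred = [1] * c.tp + [1] * c.fp + [-1] * c.fn + [-1] * c.tn
            p, r, f1 = precision_recall_f1(c)
            assert p == pytest.approx(precision_score(y_true, y_pred,
                                                      zero_division=0))
            assert r == pytest.approx(recall_score(y_true, y_pred,
                                                   zero_division=0))
            assert f1 == pytest.approx(f1_score(y_true, y_pred, zero_division=0))
            if p + r:
                assert f1 == pytest.approx(2 * p * r / (p + r))
            m = mcc(c)
            assert -1.0 <= m <= 1.0
            if len(set(y_true)) == 2 and len(set(y_pred)) == 2:
                assert m == pytest.approx(matthews_corrcoef(y_true, y_pred))

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(counts=st.tuples(*(st.integers(0, 100) for _ in range(4))))
    def test_metric_bounds_hold_for_all_count_tables(self, counts):
        c = ClassificationCounts(*counts)
        p, r, f1 = precision_recall_f1(c)
        assert 0.0 <= p <= 1.0 and 0.0 <= r <= 1.0 and 0.0 <= f1 <= 1.0
        assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12  # harmonic mean bracket
        assert -1.0 <= mcc(c) <= 1.0

    def test_score_ddg_correlation_limits(self, rng):
        ddg = rng.normal(2.0, 1.5, 200)
        assert score_ddg_correlation(ddg, ddg) == pytest.approx(1.0)
        assert score_ddg_correlation(-ddg, ddg) == pytest.approx(-1.0)
        noisy = 0.8 * ddg + rng.normal(0, 1.5 * 0.6, 200)
        expected = 0.8 * 1.5 / np.sqrt((0.8 * 1.5) ** 2 + (1.5 * 0.6) ** 2)
        assert score_ddg_correlation(noisy, ddg) == pytest.approx(expected, abs=0.1)
        with pytest.raises(ValueError):
            score_ddg_correlation([1.0, 2.0], [1.0, 2.0])


def recoverable_dataset(seed=31, n=400, noise=0.02):
    return generate_feature_dataset(SyntheticFeatureSpec(
        n_rows=n, seed=seed, label_noise=noise, n_clusters=8))


class TestNestedCV:
    def test_recoverable_signal_reaches_high_f1(self):
        # labels are exactly the sign of a fixed linear function of 3 features
        data = generate_feature_dataset(SyntheticFeatureSpec(
            n_rows=400, seed=31, label_noise=0.0, ddg_noise_sd=0.0,
            true_weights={"vdw_sc_inter": -1.0, "hbond_sc_inter": -0.8,
                          "desolv_sc_inter": -0.6},
            n_clusters=8))
        plan = make_cluster_folds(data.table["cluster_id"], k_outer=8, seed=0)
        result = nested_cv(data.table, plan, FAST, mode="general")
        assert result.metrics.f1 > 0.9
        assert result.metrics.counts.total == len(data.table)

    def test_permuted_labels_give_null_mcc(self):
        data = recoverable_dataset(seed=32, n=500)
        table = data.table.copy()
        rng = np.random.default_rng(5)
        table["label"] = rng.permutation(table["label"].to_numpy())
        plan = make_cluster_folds(table["cluster_id"], k_outer=5, seed=0)
        result = nested_cv(table, plan, FAST, mode="general")
        assert abs(result.metrics.mcc) <= 0.15

    def test_label_leak_sentinel_reaches_perfect_f1(self):
        data = generate_feature_dataset(SyntheticFeatureSpec(
            n_rows=300, seed=33, label_noise=0.0, n_clusters=6))
        table = data.table.copy()
        table["vdw_sc_inter"] = table["label"].astype(float)  # leak sentinel
        plan = make_cluster_folds(table["cluster_id"], k_outer=6, seed=0)
        result = nested_cv(table, plan, FAST, mode="general")
        assert result.metrics.f1 == 1.0
        # ... and only via outer-test scoring: training never saw test rows
        for rows, fold_pred in zip(
                result.rows_used_by_fold,
                (grp for _, grp in result.predictions.groupby("outer_fold"))):
            assert rows.isdisjoint(fold_pred.index)

    def test_ensemble_without_specialists_degrades_to_general(self):
        data = recoverable_dataset(seed=34, n=300)
        plan = make_cluster_folds(data.table["cluster_id"], k_outer=4, seed=0)
        general = nested_cv(data.table, plan, FAST, mode="general")
        degraded = nested_cv(data.table, plan, FAST, mode="ensemble",
                             specialist_aas=())
        pd.testing.assert_frame_equal(general.predictions, degraded.predictions)

    def test_counts_conserve_and_clusters_never_leak(self):
        data = recoverable_dataset(seed=35, n=300)
        plan = make_cluster_folds(data.table["cluster_id"], k_outer=4, seed=2)
        result = nested_cv(data.table, plan, FAST, mode="general")
        c = result.metrics.counts
        assert c.tp + c.fp + c.fn + c.tn == len(data.table)
        for (train, test), rows, (_, fold_pred) in zip(
                plan.outer, result.rows_used_by_fold,
                result.predictions.groupby("outer_fold")):
            used_clusters = set(data.table.loc[sorted(rows), "cluster_id"])
            assert used_clusters <= train
            assert set(fold_pred["cluster_id"]) <= test

    def test_cluster_mismatch_is_hard_error(self):
        data = recoverable_dataset(seed=36, n=100)
        plan = make_cluster_folds(["x0", "x1", "x2"], k_outer=3)
        with pytest.raises(ValueError, match="cluster mismatch"):
            nested_cv(data.table, plan, FAST)

    def test_per_aa_breakdown_covers_observed_types(self):
        data = recoverable_dataset(seed=37, n=300)
        plan = make_cluster_folds(data.table["cluster_id"], k_outer=4, seed=0)
        result = nested_cv(data.table, plan, FAST, mode="general")
        assert set(result.metrics.per_aa) == set(data.table["wt_aa"])
        assert sum(v["n"] for v in result.metrics.per_aa.values()) == len(data.table)
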