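"""Validation statistics, CV splits, summaries, and the leakage guard."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radclass.evaluation import (
    HISTOLOGY,
    PipelineOptions,
    HoldoutVault,
    auc,
    cohen_kappa,
    confusion_metrics,
    make_cv_splits,
    regenerate_split,
    run_pipeline,
    summarize,
)
from conftest import balanced_config, rng
from radclass.cohort import generate_cohort


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        m = confusion_metrics(["SCC", "AC"], ["SCC", "AC"], "SCC")
        assert m == {"sensitivity": 1.0, "specificity": 1.0, "ppv": 1.0,
                     "npv": 1.0, "youden": 1.0}

    def test_hand_computed_confusion(self):
        # TP=9, FN=1, TN=7, FP=3
        y_true = ["P"] * 10 + ["N"] * 10
        y_pred = ["P"] * 9 + ["N"] + ["P"] * 3 + ["N"] * 7
        m = confusion_metrics(y_true, y_pred, "P")
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.7)
        assert m["ppv"] == pytest.approx(0.75)
        assert m["npv"] == pytest.approx(0.875)
        assert m["youden"] == pytest.approx(0.6)

    def test_all_positive_predictions(self):
        m = confusion_metrics(["P", "N", "N"], ["P", "P", "P"], "P")
        assert (m["sensitivity"], m["specificity"]) == (1.0, 0.0)
        assert m["youden"] == 0.0
        assert math.isnan(m["npv"])

    def test_absent_class_gives_nan_sensitivity(self):
        m = confusion_metrics(["N", "N"], ["P", "N"], "P")
        assert math.isnan(m["sensitivity"]) and math.isnan(m["youden"])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1,
                    max_size=40))
    def test_youden_identity(self, pairs):
        y_true = [t for t, _ in pairs]
        y_pred = [p for _, p in pairs]
        m = confusion_metrics(y_true, y_pred, True)
        if not (math.isnan(m["sensitivity"]) or math.isnan(m["specificity"])):
            assert m["youden"] == m["sensitivity"] + m["specificity"] - 1.0


class TestAUC:
    def test_perfect_ordering(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 1) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0.4] * 6, [0, 1, 0, 1, 0, 1], 1) == 0.5

    def test_pairwise_concordance_case(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], 1) == pytest.approx(0.75)

    def test_matches_concordance_oracle(self):
        g = rng(3)
        for _ in range(10):
            y = g.integers(0, 2, size=30)
            if y.min() == y.max():
                continue
            p = np.round(g.random(30), 1)   # coarse grid forces ties
            pos, neg = p[y == 1], p[y == 0]
            wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
            assert auc(p, y, 1) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_missing(self):
        assert math.isnan(auc([0.1, 0.9], [1, 1], 1))


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(["A", "B", "A"], ["A", "B", "A"]) == 1.0

    def test_hand_computed_two_by_two(self):
        # counts [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5, kappa = 0.4
        y_true = ["A"] * 25 + ["B"] * 25
        y_pred = ["A"] * 20 + ["B"] * 5 + ["A"] * 10 + ["B"] * 15
        assert cohen_kappa(y_true, y_pred) == pytest.approx(0.4)

    def test_independent_predictions_near_zero(self):
        g = rng(4)
        y = g.integers(0, 3, size=10_000)
        p = g.integers(0, 3, size=10_000)
        assert abs(cohen_kappa(y, p)) < 0.03

    def test_both_sides_constant_and_equal(self):
        assert cohen_kappa(["A"] * 5, ["A"] * 5) == 1.0


class TestSplits:
    def test_reference_split_sizes(self):
        splits = make_cv_splits(391, n_replicates=5, master_seed=0)
        for s in splits:
            assert len(s.train_idx) == 313 and len(s.test_idx) == 78
            assert np.intersect1d(s.train_idx, s.test_idx).size == 0
            union = np.union1d(s.train_idx, s.test_idx)
            np.testing.assert_array_equal(union, np.arange(391))

    def test_master_seed_determinism(self):
        a = make_cv_splits(100, n_replicates=10, master_seed=3)
        b = make_cv_splits(100, n_replicates=10, master_seed=3)
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.train_idx, t.train_idx)

    def test_small_fraction_case(self):
        splits = make_cv_splits(10, n_replicates=3, train_fraction=0.8,
                                master_seed=1)
        for s in splits:
            assert len(s.train_idx) == 8 and len(s.test_idx) == 2

    def test_regenerate_from_logged_seed(self):
        splits = make_cv_splits(60, n_replicates=4, train_fraction=0.75,
                                master_seed=9)
        s = splits[2]
        r = regenerate_split(60, len(s.train_idx), s.replicate, s.seed)
        np.testing.assert_array_equal(r.train_idx, s.train_idx)
        np.testing.assert_array_equal(r.test_idx, s.test_idx)

    def test_stratified_splits_balance_classes(self):
        labels = np.array(["A"] * 40 + ["B"] * 10)
        splits = make_cv_splits(50, n_replicates=5, train_fraction=0.8,
                                master_seed=2, stratify_labels=labels)
        for s in splits:
            assert np.sum(labels[s.train_idx] == "B") == 8


class TestSummaries:
    def test_constant_records(self):
        records = pd.DataFrame({
            "method": "PREVALENCE", "modality": "PREV", "cls": "SCC",
            "sensitivity": [0.5] * 8})
        out = summarize(records)
        row = out[out.metric == "sensitivity"].iloc[0]
        assert (row["median"], row["low"], row["high"]) == (0.5, 0.5, 0.5)

    def test_uniform_draws_match_order_statistics(self):
        g = rng(6)
        records = pd.DataFrame({
            "method": "PREVALENCE", "modality": "PREV", "cls": "SCC",
            "youden": g.random(1000)})
        row = summarize(records).iloc[0]
        assert row["median"] == pytest.approx(0.5, abs=0.05)
        assert row["low"] == pytest.approx(0.025, abs=0.015)
        assert row["high"] == pytest.approx(0.975, abs=0.015)

    def test_missing_values_dropped_and_counted(self):
        records = pd.DataFrame({
            "method": "PREVALENCE", "modality": "PREV", "cls": "SCC",
            "sensitivity": [0.2, math.nan, 0.4, math.nan]})
        row = summarize(records).iloc[0]
        assert row["n_used"] == 2 and row["n_missing"] == 2
        assert row["median"] == pytest.approx(0.3)


class TestHarness:
    def test_vault_blocks_early_access(self):
        vault = HoldoutVault(pd.DataFrame({"CT_a": [1.0]}), np.array(["SCC"]))
        with pytest.raises(RuntimeError, match="before model finalization"):
            _ = vault.features
        with pytest.raises(RuntimeError, match="before model finalization"):
            _ = vault.y
        vault.finalize()
        assert vault.y[0] == "SCC"

    def test_aps_refused_for_multiclass(self):
        cohort = generate_cohort(balanced_config(seed=1))
        splits = make_cv_splits(cohort.features.shape[0], n_replicates=1,
                                train_fraction=0.8, master_seed=0)
        with pytest.raises(ValueError, match="binary outcomes only"):
            run_pipeline(cohort.features, cohort.labels, "ORIGIN",
                         ["APS"], ["CT"], splits)

    def test_prevalence_run_needs_no_features(self):
        cohort = generate_cohort(balanced_config(n_per_class=20, seed=3))
        splits = make_cv_splits(120, n_replicates=20, train_fraction=0.8,
                                master_seed=4)
        records = run_pipeline(cohort.features, cohort.labels, HISTOLOGY,
                               ["PREVALENCE"], [], splits)
        assert set(records["cls"]) == {"AC", "SCC"}
        assert len(records) == 20 * 2
        # Youden identity holds exactly in every record
        ok = records.dropna(subset=["youden"])
        np.testing.assert_allclose(
            ok["youden"], ok["sensitivity"] + ok["specificity"] - 1.0)

    def test_prevalence_interval_width_matches_binomial(self):
        # one-vs-rest sensitivity of the chance model: median ~ prevalence,
        # central-95% width ~ 2 * 1.96 * sqrt(p(1-p)/n_class_test)
        cohort = generate_cohort(balanced_config(n_per_class=30, seed=5))
        n = 180
        splits = make_cv_splits(n, n_replicates=400, train_fraction=0.8,
                                master_seed=7)
        records = run_pipeline(cohort.features, cohort.labels, HISTOLOGY,
                               ["PREVALENCE"], [], splits)
        summary = summarize(records)
        row = summary[(summary.cls == "SCC")
                      & (summary.metric == "sensitivity")].iloc[0]
        p = 0.5
        n_class_test = 0.5 * 0.2 * n
        expected_width = 2 * 1.96 * math.sqrt(p * (1 - p) / n_class_test)
        assert row["median"] == pytest.approx(p, abs=0.02)
        assert row["high"] - row["low"] == pytest.approx(expected_width,
                                                         rel=0.20)
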