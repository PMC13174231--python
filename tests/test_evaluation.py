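"""Metric computation: 2x2 counts, P/R/S/F1, NA conventions, category level."""

import math

import numpy as np
import pytest

from iraescan import (
    ConfusionCounts,
    compute_metrics,
    confusion_counts,
    evaluate_at_category_level,
    evaluate_label_sets,
)

from conftest import assert_close_or_both_nan, oracle_confusion, oracle_metrics


class TestConfusionCounts:
    def test_perfect_agreement_has_no_errors(self):
        units = {"u1": {"a"}, "u2": {"b"}, "u3": set()}
        cc = confusion_counts(units, units, ["a", "b"])
        for tp, fp, fn, tn in cc.counts.values():
            assert fp == 0 and fn == 0

    def test_hand_built_disagreements_match_enumeration(self):
        pred = {"u1": {"a"}, "u2": {"a", "b"}, "u3": set(), "u4": {"b"}}
        gold = {"u1": {"b"}, "u2": {"a"}, "u3": {"a"}, "u4": {"b"}}
        cc = confusion_counts(pred, gold, ["a", "b"])
        assert cc.counts == oracle_confusion(pred, gold, ["a", "b"])
        assert cc.counts["a"] == (1, 1, 1, 1)
        assert cc.counts["b"] == (1, 1, 1, 1)

    def test_none_unit_contributes_tn_or_fp_for_every_label(self):
        pred = {"u1": {"a"}}
        gold = {"u1": set()}  # the explicit 'None' annotation
        cc = confusion_counts(pred, gold, ["a", "b", "c"])
        assert cc.counts["a"] == (0, 1, 0, 0)
        assert cc.counts["b"] == (0, 0, 0, 1)
        assert cc.counts["c"] == (0, 0, 0, 1)

    def test_unit_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts({"u1": set()}, {"u2": set()}, ["a"])

    def test_counts_partition_units(self):
        with pytest.raises(ValueError):
            ConfusionCounts(counts={"a": (1, 1, 1, 1)}, n_units=5)

    def test_conservation_of_gold_and_predicted_positives(self):
        rng = np.random.default_rng(7)
        labels = ["a", "b", "c"]
        pred = {f"u{i}": {l for l in labels if rng.random() < 0.4} for i in range(40)}
        gold = {f"u{i}": {l for l in labels if rng.random() < 0.3} for i in range(40)}
        cc = confusion_counts(pred, gold, labels)
        for label, (tp, fp, fn, tn) in cc.counts.items():
            assert tp + fn == sum(1 for u in gold if label in gold[u])
            assert tp + fp == sum(1 for u in pred if label in pred[u])


class TestComputeMetrics:
    def test_symmetric_counts_give_half_everywhere(self):
        table = compute_metrics(ConfusionCounts({"a": (1, 1, 1, 1)}, 4))
        row = table.loc["a"]
        assert (row[["P", "R", "S", "F1"]] == 0.5).all()

    def test_absent_label_yields_na_cells_but_defined_specificity(self):
        # a label with no gold positives and no predictions: P, R, F1 are NA
        table = compute_metrics(ConfusionCounts({"a": (0, 0, 0, 10)}, 10))
        row = table.loc["a"]
        assert math.isnan(row["P"]) and math.isnan(row["R"]) and math.isnan(row["F1"])
        assert row["S"] == 1.0

    def test_f1_zero_when_errors_exist_without_tp(self):
        table = compute_metrics(ConfusionCounts({"a": (0, 2, 1, 7)}, 10))
        assert table.loc["a", "F1"] == 0.0

    def test_macro_excludes_na_labels_per_metric(self):
        counts = ConfusionCounts({"a": (1, 1, 1, 1), "b": (0, 0, 0, 4)}, 4)
        table = compute_metrics(counts)
        # P: only label 'a' defined -> macro P = 0.5; S: both defined -> (0.5+1)/2
        assert table.loc["macro avg", "P"] == 0.5
        assert table.loc["macro avg", "S"] == pytest.approx(0.75)

    def test_micro_f1_is_harmonic_mean_of_micro_p_and_r(self):
        rng = np.random.default_rng(13)
        labels = [f"l{i}" for i in range(5)]
        counts = {}
        total = 30
        for l in labels:
            parts = rng.multinomial(total, [0.25] * 4)
            counts[l] = tuple(int(x) for x in parts)
        table = compute_metrics(ConfusionCounts(counts, total))
        p, r = table.loc["micro avg", "P"], table.loc["micro avg", "R"]
        assert table.loc["micro avg", "F1"] == pytest.approx(2 * p * r / (p + r))

    def test_random_counts_match_independent_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            labels = [f"l{i}" for i in range(int(rng.integers(1, 6)))]
            total = int(rng.integers(1, 40))
            counts = {
                l: tuple(int(x) for x in rng.multinomial(total, [0.25] * 4))
                for l in labels
            }
            table = compute_metrics(ConfusionCounts(counts, total))
            expected = oracle_metrics(counts)
            for row_name, row in expected.items():
                for col in ("P", "R", "S", "F1"):
                    assert_close_or_both_nan(table.loc[row_name, col], row[col])

    def test_micro_row_agrees_with_sklearn_on_binary_indicator_matrix(self):
        from sklearn.metrics import f1_score, precision_score, recall_score

        rng = np.random.default_rng(41)
        labels = ["a", "b", "c", "d"]
        pred = {f"u{i}": {l for l in labels if rng.random() < 0.4} for i in range(60)}
        gold = {f"u{i}": {l for l in labels if rng.random() < 0.35} for i in range(60)}
        table = evaluate_label_sets(pred, gold, labels)
        units = sorted(pred)
        y_pred = np.array([[l in pred[u] for l in labels] for u in units], dtype=int)
        y_true = np.array([[l in gold[u] for l in labels] for u in units], dtype=int)
        assert table.loc["micro avg", "P"] == pytest.approx(
            precision_score(y_true, y_pred, average="micro"), abs=1e-12
        )
        assert table.loc["micro avg", "R"] == pytest.approx(
            recall_score(y_true, y_pred, average="micro"), abs=1e-12
        )
        assert table.loc["micro avg", "F1"] == pytest.approx(
            f1_score(y_true, y_pred, average="micro"), abs=1e-12
        )


class TestCategoryLevel:
    def test_within_category_confusion_scores_as_category_tp(self, demo_profile):
        # colitis predicted where gold says hepatitis: both Gastrointestinal
        pred = {"u1": {"colitis"}}
        gold = {"u1": {"hepatitis"}}
        label_table = evaluate_label_sets(pred, gold, demo_profile.label_ids)
        cat_table = evaluate_at_category_level(pred, gold, demo_profile)
        assert label_table.loc["micro avg", "F1"] == 0.0
        assert cat_table.loc["Gastrointestinal", "F1"] == 1.0

    def test_identical_sets_give_unit_f1_at_both_levels(self, demo_profile):
        units = {"u1": {"colitis", "rash"}, "u2": {"pneumonitis"}, "u3": set()}
        label_table = evaluate_label_sets(units, units, demo_profile.label_ids)
        cat_table = evaluate_at_category_level(units, units, demo_profile)
        assert label_table.loc["micro avg", "F1"] == 1.0
        assert cat_table.loc["micro avg", "F1"] == 1.0

    def test_all_within_category_errors_make_category_level_perfect(self, demo_profile):
        # every disagreement swaps colitis <-> hepatitis (same category)
        pred = {"u1": {"colitis"}, "u2": {"hepatitis"}, "u3": {"rash"}, "u4": set()}
        gold = {"u1": {"hepatitis"}, "u2": {"colitis"}, "u3": {"rash"}, "u4": set()}
        label_table = evaluate_label_sets(pred, gold, demo_profile.label_ids)
        cat_table = evaluate_at_category_level(pred, gold, demo_profile)
        assert label_table.loc["micro avg", "F1"] < 1.0
        assert cat_table.loc["micro avg", "F1"] == 1.0
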