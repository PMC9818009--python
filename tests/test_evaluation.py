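"""Evaluation statistics: confusion counts, accuracy, kappa, cross-entropy,
min-max normalization and the two-group t-test."""

import math

import numpy as np
import pytest

from peepwatch.evaluation import (
    ConfusionMatrix,
    EvalReport,
    TTestResult,
    accuracy,
    compare_classifiers,
    confusion,
    cross_entropy,
    evaluate_predictions,
    kappa,
    label_distribution,
    min_max_normalize,
    two_group_t_test,
)


class TestConfusion:
    def test_identity_predictions(self):
        y = ["distress"] * 5 + ["normal"] * 5
        cm = confusion(y, y)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (5, 5, 0, 0)

    def test_all_normal_predictions(self):
        y_true = ["distress"] * 3 + ["normal"] * 7
        cm = confusion(y_true, ["normal"] * 10)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (0, 3, 7, 0)

    def test_empty_and_mismatched_sequences_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion([], [])
        with pytest.raises(ValueError, match="length mismatch"):
            confusion(["normal"], ["normal", "normal"])
        with pytest.raises(ValueError, match="unknown label"):
            confusion(["ok"], ["normal"])


class TestAccuracyKappa:
    def test_accuracy_closed_form(self):
        assert accuracy(ConfusionMatrix(tp=5, tn=7, fp=1, fn=1)) == pytest.approx(100 * 12 / 14)

    def test_accuracy_extremes(self):
        assert accuracy(ConfusionMatrix(4, 6, 0, 0)) == 100.0
        assert accuracy(ConfusionMatrix(0, 0, 3, 2)) == 0.0

    def test_kappa_perfect_and_chance(self):
        assert kappa(ConfusionMatrix(5, 5, 0, 0)) == pytest.approx(1.0)
        assert kappa(ConfusionMatrix(25, 25, 25, 25)) == pytest.approx(0.0)

    def test_kappa_worked_example(self):
        # p_o = 12/14, p_e = (6*6 + 8*8)/14^2 -> kappa = 68/96
        assert kappa(ConfusionMatrix(5, 7, 1, 1)) == pytest.approx(68 / 96)

    def test_kappa_degenerate_single_cell(self):
        assert kappa(ConfusionMatrix(10, 0, 0, 0)) == 0.0

    def test_kappa_matches_brute_force_and_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(42)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 20, size=4)
            if tp + tn + fp + fn == 0:
                continue
            cm = ConfusionMatrix(int(tp), int(tn), int(fp), int(fn))
            n = cm.total
            # brute-force chance agreement from marginals
            p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
            p_o = (tp + tn) / n
            expected = 0.0 if p_e == 1 else (p_o - p_e) / (1 - p_e)
            assert kappa(cm) == pytest.approx(expected, abs=1e-12)
            assert kappa(cm) <= 1.0
        # dual route on a label-sequence example
        y_true = ["distress"] * 6 + ["normal"] * 8
        y_pred = ["distress"] * 5 + ["normal"] * 2 + ["normal"] * 6 + ["distress"]
        assert kappa(confusion(y_true, y_pred)) == pytest.approx(
            cohen_kappa_score(y_true, y_pred), abs=1e-12
        )


class TestCrossEntropy:
    def test_certain_event(self):
        assert cross_entropy([1, 0], [1, 0]) == 0.0

    def test_uniform_binary(self):
        assert cross_entropy([0.5, 0.5], [0.5, 0.5], base=2) == pytest.approx(1.0)

    def test_single_term_closed_form(self):
        # weights from the estimate Q = [1, 0]; log of the target P
        assert cross_entropy([0.9, 0.1], [1, 0], base=2) == pytest.approx(-math.log2(0.9))

    def test_self_cross_entropy_equals_entropy(self):
        p = np.array([0.2, 0.3, 0.5])
        h = -(p * np.log2(p)).sum()
        assert cross_entropy(p, p) == pytest.approx(h)
        assert cross_entropy(p, p, base=math.e) == pytest.approx(-(p * np.log(p)).sum())

    def test_zero_target_probability_with_mass_is_infinite(self):
        assert cross_entropy([1, 0], [0.5, 0.5]) == math.inf

    def test_conventions_differ(self):
        p, q = [0.9, 0.1], [0.6, 0.4]
        default = cross_entropy(p, q)
        textbook = cross_entropy(p, q, convention="target_weighted")
        assert default == pytest.approx(-(0.6 * math.log2(0.9) + 0.4 * math.log2(0.1)))
        assert textbook == pytest.approx(-(0.9 * math.log2(0.6) + 0.1 * math.log2(0.4)))
        assert default != textbook

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            cross_entropy([0.5, 0.6], [0.5, 0.5])

    def test_log_loss_confident_correct_predictions_near_zero(self):
        from peepwatch.evaluation import log_loss_score

        h = log_loss_score(["distress", "normal"], [0.99, 0.01], base=2)
        assert h == pytest.approx(-math.log2(0.99), rel=1e-9)
        # a confident wrong prediction is heavily penalized, not infinite
        assert np.isfinite(log_loss_score(["distress"], [0.0]))

    def test_nonnegative_for_valid_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = rng.dirichlet(np.ones(4))
            q = rng.dirichlet(np.ones(4))
            assert cross_entropy(p, q) >= 0


class TestMinMaxAndTTest:
    def test_min_max_arithmetic(self):
        assert min_max_normalize([1, 3, 5]) == pytest.approx([0, 0.5, 1.0])

    def test_endpoints_map_exactly(self):
        out = min_max_normalize([7.2, -1.0, 3.0])
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            min_max_normalize([2, 2])

    def test_identical_groups_not_significant(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = two_group_t_test(a, a)
        assert res.statistic == pytest.approx(0.0)
        assert not res.significant

    def test_separated_synthetic_groups_significant(self):
        # energy units of isolated vs 15-bird groups
        rng = np.random.default_rng(11)
        a = np.clip(rng.normal(14.87, 12.501, 12), 0, None)
        b = np.clip(rng.normal(0.05, 0.029, 12), 0, None)
        assert two_group_t_test(a, b).significant

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(1.0, 1.0, size=10)
        p1 = two_group_t_test(a, b).p_value
        p2 = two_group_t_test(rng.permutation(a), rng.permutation(b)).p_value
        assert p1 == pytest.approx(p2)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            two_group_t_test([1.0], [1.0, 2.0])


class TestEvalReport:
    def test_passing_triple(self):
        rep = EvalReport(accuracy=85.71, kappa=0.73, cross_entropy=0.2)
        assert rep.pass_flags == {"accuracy": True, "kappa": True, "cross_entropy": True}
        assert rep.passed

    def test_failing_triple_flags_kappa_and_cross_entropy(self):
        rep = EvalReport(accuracy=71.43, kappa=0.46, cross_entropy=0.6)
        assert rep.pass_flags == {"accuracy": False, "kappa": False, "cross_entropy": False}

    def test_cross_entropy_only_failure(self):
        rep = EvalReport(accuracy=85.71, kappa=0.72, cross_entropy=0.3)
        flags = rep.pass_flags
        assert flags["accuracy"] and flags["kappa"] and not flags["cross_entropy"]

    def test_report_from_label_sequences(self):
        y_true = ["distress"] * 6 + ["normal"] * 8
        y_pred = ["distress"] * 5 + ["normal"] + ["normal"] * 7 + ["distress"]
        rep = evaluate_predictions(y_true, y_pred)
        assert rep.accuracy == pytest.approx(100 * 12 / 14)
        assert rep.confusion.total == 14
        h = cross_entropy(label_distribution(y_true), label_distribution(y_pred))
        assert rep.cross_entropy == pytest.approx(h)

    def test_json_serialization(self, tmp_path):
        import json

        rep = evaluate_predictions(
            ["distress", "normal"], ["distress", "normal"], prob_distress=[1.0, 0.0]
        )
        path = tmp_path / "report.json"
        rep.to_json(path)
        data = json.loads(path.read_text())
        assert data["passed"] is True
        assert data["confusion"] == {"tp": 1, "tn": 1, "fp": 0, "fn": 0}

    def test_compare_classifiers_table(self):
        from peepwatch import synth_feature_table
        from peepwatch.synth import binarize_labels

        t = binarize_labels(synth_feature_table(72, seed=13))
        table = compare_classifiers(t, seed=13)
        assert list(table["classifier"]) == ["knn", "decision_tree", "random_forest"]
        assert set(table.columns) >= {"accuracy_pct", "kappa", "cross_entropy"}
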