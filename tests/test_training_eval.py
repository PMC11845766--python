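import warnings
from fractions import Fraction

import numpy as np
import pytest

from trispectrakan.training_eval import (TrainConfig,
                                         binary_metrics_from_counts,
                                         confusion_matrix, make_folds,
                                         multiclass_metrics, stratified_split)


class TestStratifiedSplit:
    def test_balanced_two_class_70_10_20(self):
        labels = np.repeat([0, 1], 50)
        tr, va, te = stratified_split(labels, seed=0)
        assert (len(tr), len(va), len(te)) == (70, 10, 20)
        for part in (tr, va, te):
            counts = np.bincount(labels[part], minlength=2)
            assert abs(counts[0] - counts[1]) <= 1

    def test_disjoint_and_exhaustive(self):
        labels = np.random.default_rng(0).integers(0, 6, 200)
        tr, va, te = stratified_split(labels, seed=3)
        all_idx = np.concatenate([tr, va, te])
        assert len(all_idx) == 200
        assert len(np.unique(all_idx)) == 200

    def test_same_seed_reproduces(self):
        labels = np.repeat(np.arange(6), 20)
        a = stratified_split(labels, seed=9)
        b = stratified_split(labels, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_degenerate_all_train(self):
        labels = np.repeat([0, 1], 10)
        tr, va, te = stratified_split(labels, ratios=(1.0, 0.0, 0.0), seed=0)
        assert len(tr) == 20 and len(va) == 0 and len(te) == 0

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="class 1"):
            stratified_split(np.array([0, 0, 0, 0, 1, 1]), seed=0)


class TestMakeFolds:
    def test_five_fold_partition(self):
        labels = np.repeat([0, 1], 25)
        folds = make_folds(labels, k=5, seed=0)
        assert len(folds) == 5
        assert all(len(te) == 10 and len(tr) == 40 for tr, te in folds)
        union = np.sort(np.concatenate([te for _, te in folds]))
        assert np.array_equal(union, np.arange(50))

    def test_stratification_within_one(self):
        labels = np.repeat(np.arange(5), 20)
        for _, te in make_folds(labels, k=5, seed=1):
            counts = np.bincount(labels[te], minlength=5)
            assert counts.max() - counts.min() <= 1

    def test_undersized_class_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array([0] * 10 + [1] * 3), k=5, seed=0)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 2, 3, 4, 5, 2, 2])
        conf = confusion_matrix(y, y)
        assert np.array_equal(conf, np.diag(np.bincount(y, minlength=6)))

    def test_hand_counted_two_class(self):
        conf = confusion_matrix([0, 0, 1], [0, 1, 1], n_classes=2)
        assert conf.tolist() == [[1, 1], [0, 1]]

    def test_total_conserved(self):
        rng = np.random.default_rng(0)
        y, p = rng.integers(0, 6, 100), rng.integers(0, 6, 100)
        assert confusion_matrix(y, p).sum() == 100

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 6], [0, 0])


class TestBinaryMetrics:
    def test_hand_computed_quadruple(self):
        m = binary_metrics_from_counts(8, 9, 2, 1)
        assert m["precision"] == pytest.approx(0.800, abs=5e-4)
        assert m["sensitivity"] == pytest.approx(0.8889, abs=5e-5)
        assert m["specificity"] == pytest.approx(0.8182, abs=5e-5)
        assert m["accuracy"] == pytest.approx(0.85, abs=1e-12)
        assert m["f1"] == pytest.approx(0.8421, abs=5e-5)

    def test_perfect_classifier(self):
        m = binary_metrics_from_counts(5, 7, 0, 0)
        assert all(v == 1.0 for v in m.values())

    def test_zero_tp_with_fn(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = binary_metrics_from_counts(0, 5, 0, 3)
        assert m["sensitivity"] == 0.0 and m["f1"] == 0.0

    def test_zero_denominator_warns(self):
        with pytest.warns(RuntimeWarning):
            binary_metrics_from_counts(0, 5, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics_from_counts(-1, 0, 0, 0)

    def test_matches_exact_oracle_on_random_quadruples(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 50, 4))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = binary_metrics_from_counts(tp, tn, fp, fn)
            # independent exact-fraction evaluation of each formula
            def frac(num, den):
                return Fraction(num, den) if den else Fraction(0)
            prec = frac(tp, tp + fp)
            sens = frac(tp, tp + fn)
            expected = {
                "accuracy": frac(tp + tn, tp + tn + fn + fp),
                "specificity": frac(tn, tn + fp),
                "sensitivity": sens,
                "precision": prec,
            }
            for key, val in expected.items():
                assert abs(m[key] - float(val)) < 1e-12, (key, tp, tn, fp, fn)
            f1 = (2 * prec * sens / (prec + sens)) if (prec + sens) else Fraction(0)
            assert abs(m["f1"] - float(f1)) < 1e-12


class TestMulticlassMetrics:
    def test_all_correct_gives_ones(self):
        report = multiclass_metrics(np.diag([5, 4, 6, 3, 2, 7]))
        assert report.accuracy == 1.0
        assert all(v == 1.0 for v in report.macro.values())

    def test_macro_f1_is_mean_of_per_class(self):
        rng = np.random.default_rng(1)
        conf = rng.integers(0, 20, (6, 6))
        report = multiclass_metrics(conf)
        assert report.macro["f1"] == pytest.approx(
            np.mean([report.per_class[c]["f1"] for c in range(6)]), abs=1e-12)

    def test_chance_level_accuracy_for_random_predictions(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 6, 6000)
        p = rng.integers(0, 6, 6000)
        report = multiclass_metrics(confusion_matrix(y, p))
        assert report.accuracy == pytest.approx(1 / 6, abs=0.05)

    def test_accuracy_is_trace_over_total(self):
        conf = np.array([[3, 1], [2, 4]])
        assert multiclass_metrics(conf).accuracy == pytest.approx(7 / 10)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            multiclass_metrics(np.zeros((2, 3)))


class TestTrainingLoop:
    def _separable_data(self, n=200, seed=0, width=40):
        """Tiny linearly separable 2-of-6-class feature batches.

        Narrow time axis keeps the conv heads fast; they accept any width.
        """
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        xs = []
        for h in (20, 12, 128):
            x = 0.1 * rng.standard_normal((n, h, width, 1))
            x[y == 1, :, :width // 2, :] += 1.0  # class-1 energy early
            xs.append(x.astype(np.float32))
        return xs, y.astype(np.int64)

    def test_learns_separable_problem(self):
        from trispectrakan.model import ModelConfig, build_hybrid_cnn_baseline
        from trispectrakan.training_eval import train_model
        xs, y = self._separable_data(60)
        model = build_hybrid_cnn_baseline(ModelConfig(variant="hybrid_cnn"),
                                          seed=0)
        cfg = TrainConfig(epochs=12, seed=0)
        model, hist = train_model(model, (xs, y), (xs, y), cfg)
        assert max(hist["train_acc"]) >= 0.95
        assert len(hist["train_loss"]) <= cfg.epochs

    def test_same_seed_same_trajectory(self):
        from trispectrakan.model import ModelConfig, build_hybrid_cnn_baseline
        from trispectrakan.training_eval import train_model
        xs, y = self._separable_data(40)
        runs = []
        for _ in range(2):
            model = build_hybrid_cnn_baseline(
                ModelConfig(variant="hybrid_cnn"), seed=1)
            _, hist = train_model(model, (xs, y), (xs, y),
                                  TrainConfig(epochs=2, seed=1))
            runs.append(hist["train_loss"])
        assert runs[0] == runs[1]

    def test_cross_validation_reports_fold_and_mean_accuracy(self):
        from trispectrakan.model import ModelConfig, build_hybrid_cnn_baseline
        from trispectrakan.training_eval import cross_validate
        xs, y = self._separable_data(48, width=24)
        res = cross_validate(
            lambda s: build_hybrid_cnn_baseline(
                ModelConfig(variant="hybrid_cnn"), seed=s),
            xs, y, k=3, cfg=TrainConfig(epochs=2, seed=0))
        assert len(res["fold_accuracies"]) == 3
        assert res["mean_accuracy"] == pytest.approx(
            np.mean(res["fold_accuracies"]))
        for report, acc in zip(res["per_fold"], res["fold_accuracies"]):
            assert report.accuracy == acc

    def test_empty_sets_rejected(self):
        from trispectrakan.model import build_trispectrakan
        from trispectrakan.training_eval import train_model
        model = build_trispectrakan(seed=0)
        xs, y = self._separable_data(20)
        with pytest.raises(ValueError):
            train_model(model, (xs, y[:0]), (xs, y), TrainConfig(epochs=1))


class TestEvaluate:
    def test_report_consistency_and_null_auc(self):
        """Random scores give chance AUC; accuracy equals trace/total."""
        from trispectrakan.training_eval import MetricsReport, evaluate
        rng = np.random.default_rng(4)

        class FakeModel:
            def predict_proba(self, xs):
                n = xs[0].shape[0]
                p = rng.random((n, 6))
                return p / p.sum(axis=1, keepdims=True)

        y = rng.integers(0, 6, 2000)
        xs = [np.zeros((2000, 1, 1, 1))] * 3
        report = evaluate(FakeModel(), (xs, y))
        assert report.accuracy == pytest.approx(
            np.trace(report.confusion) / report.confusion.sum())
        for c, a in report.auc_ovr.items():
            assert a == pytest.approx(0.5, abs=0.05)

    def test_empty_test_set_rejected(self):
        from trispectrakan.training_eval import evaluate
        with pytest.raises(ValueError):
            evaluate(None, ([np.zeros((0, 1, 1, 1))] * 3, np.array([])))
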