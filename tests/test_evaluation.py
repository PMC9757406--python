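import numpy as np
import pandas as pd
import pytest

from dmelm.elm import ELMConfig
from dmelm.evaluation import (
    ConfusionMatrix,
    MetricReport,
    activation_sweep,
    confusion,
    cross_validate,
    elm_classifier_factory,
    metrics,
    stratified_folds,
    validation_curve,
)


def brute_force_metrics(counts):
    """Independent per-class tally oracle for the macro metrics."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    C = counts.shape[0]
    acc = counts.trace() / total
    sens, spec, fs = [], [], []
    for i in range(C):
        tp = counts[i, i]
        fn = sum(counts[i, j] for j in range(C) if j != i)
        fp = sum(counts[j, i] for j in range(C) if j != i)
        tn = total - tp - fn - fp
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        sens.append(rec)
        spec.append(tn / (tn + fp) if tn + fp > 0 else 0.0)
        fs.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
    return acc, np.mean(sens), np.mean(spec), np.mean(fs)


class _MajorityClassifier:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.array([self.label] * len(X), dtype=object)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        cm = confusion(["a", "b", "c"], ["a", "b", "c"], ["a", "b", "c"])
        np.testing.assert_array_equal(cm.counts, np.eye(3, dtype=int))

    def test_everything_predicted_as_first_class(self):
        cm = confusion(["a", "b", "b"], ["a", "a", "a"], ["a", "b"])
        np.testing.assert_array_equal(cm.counts, [[1, 0], [2, 0]])

    def test_matches_loop_oracle_on_random_labels(self, rng):
        classes = ["x", "y", "z"]
        true = rng.choice(classes, size=100)
        pred = rng.choice(classes, size=100)
        cm = confusion(true, pred, classes)
        expect = np.zeros((3, 3), dtype=int)
        for t, p in zip(true, pred):
            expect[classes.index(t), classes.index(p)] += 1
        np.testing.assert_array_equal(cm.counts, expect)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="'q'"):
            confusion(["a", "q"], ["a", "a"], ["a", "b"])


class TestMetrics:
    def test_perfect_three_class_scores_all_one(self):
        cm = ConfusionMatrix(np.eye(3, dtype=int) * 10, ("a", "b", "c"))
        m = metrics(cm)
        assert m.as_array().tolist() == [1.0, 1.0, 1.0, 1.0]

    def test_hand_worked_binary_example(self):
        m = metrics(ConfusionMatrix(np.array([[8, 2], [1, 9]]), ("pos", "neg")))
        assert m.accuracy == pytest.approx(0.85)
        assert m.sensitivity == pytest.approx(0.85)
        assert m.specificity == pytest.approx(0.85)
        assert m.f_score == pytest.approx(0.8496, abs=5e-5)

    def test_never_predicted_class_scores_zero_by_rule(self):
        m = metrics(ConfusionMatrix(np.array([[5, 0], [3, 0]]), ("a", "b")))
        assert np.isfinite(m.as_array()).all()
        # class b: precision and F are 0/0 -> 0
        assert m.f_score == pytest.approx(0.5 * (2 * (5 / 8) * 1.0 / (5 / 8 + 1.0)))

    def test_agrees_with_tally_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            C = rng.integers(2, 5)
            counts = rng.integers(0, 20, size=(C, C))
            if counts.sum() == 0:
                counts[0, 0] = 1
            m = metrics(ConfusionMatrix(counts, tuple(f"c{i}" for i in range(C))))
            np.testing.assert_allclose(m.as_array(), brute_force_metrics(counts),
                                       atol=1e-12)

    def test_all_metrics_bounded(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, size=(3, 3))
            counts[0, 0] += 1
            arr = metrics(ConfusionMatrix(counts, ("a", "b", "c"))).as_array()
            assert np.all(arr >= 0) and np.all(arr <= 1)


class TestCrossValidate:
    def test_majority_classifier_scores_chance_on_balanced_table(self, small_table):
        factory = lambda X, y: _MajorityClassifier("ictal")
        report = cross_validate(factory, small_table, k=5, seed=0)
        assert report.mean("accuracy") == pytest.approx(1 / 3, abs=1e-9)

    def test_same_seed_identical_report(self, small_table):
        cfg = ELMConfig(n_hidden=20, activation="sine", seed=0)
        a = cross_validate(elm_classifier_factory(cfg), small_table, k=5, seed=3)
        b = cross_validate(elm_classifier_factory(cfg), small_table, k=5, seed=3)
        np.testing.assert_array_equal(a.to_frame().to_numpy(), b.to_frame().to_numpy())

    @pytest.mark.parametrize("n", [30, 31, 35])
    def test_per_class_fold_sizes_differ_by_at_most_one(self, n):
        y = np.array(["a"] * n + ["b"] * n)
        folds = stratified_folds(y, k=10, seed=0)
        assert len(folds) == 10
        for label in ("a", "b"):
            sizes = [np.sum(y[test] == label) for _, test in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_too_few_samples_per_class_rejected(self):
        y = np.array(["a"] * 3 + ["b"] * 10)
        with pytest.raises(ValueError, match="'a'"):
            stratified_folds(y, k=5, seed=0)

    def test_report_summary_format(self, small_table):
        factory = lambda X, y: _MajorityClassifier("normal")
        report = cross_validate(factory, small_table, k=4, seed=0)
        text = report.summary()
        assert "accuracy" in text and "±" in text
        assert report.n_folds == 4


class TestActivationSweep:
    def test_one_row_per_activation(self, small_table):
        cfg = ELMConfig(n_hidden=20, seed=0)
        out = activation_sweep(small_table, elm_config=cfg, k=4, seed=0)
        assert len(out) == 10
        assert list(out.columns) == ["activation", "accuracy_mean", "accuracy_std"]

    def test_smooth_activations_beat_hardlim(self, synthetic_table):
        means = {"sine": [], "multiquadric": [], "hardlim": []}
        for seed in range(5):
            cfg = ELMConfig(n_hidden=100, seed=seed)
            out = activation_sweep(synthetic_table, activations=list(means),
                                   elm_config=cfg, k=5, seed=seed)
            for _, row in out.iterrows():
                means[row["activation"]].append(row["accuracy_mean"])
        assert np.mean(means["sine"]) > np.mean(means["hardlim"])
        assert np.mean(means["multiquadric"]) > np.mean(means["hardlim"])

    def test_shared_folds_make_sweep_deterministic(self, small_table):
        cfg = ELMConfig(n_hidden=20, seed=0)
        a = activation_sweep(small_table, ["sine", "tanh"], cfg, k=4, seed=1)
        b = activation_sweep(small_table, ["sine", "tanh"], cfg, k=4, seed=1)
        pd.testing.assert_frame_equal(a, b)


class TestValidationCurve:
    def test_grid_length_and_determinism(self, small_table):
        cfg = ELMConfig(n_hidden=10, activation="sine", seed=0)
        a = validation_curve(small_table, [5, 10, 20], elm_config=cfg, k=4, seed=0)
        b = validation_curve(small_table, [5, 10, 20], elm_config=cfg, k=4, seed=0)
        assert len(a) == 3
        pd.testing.assert_frame_equal(a, b)

    def test_unsorted_grid_rejected(self, small_table):
        with pytest.raises(ValueError, match="ascending"):
            validation_curve(small_table, [20, 10], k=4, seed=0)

    def test_train_accuracy_grows_with_capacity(self, synthetic_table):
        cfg = ELMConfig(n_hidden=10, activation="multiquadric", seed=0)
        out = validation_curve(synthetic_table, [10, 40, 160], elm_config=cfg,
                               k=5, seed=0)
        train = out["train_accuracy"].to_numpy()
        assert np.all(np.diff(train) >= -0.02)
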