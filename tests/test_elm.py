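import numpy as np
import pytest

from dmelm.elm import (
    ACTIVATION_KINDS,
    DISTANCE_KINDS,
    ELM,
    ActivationSpec,
    ELMConfig,
    ELMResults,
    HiddenLayer,
    activation_value,
    hidden_matrix,
    init_hidden,
    solve_output_weights,
)


def make_blobs(n=200, separation=6.0, seed=0):
    """Two Gaussian blobs separated by `separation` standard deviations."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack([
        rng.normal(loc=(0.0, 0.0), size=(half, 2)),
        rng.normal(loc=(separation, separation), size=(n - half, 2)),
    ])
    y = np.array(["a"] * half + ["b"] * (n - half))
    return X, y


class TestActivationValues:
    @pytest.mark.parametrize(
        "kind,arg,expected",
        [
            ("tribas", 0.0, 1.0),
            ("tribas", 2.0, 0.0),
            ("inv_tribas", 0.0, 0.0),
            ("sigmoid", 0.0, 0.5),
            ("hardlim", 0.0, 0.0),
            ("hardlim", 0.1, 1.0),
            ("softlim", 0.4, 0.4),
            ("softlim", 2.0, 1.0),
            ("sine", np.pi / 2, 1.0),
            ("tanh", 0.0, 0.0),
            ("gaussian", 0.0, 1.0),
            ("multiquadric", 0.0, 1.0),
            ("inv_multiquadric", 0.0, 1.0),
        ],
    )
    def test_pointwise_definitions(self, kind, arg, expected):
        assert activation_value(kind, arg) == pytest.approx(expected, abs=1e-12)

    def test_family_split(self):
        for kind in ACTIVATION_KINDS:
            spec = ActivationSpec(kind)
            assert (spec.family == "distance") == (kind in DISTANCE_KINDS)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ActivationSpec("relu")


class TestInitHidden:
    def test_seed_determinism(self):
        cfg = ELMConfig(n_hidden=8, activation="sine", seed=5)
        a = init_hidden(cfg, 3)
        b = init_hidden(cfg, 3)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.biases, b.biases)

    def test_zero_weight_scale_gives_constant_hidden_matrix(self, rng):
        cfg = ELMConfig(n_hidden=4, activation="sigmoid", weight_scale=0.0, seed=0)
        hidden = init_hidden(cfg, 3)
        M = hidden_matrix(hidden, rng.normal(size=(5, 3)))
        np.testing.assert_allclose(M, 0.5)

    def test_centers_lie_inside_data_box(self, rng):
        X = rng.normal(size=(100, 4)) * np.array([1.0, 5.0, 0.1, 10.0])
        lo, hi = X.min(axis=0), X.max(axis=0)
        cfg = ELMConfig(n_hidden=100, activation="gaussian", seed=2)
        hidden = init_hidden(cfg, 4, data_ranges=(lo, hi))
        assert np.all(hidden.centers >= lo) and np.all(hidden.centers <= hi)
        assert np.all(hidden.widths > 0)

    def test_degenerate_data_range_width_fallback(self):
        cfg = ELMConfig(n_hidden=5, activation="gaussian", seed=0)
        hidden = init_hidden(cfg, 2, data_ranges=(np.array([1.0, 1.0]),
                                                  np.array([1.0 + 1e-300, 1.0 + 1e-300])))
        np.testing.assert_array_equal(hidden.widths, 1.0)


class TestHiddenMatrix:
    def test_single_unit_substitution(self):
        hidden = HiddenLayer(
            activation=ActivationSpec("sine"),
            weights=np.array([[1.0, 0.0]]),
            biases=np.array([0.0]),
        )
        M = hidden_matrix(hidden, np.array([[np.pi / 2, 9.0]]))
        assert M.shape == (1, 1)
        assert M[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("kind", ["sine", "sigmoid", "gaussian", "multiquadric"])
    def test_matches_scalar_loop_oracle(self, rng, kind):
        cfg = ELMConfig(n_hidden=4, activation=kind, seed=1)
        X = rng.normal(size=(5, 3))
        hidden = init_hidden(cfg, 3, data_ranges=(X.min(axis=0), X.max(axis=0)))
        M = hidden_matrix(hidden, X)
        spec = cfg.activation
        for j in range(5):
            for i in range(4):
                if spec.family == "projection":
                    a = float(hidden.weights[i] @ X[j] + hidden.biases[i])
                else:
                    a = float(np.linalg.norm(X[j] - hidden.centers[i]) / hidden.widths[i])
                assert M[j, i] == pytest.approx(float(activation_value(spec, a)),
                                                abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        cfg = ELMConfig(n_hidden=4, activation="sine", seed=1)
        hidden = init_hidden(cfg, 3)
        with pytest.raises(ValueError):
            hidden_matrix(hidden, rng.normal(size=(5, 2)))


class TestFit:
    def test_identity_hidden_matrix_reproduces_targets(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        v = solve_output_weights(np.eye(3), Y)
        np.testing.assert_allclose(v, Y, atol=1e-12)

    def test_normal_equations_satisfied(self, rng):
        X, y = make_blobs(n=40, seed=3)
        res = ELM(X, y, n_hidden=15, activation="tanh", seed=3).fit()
        assert res.normal_equation_residual() < 1e-6

    @pytest.mark.parametrize("kind", ["sine", "sigmoid", "multiquadric"])
    @pytest.mark.parametrize("seed", range(5))
    def test_separable_blobs_reach_perfect_training_accuracy(self, kind, seed):
        X, y = make_blobs(n=200, separation=6.0, seed=seed)
        res = ELM(X, y, n_hidden=50, activation=kind, seed=seed).fit()
        assert res.training_accuracy() == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two distinct classes"):
            ELM(np.zeros((4, 2)), ["a"] * 4, n_hidden=2)

    def test_non_finite_features_rejected(self):
        X = np.array([[1.0, np.inf], [0.0, 1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            ELM(X, ["a", "b"], n_hidden=2)

    def test_ridge_path_converges_to_min_norm_solution(self, rng):
        M = rng.normal(size=(12, 6))
        Y = rng.normal(size=(12, 2))
        v0 = solve_output_weights(M, Y, ridge=0.0)
        prev_gap = np.inf
        for ridge in (1e-2, 1e-4, 1e-6):
            gap = np.max(np.abs(solve_output_weights(M, Y, ridge=ridge) - v0))
            assert gap < prev_gap
            prev_gap = gap
        assert prev_gap < 1e-5


class TestPredict:
    def test_interpolation_regime_recovers_training_labels(self, rng):
        X, y = make_blobs(n=30, separation=3.0, seed=1)
        res = ELM(X, y, n_hidden=60, activation="sine", seed=1).fit()
        np.testing.assert_array_equal(res.predict(X), y)

    def test_duplicated_sample_scores_identical(self, rng):
        X, y = make_blobs(n=20, seed=2)
        res = ELM(X, y, n_hidden=10, activation="sigmoid", seed=2).fit()
        scores = res.predict_scores(np.vstack([X[0], X[0]]))
        np.testing.assert_array_equal(scores[0], scores[1])

    def test_argmax_tie_goes_to_first_sorted_class(self):
        res = ELMResults(
            model=ELM(np.zeros((2, 1)), ["b", "a"], n_hidden=1, activation="sine"),
            hidden=HiddenLayer(activation=ActivationSpec("softlim"),
                               weights=np.zeros((1, 1)), biases=np.zeros(1)),
            output_weights=np.zeros((1, 2)),  # all scores tie at 0
        )
        assert list(res.predict(np.array([[5.0]]))) == ["a"]

    def test_empty_input_gives_empty_output(self):
        X, y = make_blobs(n=20, seed=0)
        res = ELM(X, y, n_hidden=5, activation="sine", seed=0).fit()
        assert len(res.predict(np.empty((0, 2)))) == 0

    def test_save_load_round_trip(self, tmp_path, rng):
        X, y = make_blobs(n=40, seed=4)
        res = ELM(X, y, n_hidden=12, activation="multiquadric", seed=4).fit()
        path = tmp_path / "model.npz"
        res.save(path)
        back = ELMResults.load_predictor(path)
        np.testing.assert_array_equal(back.predict(X), res.predict(X))

    def test_summary_mentions_key_settings(self):
        X, y = make_blobs(n=20, seed=0)
        res = ELM(X, y, n_hidden=5, activation="sine", seed=0).fit()
        text = res.summary()
        assert "sine" in text and "training accuracy" in text
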