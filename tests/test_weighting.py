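"""BP/Garson weighting, RF oob permutation importance, maximizing-deviations fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from climacop import (
    ConfigurationError,
    DataError,
    NNConfig,
    RFConfig,
    WeightVector,
    garson_importance,
    hidden_layer_size,
    linearity_screen,
    md_combine,
    rf_importance,
    rf_raw_importance,
    train_bp,
)


class TestHiddenLayerSize:
    @pytest.mark.parametrize(
        "m,n,a,expected",
        [
            (27, 1, 2, 7),  # the survey sizing: floor(sqrt(28)) + 2
            (3, 1, 1, 3),
            (8, 1, 4, 7),
        ],
    )
    def test_sizing_rule(self, m, n, a, expected):
        assert hidden_layer_size(m, n, a) == expected

    def test_constant_out_of_range_is_error(self):
        with pytest.raises(ConfigurationError):
            hidden_layer_size(5, 1, 0)
        with pytest.raises(ConfigurationError):
            hidden_layer_size(5, 1, 11)


class TestLinearityScreen:
    def test_identical_column_has_r_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 2))
        r = linearity_screen(x, x[:, 0])
        assert r[0] == pytest.approx(1.0)

    def test_negated_column_has_r_minus_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 1))
        assert linearity_screen(x, -x[:, 0])[0] == pytest.approx(-1.0)

    def test_independent_column_has_small_r(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((10_000, 1))
        y = rng.standard_normal(10_000)
        assert abs(linearity_screen(x, y)[0]) < 0.05

    def test_constant_target_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            r = linearity_screen(np.random.default_rng(0).normal(size=(10, 2)), np.ones(10))
        assert (r == 0).all()


class TestTrainBP:
    def test_constant_target_reaches_tiny_error(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(200, 3))
        model = train_bp(X, np.full(200, 0.5), NNConfig(seed=0))
        assert model.training_error < 1e-4

    def test_smooth_linear_target_is_learnable(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(500, 2))
        y = 0.8 * X[:, 0] + 0.2 * X[:, 1]
        model = train_bp(X, y, NNConfig(seed=2, max_epochs=800))
        assert model.test_error < 1e-3

    def test_same_seed_gives_identical_weights(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(100, 4))
        y = X.mean(axis=1)
        m1 = train_bp(X, y, NNConfig(seed=5))
        m2 = train_bp(X, y, NNConfig(seed=5))
        assert (m1.V == m2.V).all() and (m1.W == m2.W).all()

    def test_non_finite_input_is_error(self):
        X = np.ones((20, 2))
        X[0, 0] = np.nan
        with pytest.raises(DataError):
            train_bp(X, np.ones(20))


class TestGarson:
    def test_symmetric_network_splits_importance_evenly(self):
        w = garson_importance(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([1.0, 1.0]))
        assert np.allclose(w.weights, [0.5, 0.5])

    def test_hand_computed_example(self):
        # hidden 1 shares (0.5, 0.5); hidden 2 shares (1, 0) -> (1.5, 0.5)/2.
        w = garson_importance(np.array([[1.0, 1.0], [1.0, 0.0]]), np.array([1.0, 1.0]))
        assert np.allclose(w.weights, [0.75, 0.25])

    def test_disconnected_input_has_zero_importance(self):
        w = garson_importance(np.array([[1.0, 1.0], [0.0, 0.0]]), np.array([1.0, 1.0]))
        assert w.weights[1] == 0.0

    def test_invariant_to_positive_scaling_of_W(self):
        rng = np.random.default_rng(0)
        V = rng.normal(size=(5, 3))
        W = rng.normal(size=3)
        a = garson_importance(V, W).weights
        b = garson_importance(V, 7.3 * W).weights
        assert np.allclose(a, b)

    def test_all_zero_weights_is_error(self):
        with pytest.raises(DataError):
            garson_importance(np.zeros((3, 2)), np.zeros(2))


class TestRFImportance:
    def test_planted_single_signal_is_top_ranked(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(1000, 5))
        y = X[:, 0].copy()
        w = rf_importance(X, y, RFConfig(n_trees=100, seed=1))
        assert w.weights.argmax() == 0

    def test_pure_noise_raw_importances_are_null(self):
        # Under independence the permutation importances fluctuate around
        # zero; averaged over 500 trees they stay far below the oob error.
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(2000, 5))
        y = rng.uniform(size=2000)
        raw, oob_error = rf_raw_importance(X, y, RFConfig(n_trees=500, seed=3))
        assert np.abs(raw).max() < 0.05 * oob_error

    def test_same_seed_gives_identical_output(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(200, 3))
        y = X.sum(axis=1)
        a = rf_importance(X, y, RFConfig(n_trees=50, seed=9)).weights
        b = rf_importance(X, y, RFConfig(n_trees=50, seed=9)).weights
        assert (a == b).all()


class TestMDCombine:
    def test_equal_inputs_pass_through(self):
        u = WeightVector(np.array([0.3, 0.7]), "bp")
        v = WeightVector(np.array([0.3, 0.7]), "rf")
        R = np.random.default_rng(0).uniform(size=(10, 2))
        combined, _ = md_combine(u, v, R)
        assert np.allclose(combined.weights, u.weights)

    def test_hand_computed_two_criterion_example(self):
        # D = (2, 1): A = 1.6, B = 1.2 -> alpha = 0.8, beta = 0.6.
        u = WeightVector(np.array([0.6, 0.4]), "bp")
        v = WeightVector(np.array([0.2, 0.8]), "rf")
        R = np.array([[1.0, 0.5], [-1.0, -0.5], [0.0, 0.5], [0.0, -0.5]])
        combined, diag = md_combine(u, v, R)
        assert diag.alpha == pytest.approx(0.8)
        assert diag.beta == pytest.approx(0.6)
        assert diag.alpha_norm == pytest.approx(0.5714, abs=1e-4)
        assert np.allclose(combined.weights, [0.4286, 0.5714], atol=1e-4)

    def test_unit_circle_constraint(self):
        u = WeightVector(np.array([0.5, 0.5]), "bp")
        v = WeightVector(np.array([0.9, 0.1]), "rf")
        R = np.random.default_rng(1).uniform(size=(8, 2))
        _, diag = md_combine(u, v, R)
        assert diag.alpha**2 + diag.beta**2 == pytest.approx(1.0, abs=1e-9)
        assert diag.alpha_norm + diag.beta_norm == pytest.approx(1.0, abs=1e-12)

    def test_zero_deviation_matrix_is_error(self):
        u = WeightVector(np.array([0.5, 0.5]), "bp")
        v = WeightVector(np.array([0.4, 0.6]), "rf")
        with pytest.raises(DataError):
            md_combine(u, v, np.ones((5, 2)))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_matches_dense_grid_search_oracle(self, seed):
        # Independent oracle: maximize Z(theta) = A cos(theta) + B sin(theta)
        # by dense search over the positive quarter circle.
        rng = np.random.default_rng(seed)
        u = WeightVector.normalized(rng.uniform(0.05, 1, 5), "bp")
        v = WeightVector.normalized(rng.uniform(0.05, 1, 5), "rf")
        R = rng.uniform(size=(12, 5))
        _, diag = md_combine(u, v, R)
        D = ((R - R.mean(axis=0)) ** 2).sum(axis=0)
        A, B = D @ u.weights, D @ v.weights
        thetas = np.linspace(1e-9, np.pi / 2 - 1e-9, 2_000_001)
        Z = A * np.cos(thetas) + B * np.sin(thetas)
        best = thetas[Z.argmax()]
        assert diag.alpha == pytest.approx(np.cos(best), abs=1e-6)
        assert diag.beta == pytest.approx(np.sin(best), abs=1e-6)


@pytest.mark.parametrize("provenance", ["bp", "rf", "combined"])
def test_weight_vector_invariants(provenance):
    w = WeightVector.normalized(np.array([1.0, 2.0, 3.0]), provenance)
    assert (w.weights >= 0).all()
    assert w.weights.sum() == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(DataError):
        WeightVector(np.array([0.5, 0.6]), provenance)  # does not sum to 1
    with pytest.raises(DataError):
        WeightVector(np.array([-0.2, 1.2]), provenance)  # negative entry
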