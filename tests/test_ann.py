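"""Network activations, gradients, training dynamics, and evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stratomics.ann import (
    AnnModel,
    TrainConfig,
    _loss_and_grads,
    error_rate,
    forward,
    init_ann,
    predict_class,
    purelin,
    tansig,
    train,
)
from stratomics.config import InvalidConfigError


class TestActivations:
    def test_tansig_values(self):
        assert tansig(0.0) == 0.0
        assert tansig(1.0) == pytest.approx(np.tanh(1.0))
        # the rational form -1 + 2/(1+exp(-2n)) is algebraically tanh
        for n in (-3.0, -0.5, 0.2, 4.0):
            assert tansig(n) == pytest.approx(-1 + 2 / (1 + np.exp(-2 * n)),
                                              abs=1e-12)

    def test_tansig_saturation(self):
        assert tansig(20.0) == pytest.approx(1.0, abs=1e-12)
        assert tansig(-20.0) == pytest.approx(-1.0, abs=1e-12)
        assert np.isfinite(tansig(1e6))

    @given(hst.floats(min_value=-50, max_value=50))
    @settings(max_examples=50, deadline=None)
    def test_tansig_odd_symmetry(self, n):
        assert tansig(-n) == pytest.approx(-tansig(n), abs=1e-12)

    def test_purelin_identity(self):
        assert purelin(0.0) == 0.0
        assert purelin(-3.7) == -3.7
        v = np.array([1.0, -2.0, 0.5])
        np.testing.assert_array_equal(purelin(v), v)


class TestInitAndForward:
    def test_seeded_determinism_and_shapes(self):
        cfg = TrainConfig(seed=5)
        a = init_ann(5, 10, cfg)
        b = init_ann(5, 10, cfg)
        assert a.w_hidden.shape == (10, 5)
        np.testing.assert_array_equal(a.w_hidden, b.w_hidden)
        np.testing.assert_array_equal(a.w_out, b.w_out)

    def test_zero_init_outputs_bias(self):
        m = init_ann(3, 4, TrainConfig(init_scale=0.0))
        m.b_out = 0.25
        np.testing.assert_allclose(forward(m, np.random.normal(size=(6, 3))), 0.25)

    def test_hand_evaluated_single_unit(self):
        m = AnnModel(np.array([[1.0]]), np.array([0.0]), np.array([2.0]), 1.0, 1)
        assert forward(m, np.array([[0.0]]))[0] == pytest.approx(1.0)
        assert forward(m, np.array([[1.0]]))[0] == pytest.approx(1 + 2 * np.tanh(1))

    def test_dimension_mismatch(self):
        m = init_ann(3, 2, TrainConfig())
        with pytest.raises(ValueError):
            forward(m, np.zeros((4, 5)))

    def test_invalid_counts(self):
        with pytest.raises(InvalidConfigError):
            init_ann(0, 3, TrainConfig())


class TestGradients:
    def test_analytic_matches_central_differences(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 4))
        y = rng.integers(0, 2, size=12).astype(float)
        m = init_ann(4, 3, TrainConfig(seed=2))
        _, (g_wh, g_bh, g_wo, g_bo) = _loss_and_grads(m, X, y)
        eps = 1e-6

        def loss_of(model):
            return _loss_and_grads(model, X, y)[0]

        def check(get, set_, analytic):
            flat = get(m).ravel() if hasattr(get(m), "ravel") else None
            if flat is None:  # scalar b_out
                m2 = m.copy(); m2.b_out += eps
                m3 = m.copy(); m3.b_out -= eps
                num = (loss_of(m2) - loss_of(m3)) / (2 * eps)
                assert num == pytest.approx(analytic, rel=1e-6, abs=1e-10)
                return
            for i in range(flat.size):
                m2, m3 = m.copy(), m.copy()
                get(m2).ravel()[i] += eps
                get(m3).ravel()[i] -= eps
                num = (loss_of(m2) - loss_of(m3)) / (2 * eps)
                assert num == pytest.approx(analytic.ravel()[i],
                                            rel=1e-5, abs=1e-9)

        check(lambda mm: mm.w_hidden, None, g_wh)
        check(lambda mm: mm.b_hidden, None, g_bh)
        check(lambda mm: mm.w_out, None, g_wo)
        check(lambda mm: 0.0, None, g_bo)


class TestTraining:
    def test_plain_gd_reduction(self):
        """momentum 0 and a frozen rate reproduce textbook gradient descent."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, size=30).astype(float)
        cfg = TrainConfig(learning_rate=0.01, momentum=0.0, lr_increase=1.0,
                          lr_decrease=1.0, error_ratio_limit=1e9,
                          max_epochs=10, seed=3, early_stop_tol=0.0)
        m0 = init_ann(3, 4, cfg)
        trained, _ = train(m0, X, y, cfg)

        # independent plain-GD oracle
        m = m0.copy()
        for _ in range(10):
            _, (g_wh, g_bh, g_wo, g_bo) = _loss_and_grads(m, X, y)
            m.w_hidden -= 0.01 * g_wh
            m.b_hidden -= 0.01 * g_bh
            m.w_out -= 0.01 * g_wo
            m.b_out -= 0.01 * g_bo
        np.testing.assert_allclose(trained.w_hidden, m.w_hidden, atol=1e-10)
        np.testing.assert_allclose(trained.w_out, m.w_out, atol=1e-10)
        np.testing.assert_allclose(trained.b_out, m.b_out, atol=1e-10)

    def test_descent_property_small_rate(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, size=40).astype(float)
        cfg = TrainConfig(learning_rate=1e-3, momentum=0.0, lr_increase=1.0,
                          lr_decrease=1.0, max_epochs=100, seed=4,
                          early_stop_tol=0.0)
        m = init_ann(3, 5, cfg)
        _, trace = train(m, X, y, cfg)
        diffs = np.diff(trace.mse)
        assert (diffs <= 1e-12).all()

    def test_separable_data_reaches_zero_training_error(self):
        rng = np.random.default_rng(10)
        n = 200
        X = np.column_stack([rng.normal(size=n), rng.normal(size=n)])
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(float)
        X[y == 1] += 1.5  # widen the margin
        cfg = TrainConfig(max_epochs=2000, seed=5)
        m = init_ann(2, 5, cfg)
        m, _ = train(m, X, y, cfg)
        assert error_rate(predict_class(m, X), y) == 0.0

    def test_xor_solvable_for_some_seed(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1.0]]) * 2 - 1
        y = np.array([0, 1, 1, 0.0])
        best = np.inf
        for seed in range(10):
            cfg = TrainConfig(max_epochs=3000, seed=seed, init_scale=1.0)
            m = init_ann(2, 2, cfg)
            m, trace = train(m, X, y, cfg)
            best = min(best, trace.mse[-1])
            if best < 0.01:
                break
        assert best < 0.01

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(25, 3))
        y = rng.integers(0, 2, size=25).astype(float)
        cfg = TrainConfig(max_epochs=50, seed=6)
        m = init_ann(3, 4, cfg)
        t1, _ = train(m, X, y, cfg)
        perm = rng.permutation(25)
        t2, _ = train(m, X[perm], y[perm], cfg)
        np.testing.assert_allclose(t1.w_hidden, t2.w_hidden, atol=1e-12)


class TestEvaluation:
    def test_predict_threshold_boundary(self):
        m = AnnModel(np.zeros((1, 1)), np.zeros(1), np.zeros(1), 0.5, 1)
        # constant score exactly at threshold -> class 1
        assert (predict_class(m, np.zeros((3, 1))) == 1).all()

    def test_sign_rule_equivalence(self):
        rng = np.random.default_rng(12)
        m = init_ann(2, 3, TrainConfig(seed=7))
        X = rng.normal(size=(20, 2))
        scores = forward(m, X)
        # shifting targets to +-1 and thresholding at 0 is the same partition
        assert ((scores >= 0.5) == ((2 * scores - 1) >= 0)).all()

    def test_error_rate_counting(self):
        assert error_rate(np.array([1, 1, 0, 0]), np.array([1, 1, 0, 0])) == 0.0
        assert error_rate(np.array([1, 0]), np.array([0, 1])) == 1.0
        pred = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        truth = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        assert error_rate(pred, truth) == 0.25

    def test_error_rate_empty_rejected(self):
        with pytest.raises(ValueError):
            error_rate(np.array([]), np.array([]))
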