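"""Network forward pass, analytic Jacobian, data division and LM training."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fracbc import (
    NetworkWeights,
    ScalingSpec,
    TrainingConfig,
    forward,
    initialize_weights,
    initialize_weights_boundary_layer,
    jacobian,
    split_data,
    train_lm,
)
from fracbc.surrogate import _lm_step, load_model, save_model


def _random_weights(rng, H=4):
    return NetworkWeights(
        rng.normal(size=H), rng.normal(size=H),
        rng.normal(size=(5, H)), rng.normal(size=5),
    )


class TestSplitData:
    def test_stated_rounding_rule(self):
        cfg = TrainingConfig(seed=3)
        s101 = split_data(101, cfg)
        assert (s101.training.size, s101.validation.size, s101.test.size) == (83, 9, 9)
        s100 = split_data(100, cfg)
        assert (s100.training.size, s100.validation.size, s100.test.size) == (82, 9, 9)

    def test_deterministic_given_seed(self):
        cfg = TrainingConfig(seed=11)
        a, b = split_data(101, cfg), split_data(101, cfg)
        np.testing.assert_array_equal(a.training, b.training)
        np.testing.assert_array_equal(a.validation, b.validation)
        np.testing.assert_array_equal(a.test, b.test)
        other = split_data(101, TrainingConfig(seed=12))
        assert not np.array_equal(a.training, other.training)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            split_data(11, TrainingConfig())


class TestForward:
    def test_zero_network_outputs_zero(self):
        w = NetworkWeights(np.zeros(3), np.zeros(3), np.zeros((5, 3)), np.zeros(5))
        np.testing.assert_array_equal(forward(w, [0.0, 0.5, -1.0]), np.zeros((3, 5)))

    def test_single_unit_closed_form(self):
        # logsig(0) = 0.5 through an output weight of 2 gives exactly 1
        w = NetworkWeights([0.0], [0.0], np.array([[2.0]] * 5), np.zeros(5))
        np.testing.assert_allclose(forward(w, [-0.7, 0.0, 0.3]), np.ones((3, 5)))

    def test_matches_independent_scalar_loop(self):
        rng = np.random.default_rng(5)
        w = _random_weights(rng)
        t = 0.3
        expected = []
        for c in range(5):
            acc = w.output_biases[c]
            for k in range(w.n_hidden):
                z = w.input_weights[k] * t + w.hidden_biases[k]
                acc += w.output_weights[c, k] / (1.0 + math.exp(-z))
            expected.append(acc)
        np.testing.assert_allclose(forward(w, [t])[0], expected, rtol=1e-14)

    def test_rejects_non_finite_weights(self):
        with pytest.raises(ValueError, match="non-finite"):
            NetworkWeights([np.nan], [0.0], np.zeros((5, 1)), np.zeros(5))


class TestJacobian:
    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(0)
        w = _random_weights(rng, H=3)
        t = rng.uniform(-1, 1, 7)
        y = rng.normal(size=(7, 5))
        e, J = jacobian(w, t, y)
        theta = w.to_vector()
        eps = 1e-7
        J_fd = np.empty_like(J)
        for k in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            ep = (forward(NetworkWeights.from_vector(tp, 3), t) - y).ravel()
            em = (forward(NetworkWeights.from_vector(tm, 3), t) - y).ravel()
            J_fd[:, k] = (ep - em) / (2 * eps)
        assert np.max(np.abs(J - J_fd)) <= 1e-6

    def test_zero_output_weights_zero_input_weight_block(self):
        rng = np.random.default_rng(1)
        w = NetworkWeights(rng.normal(size=3), rng.normal(size=3),
                           np.zeros((5, 3)), rng.normal(size=5))
        _, J = jacobian(w, rng.uniform(-1, 1, 4), rng.normal(size=(4, 5)))
        np.testing.assert_array_equal(J[:, :6], np.zeros((20, 6)))

    def test_single_sample_single_unit_symbolic(self):
        # hand derivation for H = 1: y_c = w_c a + b_c, a = logsig(u t + b)
        u, b, wc, bc, t, target = 0.7, -0.2, 1.3, 0.4, 0.6, 0.9
        a = 1.0 / (1.0 + math.exp(-(u * t + b)))
        ap = a * (1.0 - a)
        w = NetworkWeights([u], [b], np.full((5, 1), wc), np.full(5, bc))
        e, J = jacobian(w, [t], np.full((1, 5), target))
        assert e[0] == pytest.approx(wc * a + bc - target)
        # columns: [d/du, d/db, d/dw_0..4, d/db_out_0..4]
        assert J[0, 0] == pytest.approx(wc * ap * t, rel=1e-12)
        assert J[0, 1] == pytest.approx(wc * ap, rel=1e-12)
        assert J[0, 2] == pytest.approx(a, rel=1e-12)
        assert J[0, 7] == pytest.approx(1.0)

    def test_dimension_mismatch_and_empty_input(self):
        rng = np.random.default_rng(2)
        w = _random_weights(rng)
        with pytest.raises(ValueError):
            jacobian(w, np.arange(3.0), np.zeros((4, 5)))
        with pytest.raises(ValueError, match="empty"):
            jacobian(w, np.array([]), np.zeros((0, 5)))


class TestInitialization:
    def test_reproducible_and_seed_sensitive(self):
        a = initialize_weights(15, 42)
        b = initialize_weights(15, 42)
        c = initialize_weights(15, 43)
        np.testing.assert_array_equal(a.to_vector(), b.to_vector())
        assert not np.array_equal(a.to_vector(), c.to_vector())

    def test_nguyen_widrow_scale_bound(self):
        # input weights have magnitude exactly 0.7 * H for a single input
        w = initialize_weights(15, 0)
        np.testing.assert_allclose(np.abs(w.input_weights), 0.7 * 15)
        # transition centers -b/w lie inside the scaled input range
        centers = -w.hidden_biases / w.input_weights
        assert np.all(np.abs(centers) <= 1.0)

    def test_boundary_layer_units_cluster_near_window_start(self):
        w = initialize_weights_boundary_layer(15, 0)
        centers = -w.hidden_biases / w.input_weights
        offsets = (centers + 1.0) / 2.0  # fraction of the window
        assert np.sum(offsets < 0.25) >= 7  # the clustered half

    def test_invalid_hidden_count(self):
        with pytest.raises(ValueError):
            initialize_weights(0, 1)


class TestScaling:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 10, 20))
        t[0], t[-1] = 0.0, 10.0
        y = rng.normal(size=(20, 5)) * rng.uniform(0.1, 100, 5)
        spec = ScalingSpec.fit(t, y)
        np.testing.assert_allclose(spec.unscale_y(spec.scale_y(y)), y,
                                   rtol=1e-12, atol=1e-12)
        scaled = spec.scale_y(y)
        assert scaled.min() >= -1.0 - 1e-12 and scaled.max() <= 1.0 + 1e-12

    def test_constant_channel_fallback(self):
        y = np.ones((10, 5))
        y[:, 0] = np.linspace(0, 1, 10)
        spec = ScalingSpec.fit(np.linspace(0, 1, 10), y)
        np.testing.assert_allclose(spec.unscale_y(spec.scale_y(y)), y, atol=1e-12)


class TestLevenbergMarquardtStep:
    def test_large_damping_shrinks_the_step(self):
        rng = np.random.default_rng(3)
        J = rng.normal(size=(40, 12))
        e = rng.normal(size=40)
        JtJ, Jte = J.T @ J, J.T @ e
        small = _lm_step(JtJ, Jte, 1.0)
        large = _lm_step(JtJ, Jte, 1e12)
        assert np.linalg.norm(large) < np.linalg.norm(small)

    def test_gauss_newton_limit_solves_linear_problem_exactly(self):
        # residual linear in the parameters: one undamped step lands on the optimum
        rng = np.random.default_rng(4)
        J = rng.normal(size=(30, 6))
        theta_star = rng.normal(size=6)
        e = J @ (np.zeros(6) - theta_star)
        step = _lm_step(J.T @ J, J.T @ e, 0.0)
        np.testing.assert_allclose(step, theta_star, rtol=1e-9)


class TestTrainLM:
    def test_zero_epoch_budget_returns_initial_weights(self):
        rng = np.random.default_rng(8)
        t = np.linspace(0, 1, 30)
        y = rng.normal(size=(30, 5))
        cfg = TrainingConfig(seed=1, max_epochs=0)
        split = split_data(30, cfg)
        weights, scaling, record = train_lm((t, y), split, cfg, seed=5)
        assert record.stop_reason == "epochs"
        assert record.n_epochs == 0
        expected = initialize_weights_boundary_layer(15, np.random.default_rng(5))
        np.testing.assert_array_equal(weights.to_vector(), expected.to_vector())

    def test_constant_targets_solved_by_output_layer_in_one_step(self):
        # with zero output weights the residual is linear in the output layer,
        # so one near-undamped LM step is a Gauss-Newton solve; the remaining
        # ~1e-19 is the double-precision floor of the damped normal equations
        t = np.linspace(0, 1, 40)
        y = np.tile(np.array([1.2, -0.3, 0.0, 7.5, 2.0]), (40, 1))
        cfg = TrainingConfig(seed=2, max_epochs=5, mu_initial=1e-12, min_gradient=0.0)
        split = split_data(40, cfg)
        init = initialize_weights_boundary_layer(15, np.random.default_rng(3))
        w0 = NetworkWeights(init.input_weights, init.hidden_biases,
                            np.zeros((5, 15)), np.zeros(5))
        _, _, record = train_lm((t, y), split, cfg, seed=3, initial_weights=w0)
        assert record.train_mse[1] <= 1e-18
        assert record.train_mse[-1] <= 1e-18

    def test_training_mse_monotone_over_accepted_steps(self, case1_trajectory):
        cfg = TrainingConfig(seed=5, max_epochs=120)
        split = split_data(101, cfg)
        _, _, record = train_lm(
            (case1_trajectory.t, case1_trajectory.states), split, cfg, seed=6
        )
        scaled = np.asarray(record.train_mse_scaled)
        assert np.all(np.diff(scaled) <= 1e-18)

    def test_bitwise_reproducible(self, case1_trajectory):
        cfg = TrainingConfig(seed=9, max_epochs=60, n_restarts=2)
        split = split_data(101, cfg)
        out1 = train_lm((case1_trajectory.t, case1_trajectory.states), split, cfg)
        out2 = train_lm((case1_trajectory.t, case1_trajectory.states), split, cfg)
        np.testing.assert_array_equal(out1[0].to_vector(), out2[0].to_vector())
        assert out1[2].to_dict() == out2[2].to_dict()

    def test_stop_reason_set_exactly_once_and_valid(self, case1_trajectory):
        cfg = TrainingConfig(seed=4, max_epochs=200)
        split = split_data(101, cfg)
        _, _, record = train_lm(
            (case1_trajectory.t, case1_trajectory.states), split, cfg, seed=7
        )
        assert record.stop_reason in {
            "epochs", "goal", "min_gradient", "mu_max", "validation_failures"
        }
        assert 0 <= record.best_epoch <= record.n_epochs
        # returned best epoch is the argmin of the validation trace (earliest tie)
        va = np.asarray(record.validation_mse)
        assert record.best_epoch == int(np.argmin(va))

    def test_invalid_dataset_rejected(self):
        cfg = TrainingConfig()
        split = split_data(30, cfg)
        with pytest.raises(ValueError):
            train_lm((np.linspace(0, 1, 30), np.zeros((29, 5))), split, cfg)
        bad = np.zeros((30, 5))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train_lm((np.linspace(0, 1, 30), bad), split, cfg)


class TestModelSerialization:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        w = _random_weights(rng, H=6)
        spec = ScalingSpec(0.0, 1.0, np.zeros(5), np.ones(5))
        path = tmp_path / "model.json"
        save_model(path, w, spec, TrainingConfig())
        w2, spec2 = load_model(path)
        np.testing.assert_array_equal(w.to_vector(), w2.to_vector())
        assert spec2.to_dict() == spec.to_dict()


class TestTrainingConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"hidden_units": 0},
            {"split_fractions": (0.8, 0.1, 0.2)},
            {"mu_decrease": 1.5},
            {"mu_initial": 0.0},
            {"n_restarts": 0},
            {"init_scheme": "bogus"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainingConfig(**kwargs)
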