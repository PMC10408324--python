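import dataclasses

import numpy as np
import pytest

from nihlnet.features import FeatureSpec
from nihlnet.mlp import MLPArchitecture, MLPParameters
from nihlnet.simulate import SimulationConfig, simulate_control, simulate_exposed
from nihlnet.train import (
    Dataset,
    TrainingConfig,
    TrainingDivergedError,
    cross_validate,
    grid_search,
    init_parameters,
    loss_gradients,
    retrain_stability,
    train,
    weighted_loss,
)


def _random_problem(seed, n=12, n_inputs=4, layers=2, units=3):
    rng = np.random.default_rng(seed)
    arch = MLPArchitecture(n_inputs, layers, units)
    params = init_parameters(arch, rng)
    X = rng.normal(size=(n, n_inputs))
    y = (rng.random(n) < 0.5).astype(float)
    return params, X, y


def _numerical_gradients(params, X, y, cw, l2, h=1e-6):
    """Central finite differences over every weight and bias entry."""
    grads_W, grads_b = [], []
    for li in range(params.n_layers):
        gW = np.zeros_like(params.weights[li])
        for idx in np.ndindex(*params.weights[li].shape):
            params.weights[li][idx] += h
            up = weighted_loss(params, X, y, cw, l2)
            params.weights[li][idx] -= 2 * h
            down = weighted_loss(params, X, y, cw, l2)
            params.weights[li][idx] += h
            gW[idx] = (up - down) / (2 * h)
        grads_W.append(gW)
        gb = np.zeros_like(params.biases[li])
        for idx in np.ndindex(*params.biases[li].shape):
            params.biases[li][idx] += h
            up = weighted_loss(params, X, y, cw, l2)
            params.biases[li][idx] -= 2 * h
            down = weighted_loss(params, X, y, cw, l2)
            params.biases[li][idx] += h
            gb[idx] = (up - down) / (2 * h)
        grads_b.append(gb)
    return grads_W, grads_b


class TestLossAndGradients:
    def test_perfect_prediction_limit_has_zero_loss(self):
        # a single exposed sample pushed to p ~ 1 by a large output bias
        params = MLPParameters(
            [np.zeros((2, 3)), np.zeros((1, 2))], [np.zeros(2), np.array([30.0])]
        )
        loss = weighted_loss(params, np.zeros((1, 3)), np.array([1.0]), 3.0, 0.0)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_l2_penalty_zero_for_zero_weights(self):
        params = MLPParameters(
            [np.zeros((2, 3)), np.zeros((1, 2))], [np.ones(2), np.ones(1)]
        )
        with_l2 = weighted_loss(params, np.zeros((2, 3)), np.array([1.0, 0.0]), 3.0, 0.01)
        without = weighted_loss(params, np.zeros((2, 3)), np.array([1.0, 0.0]), 3.0, 0.0)
        assert with_l2 == without  # biases are not penalized

    def test_empty_dataset_rejected(self):
        params, X, y = _random_problem(0)
        with pytest.raises(ValueError, match="empty"):
            weighted_loss(params, X[:0], y[:0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("cw,l2", [(1.0, 0.0), (3.0, 0.01)])
    def test_analytic_gradients_match_finite_differences(self, seed, cw, l2):
        params, X, y = _random_problem(seed)
        loss, gW, gb = loss_gradients(params, X, y, cw, l2)
        assert loss == pytest.approx(weighted_loss(params, X, y, cw, l2), rel=1e-12)
        nW, nb = _numerical_gradients(params, X, y, cw, l2)
        for a, n in zip(gW + gb, nW + nb):
            scale = np.maximum(np.abs(n), 1e-8)
            assert np.max(np.abs(a - n) / scale) < 1e-6

    def test_class_weighting_equals_sample_triplication(self):
        """Full-batch weight-3 loss and gradient equal those of the
        unweighted loss on a dataset with every exposed sample tripled."""
        params, X, y = _random_problem(7)
        exposed = y == 1
        X_dup = np.vstack([X, X[exposed], X[exposed]])
        y_dup = np.concatenate([y, y[exposed], y[exposed]])

        loss_w, gW_w, gb_w = loss_gradients(params, X, y, 3.0, 0.01)
        loss_d, gW_d, gb_d = loss_gradients(params, X_dup, y_dup, 1.0, 0.01)
        assert loss_w == pytest.approx(loss_d, rel=1e-12)
        for a, b in zip(gW_w + gb_w, gW_d + gb_d):
            np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-15)


def _toy_separable(n=30, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(loc=(-2.0, -2.0), scale=0.3, size=(n // 2, 2))
    X1 = rng.normal(loc=(2.0, 2.0), scale=0.3, size=(n - n // 2, 2))
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n // 2), np.ones(n - n // 2)])
    return Dataset(X, y)


class TestTrain:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        data = _toy_separable()
        config = TrainingConfig(learning_rate=0.05, seed=0)
        arch = MLPArchitecture(2, 1, 2)
        result = train(arch, config, data, data)
        from nihlnet.mlp import forward_batch

        pred = forward_batch(result.parameters, data.X) >= 0.5
        assert np.mean(pred == (data.y == 1)) == 1.0
        assert len(result.log) <= 500

    def test_fixed_seed_is_bit_reproducible(self):
        data = _toy_separable(seed=3)
        config = TrainingConfig(max_epochs=40, seed=12)
        arch = MLPArchitecture(2, 2, 3)
        r1 = train(arch, config, data, data)
        r2 = train(arch, config, data, data)
        for a, b in zip(
            r1.parameters.weights + r1.parameters.biases,
            r2.parameters.weights + r2.parameters.biases,
        ):
            np.testing.assert_array_equal(a, b)
        assert [rec.val_loss for rec in r1.log] == [rec.val_loss for rec in r2.log]

    def test_early_stopping_returns_best_validation_epoch(self):
        rng = np.random.default_rng(5)
        train_data = _toy_separable(seed=5)
        # noisy validation labels force a val-loss minimum before the cap
        val_X = rng.normal(size=(20, 2))
        val_y = (rng.random(20) < 0.5).astype(float)
        config = TrainingConfig(learning_rate=0.05, max_epochs=200, patience=10, seed=5)
        result = train(MLPArchitecture(2, 1, 2), config, train_data, Dataset(val_X, val_y))
        best = result.log[result.best_epoch - 1].val_loss
        assert all(rec.val_loss >= best for rec in result.log)
        # patience respected: at most `patience` epochs follow the best one
        assert len(result.log) - result.best_epoch <= config.patience

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_divergence_reports_epoch(self):
        data = _toy_separable()
        config = TrainingConfig(learning_rate=1e200, max_epochs=20, seed=0)
        with pytest.raises(TrainingDivergedError, match="epoch"):
            train(MLPArchitecture(2, 1, 2), config, data, data)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(patience=600, max_epochs=500)
        with pytest.raises(ValueError):
            TrainingConfig(batch_size=0)


@pytest.fixture(scope="module")
def study_cohorts(aahl_table):
    config = SimulationConfig(seed=21)
    exposed = simulate_exposed(config, aahl_table, name="exp")
    control = simulate_control(config, aahl_table, name="ctl")
    return exposed, control


quick = dataclasses.replace(TrainingConfig(), max_epochs=2, patience=1, batch_size=None)


class TestCrossValidation:
    def test_fold_structure(self, study_cohorts, aahl_table):
        exposed, control = study_cohorts
        spec = FeatureSpec("HTL-right")
        result = cross_validate(
            MLPArchitecture(6, 1, 2), quick, exposed, control, spec, aahl_table
        )
        assert len(result.accuracies) == 10
        seen_e, seen_c = set(), set()
        for val_e, val_c in result.fold_indices:
            assert len(val_e) == 14 and len(val_c) == 9
            assert not seen_e & set(val_e) and not seen_c & set(val_c)
            seen_e |= set(val_e)
            seen_c |= set(val_c)
        # 143 exposed / 93 control: exactly 3 of each are never validated
        assert len(seen_e) == 140 and len(seen_c) == 90

    def test_mean_accuracy_is_arithmetic_mean(self, study_cohorts, aahl_table):
        exposed, control = study_cohorts
        result = cross_validate(
            MLPArchitecture(6, 1, 2), quick, exposed, control,
            FeatureSpec("HTL-left"), aahl_table,
        )
        assert result.mean_accuracy == pytest.approx(np.mean(result.accuracies))
        assert all(0.0 <= a <= 1.0 for a in result.accuracies)

    def test_different_seeds_give_different_valid_partitions(self, study_cohorts, aahl_table):
        exposed, control = study_cohorts
        spec = FeatureSpec("HTL-right")
        arch = MLPArchitecture(6, 1, 2)
        r1 = cross_validate(arch, quick, exposed, control, spec, aahl_table)
        r2 = cross_validate(
            arch, dataclasses.replace(quick, seed=99), exposed, control, spec, aahl_table
        )
        assert any(
            not np.array_equal(a[0], b[0]) for a, b in zip(r1.fold_indices, r2.fold_indices)
        )

    def test_insufficient_individuals_rejected(self, aahl_table):
        config = SimulationConfig(n_exposed=50, n_control=50, seed=1)
        small_e = simulate_exposed(config, aahl_table)
        small_c = simulate_control(config, aahl_table)
        with pytest.raises(ValueError, match="at least"):
            cross_validate(
                MLPArchitecture(6, 1, 2), quick, small_e, small_c,
                FeatureSpec("HTL-right"), aahl_table,
            )

    def test_default_config_reaches_high_validation_accuracy(self, study_cohorts, aahl_table):
        """On the reference synthetic study conditions the full published
        procedure separates exposed from controls well (threshold from a
        pilot of this generator, not a claim about real claimants)."""
        exposed, control = study_cohorts
        result = cross_validate(
            MLPArchitecture(18, 1, 2), TrainingConfig(seed=0), exposed, control,
            FeatureSpec("AAHL+HTL-right+HTL-left"), aahl_table,
        )
        assert result.mean_accuracy > 0.9


class TestGridSearch:
    def test_grid_has_twenty_points_and_valid_accuracies(self, study_cohorts, aahl_table):
        exposed, control = study_cohorts
        result = grid_search(
            FeatureSpec("HTL-right"), exposed, control, quick, aahl_table
        )
        assert len(result.results) == 20
        assert set(result.results) == {
            (l, u) for l in range(1, 6) for u in range(2, 6)
        }
        assert all(
            0.0 <= a <= 1.0 for r in result.results.values() for a in r.accuracies
        )
        assert result.best in result.results

    def test_best_configuration_reproducible_under_seed(self, study_cohorts, aahl_table):
        exposed, control = study_cohorts
        spec = FeatureSpec("HTL-right")
        r1 = grid_search(spec, exposed, control, quick, aahl_table)
        r2 = grid_search(spec, exposed, control, quick, aahl_table)
        assert r1.best == r2.best
        assert r1.best_result.accuracies == r2.best_result.accuracies


class TestRetrainStability:
    def test_single_repeat_degenerate_sd_with_warning(self, study_cohorts, aahl_table):
        exposed, control = study_cohorts
        with pytest.warns(UserWarning, match="degenerate"):
            summary = retrain_stability(
                exposed, control, exposed, control,
                FeatureSpec("HTL-right"), aahl_table, quick, n_repeats=1,
            )
        assert summary.sd_sensitivity == 0.0 and summary.sd_specificity == 0.0

    def test_repeats_summarized(self, study_cohorts, aahl_table):
        exposed, control = study_cohorts
        summary = retrain_stability(
            exposed, control, exposed, control,
            FeatureSpec("HTL-right"), aahl_table, quick, n_repeats=3,
        )
        assert len(summary.sensitivities) == 3
        assert summary.mean_sensitivity == pytest.approx(np.mean(summary.sensitivities))
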