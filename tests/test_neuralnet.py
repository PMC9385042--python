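import numpy as np
import pytest

from odorinverse import neuralnet as nn
from odorinverse.neuralnet import (
    MLPParams,
    NetworkError,
    TrainingConfig,
    compose_model,
    fine_tune,
    kfold_indices,
    load_model,
    make_pretraining_set,
    save_model,
    sigmoid_forward,
    train_sgd,
    xavier_init,
)


def hand_forward(params, x):
    """Per-neuron scalar oracle: evaluate each sigmoid unit with plain loops."""
    layers = [np.asarray(x, dtype=float)]
    for w, b in zip(params.weights, params.biases):
        prev = layers[-1]
        out = np.empty(w.shape[0])
        for j in range(w.shape[0]):
            a = b[j]
            for i in range(w.shape[1]):
                a += w[j, i] * prev[i]
            out[j] = 1.0 / (1.0 + np.exp(-a))
        layers.append(out)
    return layers


class TestForward:
    def test_zero_network_outputs_half_everywhere(self):
        p = MLPParams([3, 4, 2], [np.zeros((4, 3)), np.zeros((2, 4))], [np.zeros(4), np.zeros(2)])
        acts = sigmoid_forward(p, np.array([0.3, -1.0, 5.0]))
        np.testing.assert_array_equal(acts[1], 0.5 * np.ones(4))
        np.testing.assert_array_equal(acts[2], 0.5 * np.ones(2))

    def test_matches_per_neuron_oracle(self):
        rng = np.random.default_rng(4)
        p = xavier_init([3, 4, 2], rng, gain=2.0)
        x = rng.uniform(size=3)
        fast = sigmoid_forward(p, x)
        slow = hand_forward(p, x)
        for f, s in zip(fast, slow):
            np.testing.assert_allclose(f, s, rtol=1e-12)

    def test_batch_and_single_agree(self):
        rng = np.random.default_rng(5)
        p = xavier_init([4, 3, 2], rng)
        X = rng.uniform(size=(6, 4))
        batch_out = sigmoid_forward(p, X)[-1]
        for i in range(6):
            np.testing.assert_allclose(sigmoid_forward(p, X[i])[-1], batch_out[i], rtol=1e-12)

    def test_dimension_mismatch(self):
        p = xavier_init([4, 3], np.random.default_rng(0))
        with pytest.raises(NetworkError, match="dimension"):
            sigmoid_forward(p, np.zeros(5))


class TestXavierInit:
    def test_bound_and_zero_biases(self):
        p = xavier_init([4, 3], np.random.default_rng(1))
        bound = np.sqrt(6.0 / 7.0)
        assert np.all(np.abs(p.weights[0]) <= bound)
        assert np.all(p.biases[0] == 0.0)

    def test_deterministic_under_seed(self):
        a = xavier_init([5, 4, 3], np.random.default_rng(42))
        b = xavier_init([5, 4, 3], np.random.default_rng(42))
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_empirical_variance_matches_uniform_moment(self):
        # Var of U(-a, a) is a^2/3 = 2/(n_in+n_out) for the Glorot bound
        rng = np.random.default_rng(7)
        n_in, n_out = 40, 60
        draws = np.concatenate(
            [xavier_init([n_in, n_out], rng).weights[0].ravel() for _ in range(42)]
        )
        assert draws.size >= 1e5
        expected = 2.0 / (n_in + n_out)
        assert abs(draws.var() / expected - 1.0) < 0.05


class TestBackpropGradients:
    def test_gradient_matches_central_finite_differences(self):
        """Backprop on a random 4-5-3 net vs central differences on every parameter."""
        rng = np.random.default_rng(11)
        p = xavier_init([4, 5, 3], rng, gain=1.5)
        X = rng.uniform(size=(7, 4))
        T = rng.uniform(0.1, 0.9, size=(7, 3))
        lam = 1e-3
        loss0, gw, gb = nn._backprop(p, X, T, lam)
        eps = 1e-6

        def loss_at(params):
            out = sigmoid_forward(params, X)[-1]
            return 0.5 * np.sum((out - T) ** 2) / X.shape[0] + 0.5 * lam * sum(
                np.sum(w**2) for w in params.weights
            )

        for k in range(len(p.weights)):
            for arr, grad in ((p.weights[k], gw[k]), (p.biases[k], gb[k])):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    lp = loss_at(p)
                    arr[idx] = orig - eps
                    lm = loss_at(p)
                    arr[idx] = orig
                    fd = (lp - lm) / (2 * eps)
                    denom = max(abs(fd), 1e-8)
                    assert abs(grad[idx] - fd) / denom < 1e-5


class TestTrainSgd:
    def test_learning_rate_schedule(self):
        # eta_tau = eta0 * gamma**tau: third step under the standard schedule
        cfg = TrainingConfig(eta0=0.5, gamma=0.99, n_updates=3)
        assert cfg.eta0 * cfg.gamma**2 == pytest.approx(0.49005)

    def test_loss_decreases_without_momentum_or_ridge(self):
        rng = np.random.default_rng(3)
        p = xavier_init([3, 4, 2], rng)
        X = rng.uniform(size=(10, 3))
        T = rng.uniform(0.2, 0.8, size=(10, 2))
        cfg = TrainingConfig(eta0=0.05, gamma=1.0, alpha=0.0, lambda_reg=0.0, n_updates=10)
        _, losses = train_sgd(p, X, T, cfg)
        assert len(losses) == 10
        assert np.all(np.diff(losses) < 0)

    def test_monotone_nonincreasing_full_batch_small_eta(self):
        rng = np.random.default_rng(9)
        p = xavier_init([4, 6, 3], rng)
        X = rng.uniform(size=(20, 4))
        T = rng.uniform(0.1, 0.9, size=(20, 3))
        cfg = TrainingConfig(eta0=0.02, gamma=1.0, alpha=0.0, lambda_reg=0.0, n_updates=50)
        _, losses = train_sgd(p, X, T, cfg)
        assert np.all(np.diff(losses) <= 1e-15)

    def test_large_ridge_shrinks_weights(self):
        rng = np.random.default_rng(13)
        p = xavier_init([3, 3, 2], rng)
        X = rng.uniform(size=(5, 3))
        T = rng.uniform(size=(5, 2))
        cfg = TrainingConfig(eta0=0.1, gamma=1.0, alpha=0.0, lambda_reg=10.0, n_updates=20)
        trained, _ = train_sgd(p, X, T, cfg)
        before = sum(np.sum(w**2) for w in p.weights)
        after = sum(np.sum(w**2) for w in trained.weights)
        assert after < before

    def test_zero_updates_returns_equal_params(self):
        rng = np.random.default_rng(1)
        p = xavier_init([3, 2], rng)
        cfg = TrainingConfig(eta0=0.1, n_updates=0)
        trained, losses = train_sgd(p, rng.uniform(size=(4, 3)), rng.uniform(size=(4, 2)), cfg)
        assert losses.size == 0
        np.testing.assert_array_equal(trained.weights[0], p.weights[0])


class TestPretrainingSet:
    def test_unit_max_and_support(self, tiny_library):
        rng = np.random.default_rng(2)
        mixtures = make_pretraining_set(tiny_library, 40, k_components=3, rng=rng)
        assert len(mixtures) == 40
        for m in mixtures:
            assert m.intensities.max() == pytest.approx(1.0)

    def test_k1_gives_renormalized_members(self, tiny_library):
        rng = np.random.default_rng(2)
        mixtures = make_pretraining_set(tiny_library, 10, k_components=1, rng=rng)
        originals = {tuple(np.round(s.intensities / s.intensities.max(), 12)) for s in tiny_library}
        for m in mixtures:
            assert tuple(np.round(m.intensities, 12)) in originals

    def test_library_too_small(self, tiny_library):
        with pytest.raises(NetworkError, match="k_components"):
            make_pretraining_set(tiny_library, 5, k_components=6)


class TestComposeAndFineTune:
    def test_default_dims_give_nine_layer_stack(self):
        rng = np.random.default_rng(0)
        enc = xavier_init([212, 85, 70], rng)
        conv = xavier_init([70, 30, 70, 45, 15], rng)
        dec = xavier_init([15, 20, 21], rng)
        model = compose_model(enc, conv, dec)
        assert model.combined.layer_sizes == [212, 85, 70, 30, 70, 45, 15, 20, 21]
        assert model.combined.n_layers == 9

    def test_composition_preserves_predictions_exactly(self):
        rng = np.random.default_rng(8)
        enc = xavier_init([10, 6, 4], rng, gain=2.0)
        conv = xavier_init([4, 5, 5, 5, 3], rng, gain=2.0)
        dec = xavier_init([3, 4, 21], rng, gain=2.0)
        model = compose_model(enc, conv, dec)
        x = rng.uniform(size=10)
        sequential = sigmoid_forward(dec, sigmoid_forward(conv, sigmoid_forward(enc, x)[-1])[-1])[-1]
        combined = sigmoid_forward(model.combined, x)[-1]
        np.testing.assert_array_equal(combined, sequential)

    def test_junction_mismatch_names_sizes(self):
        rng = np.random.default_rng(0)
        enc = xavier_init([10, 6, 4], rng)
        conv = xavier_init([5, 5, 3], rng)
        dec = xavier_init([3, 4, 21], rng)
        with pytest.raises(NetworkError, match="4.*5"):
            compose_model(enc, conv, dec)

    def test_fine_tune_zero_updates_is_identity(self):
        rng = np.random.default_rng(3)
        model = compose_model(
            xavier_init([8, 5, 3], rng), xavier_init([3, 4, 4, 4, 2], rng), xavier_init([2, 3, 21], rng)
        )
        X = rng.uniform(size=(5, 8))
        Y = rng.uniform(size=(5, 21))
        tuned, losses = fine_tune(model, X, Y, TrainingConfig(eta0=0.1, n_updates=0))
        assert losses.size == 0
        for w0, w1 in zip(model.combined.weights, tuned.combined.weights):
            np.testing.assert_array_equal(w0, w1)

    def test_fine_tune_reslices_parts_consistently(self):
        rng = np.random.default_rng(3)
        model = compose_model(
            xavier_init([8, 5, 3], rng), xavier_init([3, 4, 4, 4, 2], rng), xavier_init([2, 3, 21], rng)
        )
        X = rng.uniform(size=(5, 8))
        Y = rng.uniform(size=(5, 21))
        tuned, _ = fine_tune(model, X, Y, TrainingConfig(eta0=0.3, n_updates=5))
        x = rng.uniform(size=8)
        via_parts = sigmoid_forward(
            tuned.decoder_sensory,
            sigmoid_forward(tuned.converter, sigmoid_forward(tuned.encoder_ms, x)[-1])[-1],
        )[-1]
        np.testing.assert_array_equal(via_parts, sigmoid_forward(tuned.combined, x)[-1])


class TestKFold:
    def test_leave_one_out(self):
        folds = kfold_indices(12, 12, seed=0)
        assert len(folds) == 12
        assert all(len(test) == 1 for _, test in folds)

    def test_383_molecules_12_folds(self):
        folds = kfold_indices(383, 12, seed=1)
        sizes = sorted(len(test) for _, test in folds)
        assert set(sizes) <= {31, 32}
        all_test = np.sort(np.concatenate([test for _, test in folds]))
        np.testing.assert_array_equal(all_test, np.arange(383))

    def test_deterministic_under_seed(self):
        a = kfold_indices(50, 5, seed=9)
        b = kfold_indices(50, 5, seed=9)
        for (_, ta), (_, tb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(NetworkError):
            kfold_indices(5, 6)


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(17)
        model = compose_model(
            xavier_init([8, 5, 3], rng),
            xavier_init([3, 4, 4, 4, 2], rng),
            xavier_init([2, 3, 21], rng),
            ms_decoder=xavier_init([3, 5, 8], rng),
            sensory_norm=7.5,
        )
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        x = rng.uniform(size=8)
        np.testing.assert_array_equal(
            sigmoid_forward(back.combined, x)[-1], sigmoid_forward(model.combined, x)[-1]
        )
        assert back.sensory_norm == 7.5
        assert back.ms_decoder is not None
        assert back.encoder_ms.layer_sizes == model.encoder_ms.layer_sizes
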