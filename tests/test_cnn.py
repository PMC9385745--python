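"""Architecture contracts, training mechanics, epoch selection."""

import numpy as np
import pytest

from svdose import cnn, nn
from svdose.cnn import CNNConfig, TrainingHistory


def _analytic_param_count(input_shape, filters=(16, 32, 64, 64),
                          dense=(256, 64)):
    total, c_in = 0, 1
    for f in filters:
        total += 27 * c_in * f + f
        c_in = f
    n_flat = (np.prod(input_shape) // 16**3) * filters[-1]
    n_in = n_flat
    for u in dense:
        total += n_in * u + u
        n_in = u
    return int(total + n_in + 1)


class TestBuildModel:
    def test_pooling_arithmetic_at_64(self):
        model = cnn.build_model(CNNConfig(seed=0), (64, 64, 64))
        text = cnn.summarize(model)
        for ext in (32, 16, 8, 4):
            assert f"({ext}, {ext}, {ext}," in text

    def test_filter_counts_read_back(self):
        model = cnn.build_model(CNNConfig(seed=0), (16, 16, 16))
        convs = [l for l in model.layers if isinstance(l, nn.Conv3D)]
        assert tuple(l.c_out for l in convs) == (16, 32, 64, 64)
        dense = [l for l in model.layers if isinstance(l, nn.Dense)]
        assert tuple(l.weight.shape[1] for l in dense) == (256, 64, 1)

    def test_parameter_count_is_pure_function_of_shape(self):
        for shape in ((16, 16, 16), (64, 64, 64), (32, 48, 32)):
            model = cnn.build_model(CNNConfig(seed=3), shape)
            assert model.n_params == _analytic_param_count(shape)

    def test_seed_does_not_change_architecture(self):
        a = cnn.build_model(CNNConfig(seed=1), (16, 16, 16))
        b = cnn.build_model(CNNConfig(seed=99), (16, 16, 16))
        assert cnn.summarize(a) == cnn.summarize(b)

    def test_too_small_input_names_axis(self):
        with pytest.raises(ValueError, match="width"):
            cnn.build_model(CNNConfig(seed=0), (16, 8, 16))
        with pytest.raises(ValueError, match="depth"):
            cnn.build_model(CNNConfig(seed=0), (16, 16, 24))

    def test_architecture_is_fixed(self):
        with pytest.raises(ValueError):
            CNNConfig(conv_filters=(16, 32, 64))
        with pytest.raises(ValueError):
            CNNConfig(dense_units=(256,))


class TestGradients:
    def test_dense_gradient_numerical(self):
        rng = np.random.default_rng(0)
        layer = nn.Dense(5, 3, rng)
        x = rng.normal(size=(4, 5)).astype(np.float32)
        y = layer.forward(x, train=True)
        dy = rng.normal(size=y.shape).astype(np.float32)
        layer.backward(dy)
        eps = 1e-3
        w0 = layer.weight[2, 1]
        layer.weight[2, 1] = w0 + eps
        up = (layer.forward(x) * dy).sum()
        layer.weight[2, 1] = w0 - eps
        dn = (layer.forward(x) * dy).sum()
        layer.weight[2, 1] = w0
        assert layer.grads[0][2, 1] == pytest.approx((up - dn) / (2 * eps), rel=1e-2)

    def test_conv_gradient_numerical(self):
        rng = np.random.default_rng(1)
        layer = nn.Conv3D(2, 3, rng)
        x = rng.normal(size=(2, 4, 4, 4, 2)).astype(np.float32)
        y = layer.forward(x, train=True)
        dy = rng.normal(size=y.shape).astype(np.float32)
        dx = layer.backward(dy)
        eps = 1e-3
        idx = (1, 2, 3, 1, 0)
        x2 = x.copy()
        x2[idx] += eps
        up = (layer.forward(x2) * dy).sum()
        x2[idx] -= 2 * eps
        dn = (layer.forward(x2) * dy).sum()
        assert dx[idx] == pytest.approx((up - dn) / (2 * eps), rel=1e-2)

    def test_pool_routes_gradient_to_argmax(self):
        pool = nn.MaxPool3D()
        x = np.zeros((1, 2, 2, 2, 1), dtype=np.float32)
        x[0, 1, 0, 1, 0] = 5.0
        out = pool.forward(x, train=True)
        assert out[0, 0, 0, 0, 0] == 5.0
        dx = pool.backward(np.ones_like(out))
        assert dx[0, 1, 0, 1, 0] == 1.0 and dx.sum() == 1.0


class TestLossFunctions:
    def test_bce_of_perfect_predictions_is_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert nn.bce_from_probs(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_bce_of_coin_flip_is_ln2(self):
        y = np.array([1, 0, 1, 0])
        p = np.full(4, 0.5)
        assert nn.bce_from_probs(p, y) == pytest.approx(np.log(2), abs=1e-12)
        z = np.zeros(4)
        assert nn.bce_with_logits(z, y) == pytest.approx(np.log(2), abs=1e-12)

    def test_logit_and_prob_losses_agree(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=20)
        y = rng.integers(0, 2, 20).astype(float)
        assert nn.bce_with_logits(z, y) == pytest.approx(
            nn.bce_from_probs(nn.sigmoid(z), y), rel=1e-10
        )


def _toy_data(n, shape, separation, seed):
    """Two classes of sparse blob volumes whose density differs by a
    factor `separation` (1.0 => identically distributed classes)."""
    rng = np.random.default_rng(seed)
    x = np.zeros((n, *shape, 1), dtype=np.float32)
    y = np.tile([1, 0], n // 2 + 1)[:n]
    for i in range(n):
        density = 0.08 * (separation if y[i] == 1 else 1.0)
        x[i, ..., 0] = (rng.uniform(size=shape) < density) * rng.uniform(
            0.5, 1.0, size=shape
        )
    return x, y


class TestTraining:
    def test_separable_classes_are_learned(self):
        """A 3x density contrast is learned to >= 90% train accuracy."""
        x, y = _toy_data(24, (16, 16, 16), separation=3.0, seed=0)
        cfg = CNNConfig(seed=1, epochs=10, batch_size=2, learning_rate=1e-3)
        model = cnn.build_model(cfg, (16, 16, 16))
        hist = cnn.train(model, x, y, x[:6], y[:6], cfg)
        assert hist.train_accuracy[-1] >= 0.9

    def test_identical_distributions_stay_near_chance(self):
        """With no class signal, held-out accuracy hovers around 0.5."""
        x, y = _toy_data(24, (16, 16, 16), separation=1.0, seed=3)
        xt, yt = _toy_data(16, (16, 16, 16), separation=1.0, seed=4)
        cfg = CNNConfig(seed=2, epochs=3, batch_size=2)
        model = cnn.build_model(cfg, (16, 16, 16))
        hist = cnn.train(model, x, y, xt, yt, cfg)
        opt = hist.optimal_epoch
        assert 0.2 <= hist.test_accuracy[opt - 1] <= 0.8

    def test_recorded_losses_recomputable_from_predictions(self):
        x, y = _toy_data(12, (16, 16, 16), separation=2.0, seed=5)
        cfg = CNNConfig(seed=3, epochs=2, batch_size=4)
        model = cnn.build_model(cfg, (16, 16, 16))
        hist = cnn.train(model, x, y, x[:4], y[:4], cfg)
        for e in range(hist.n_epochs):
            tp, tl = hist.train_predictions[e]
            assert nn.bce_from_probs(tp, tl) == pytest.approx(
                hist.train_loss[e], abs=1e-6
            )
            vp, vl = hist.test_predictions[e]
            assert nn.bce_from_probs(vp, vl) == pytest.approx(
                hist.test_loss[e], abs=1e-6
            )

    def test_checkpoint_predictions_match_recorded_loss(self, tmp_path):
        """Cross-entropy recomputed from checkpointed outputs equals the
        recorded test loss."""
        x, y = _toy_data(8, (16, 16, 16), separation=2.0, seed=6)
        cfg = CNNConfig(seed=4, epochs=2, batch_size=2)
        model = cnn.build_model(cfg, (16, 16, 16))
        hist = cnn.train(model, x, y, x[:4], y[:4], cfg, checkpoint_dir=tmp_path)
        for e in (1, 2):
            ck = np.load(tmp_path / f"epoch_{e:02d}.npz")
            loss = nn.bce_from_probs(ck["test_probs"], ck["test_labels"])
            assert loss == pytest.approx(hist.test_loss[e - 1], abs=1e-6)

    def test_training_reproducible_with_seed(self):
        x, y = _toy_data(10, (16, 16, 16), separation=2.0, seed=7)
        cfg = CNNConfig(seed=5, epochs=2, batch_size=2)
        hists = []
        for _ in range(2):
            model = cnn.build_model(cfg, (16, 16, 16))
            hists.append(cnn.train(model, x, y, x[:4], y[:4], cfg))
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].test_loss == hists[1].test_loss
        assert hists[0].test_accuracy == hists[1].test_accuracy

    def test_non_binary_labels_rejected(self):
        x, y = _toy_data(4, (16, 16, 16), separation=1.0, seed=8)
        cfg = CNNConfig(seed=0, epochs=1)
        model = cnn.build_model(cfg, (16, 16, 16))
        with pytest.raises(ValueError, match="binary"):
            cnn.train(model, x, y + 0.5, x, y, cfg)


class TestPredict:
    def test_zeroed_head_gives_half_probability(self):
        cfg = CNNConfig(seed=6)
        model = cnn.build_model(cfg, (16, 16, 16))
        head = model.layers[-1]
        head.weight[...] = 0.0
        head.bias[...] = 0.0
        x = np.random.default_rng(0).uniform(size=(3, 16, 16, 16, 1))
        probs, labels = cnn.predict(model, x, return_labels=True)
        assert np.allclose(probs, 0.5)
        # exact 0.5 goes to the negative (high-dose) class
        assert np.array_equal(labels, [0, 0, 0])

    def test_predict_deterministic(self):
        cfg = CNNConfig(seed=7)
        model = cnn.build_model(cfg, (16, 16, 16))
        x = np.random.default_rng(1).uniform(size=(2, 16, 16, 16, 1))
        assert np.array_equal(cnn.predict(model, x), cnn.predict(model, x))

    def test_probabilities_in_open_interval(self):
        cfg = CNNConfig(seed=8)
        model = cnn.build_model(cfg, (16, 16, 16))
        x = np.random.default_rng(2).uniform(size=(2, 16, 16, 16, 1))
        probs = cnn.predict(model, x)
        assert np.all((probs > 0) & (probs < 1))

    def test_shape_mismatch_rejected(self):
        cfg = CNNConfig(seed=9)
        model = cnn.build_model(cfg, (16, 16, 16))
        with pytest.raises(ValueError, match="shape"):
            cnn.predict(model, np.zeros((1, 8, 8, 8, 1)))


class TestEpochSelection:
    def _hist(self, test_loss, train_loss=None):
        n = len(test_loss)
        return TrainingHistory(
            train_accuracy=[0.5] * n,
            test_accuracy=[0.5] * n,
            train_loss=list(train_loss or np.linspace(1, 0.1, n)),
            test_loss=list(test_loss),
        )

    def test_monotone_decrease_selects_last(self):
        epoch, _ = cnn.select_optimal_epoch(self._hist([0.9, 0.7, 0.5, 0.3]))
        assert epoch == 4

    def test_argmin_with_rebound(self):
        epoch, _ = cnn.select_optimal_epoch(self._hist([0.9, 0.6, 0.4, 0.5, 0.7]))
        assert epoch == 3

    def test_tie_takes_earliest(self):
        epoch, _ = cnn.select_optimal_epoch(self._hist([0.5, 0.3, 0.3, 0.4]))
        assert epoch == 2

    def test_overfitting_history_flags_divergence(self):
        """Train loss falls monotonically while test loss turns upward: the
        turning point is selected and the divergence flag is set."""
        train = [1.0, 0.7, 0.5, 0.35, 0.25, 0.18]
        test = [0.9, 0.7, 0.55, 0.6, 0.7, 0.85]
        epoch, diverges = cnn.select_optimal_epoch(
            self._hist(test, train_loss=train)
        )
        assert epoch == 3 and diverges

    def test_no_divergence_when_test_loss_recovers(self):
        train = [1.0, 0.7, 0.5, 0.4, 0.3]
        test = [0.9, 0.5, 0.6, 0.55, 0.7]
        epoch, diverges = cnn.select_optimal_epoch(
            self._hist(test, train_loss=train)
        )
        assert epoch == 2 and not diverges

    def test_requires_two_epochs(self):
        with pytest.raises(ValueError):
            cnn.select_optimal_epoch(self._hist([0.5]))

    def test_history_validation(self):
        h = self._hist([0.5, 0.4])
        h.optimal_epoch = 5
        with pytest.raises(ValueError, match="optimal epoch"):
            h.validate()
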