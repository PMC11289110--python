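"""Binarization, training loop mechanics, backend contract, persistence."""

import numpy as np
import pytest

from cystseg import _nn
from cystseg.segmentation import (
    CystSegmenter,
    RedDarknessBaseline,
    TrainConfig,
    _TinyUNet,
    binarize,
    predict_image,
    train_reference_model,
)


def _tiny_data(rng, n=6, size=16):
    """Trivial scenes: a dark square on a bright plane, mask = the square."""
    X = np.zeros((n, size, size, 3), np.float32)
    y = np.zeros((n, size, size), bool)
    for i in range(n):
        X[i] += 1.0
        r, c = rng.integers(2, size - 6, 2)
        X[i, r:r + 4, c:c + 4, :] = -1.0
        y[i, r:r + 4, c:c + 4] = True
    return X, y


class TestBinarize:
    def test_all_zero_map(self):
        assert not binarize(np.zeros((4, 4))).any()

    def test_half_map_at_default_threshold_is_background(self):
        # strict inequality: exactly 0.5 does not clear a 0.5 threshold
        assert not binarize(np.full((4, 4), 0.5), 0.5).any()

    def test_checkerboard(self):
        p = np.indices((4, 4)).sum(axis=0) % 2 * 0.2 + 0.4  # 0.4 / 0.6
        np.testing.assert_array_equal(binarize(p), p > 0.5)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_threshold_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError, match="threshold"):
            binarize(np.zeros((2, 2)), bad)

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            binarize(np.full((2, 2), 1.7))


class TestScheduler:
    def test_restarts_at_t0_and_t0_times_tmult(self):
        lr = 1e-4
        rates = [_nn.cosine_warm_restart_lr(e, lr, t0=10, t_mult=2) for e in range(70)]
        assert rates[0] == pytest.approx(lr)
        assert rates[10] == pytest.approx(lr)   # first restart
        assert rates[30] == pytest.approx(lr)   # second restart (cycle of 20)
        assert rates[9] < rates[10]
        assert rates[29] < rates[30]
        # within a cycle the rate decays monotonically
        assert all(a >= b for a, b in zip(rates[10:30], rates[11:30]))

    def test_eta_min_floor(self):
        r = _nn.cosine_warm_restart_lr(9, 1e-4, t0=10, t_mult=2, eta_min=1e-6)
        assert r >= 1e-6


class TestTrainingLoop:
    def test_early_stopping_on_monotonically_worsening_iou(self, rng, monkeypatch):
        X, y = _tiny_data(rng)
        model = CystSegmenter(base_channels=2, patience=3, max_epochs=50, seed=0)
        ious = iter([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
        monkeypatch.setattr(CystSegmenter, "_val_iou", lambda self, Xv, yv: next(ious))
        model.fit(X, y, X_val=X, y_val=y)
        # stops after patience epochs without improvement, keeps epoch 1
        assert len(model.history_) == 4
        assert model.best_epoch_ == 1
        assert model.best_val_iou_ == 0.9

    def test_history_and_reproducibility(self, rng):
        X, y = _tiny_data(rng)
        kw = dict(base_channels=2, max_epochs=3, seed=42)
        m1 = CystSegmenter(**kw).fit(X, y, X_val=X, y_val=y)
        m2 = CystSegmenter(**kw).fit(X, y, X_val=X, y_val=y)
        assert list(m1.history_.columns) == ["epoch", "lr", "train_loss", "val_iou"]
        assert len(m1.history_) == 3
        np.testing.assert_allclose(m1.history_.train_loss, m2.history_.train_loss)
        np.testing.assert_allclose(m1.history_.val_iou, m2.history_.val_iou)

    def test_empty_train_set_rejected(self):
        model = CystSegmenter(base_channels=2)
        with pytest.raises(ValueError, match="empty"):
            model.fit(np.zeros((0, 8, 8, 3)), np.zeros((0, 8, 8), bool))

    def test_val_without_cyst_pixels_rejected(self, rng):
        X, y = _tiny_data(rng)
        with pytest.raises(ValueError, match="richer validation"):
            CystSegmenter(base_channels=2).fit(
                X, y, X_val=X, y_val=np.zeros_like(y))

    def test_train_reference_model_returns_history(self, rng):
        X, y = _tiny_data(rng)
        config = TrainConfig(max_epochs=2, base_channels=2, seed=1)
        model, history = train_reference_model(X[:4], y[:4], X[4:], y[4:], config)
        assert len(history) == 2
        assert hasattr(model, "net_")

    def test_learns_trivial_dark_square_task(self, rng):
        X, y = _tiny_data(rng, n=16, size=16)
        model = CystSegmenter(base_channels=4, max_epochs=25, learning_rate=1e-2,
                              t0=25, seed=0)
        model.fit(X, y, X_val=X, y_val=y)
        assert model.best_val_iou_ > 0.5


class TestGradients:
    def test_backward_matches_numerical_gradient(self):
        rng = np.random.default_rng(0)
        net = _TinyUNet(base=2, rng=rng)
        for layer in net.layers():
            layer.W = layer.W.astype(np.float64)
            layer.b = layer.b.astype(np.float64)
        x = rng.normal(size=(1, 8, 8, 3))
        t = (rng.random((1, 8, 8, 1)) < 0.3).astype(np.float64)

        def loss():
            z = net.forward(x)
            sp = np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))
            return float((sp - t * z).mean()), (1 / (1 + np.exp(-z)) - t) / z.size

        _, dz = loss()
        net.backward(dz)
        for layer in (net.e11, net.b2, net.d11, net.out, net.n21):
            analytic = layer.dW.copy()
            idx = np.unravel_index(int(rng.integers(layer.W.size)), layer.W.shape)
            eps, orig = 1e-6, layer.W[idx]
            layer.W[idx] = orig + eps
            lp, _ = loss()
            layer.W[idx] = orig - eps
            lm, _ = loss()
            layer.W[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(analytic[idx], rel=1e-4, abs=1e-10)


class TestPredictContract:
    def test_identical_input_identical_output(self, rng):
        X, y = _tiny_data(rng)
        model = CystSegmenter(base_channels=2, max_epochs=1, seed=0)
        model.fit(X, y, X_val=X, y_val=y)
        p1 = model.predict_proba(X[0])
        p2 = model.predict_proba(X[0])
        np.testing.assert_array_equal(p1, p2)
        assert p1.shape == X[0].shape[:2]
        assert 0.0 <= p1.min() and p1.max() <= 1.0

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            CystSegmenter().predict_proba(np.zeros((8, 8, 3)))

    def test_baseline_satisfies_backend_contract(self, rng):
        image = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        prob = predict_image(RedDarknessBaseline(), image)
        assert prob.shape == (16, 16)
        assert prob.min() >= 0 and prob.max() <= 1

    def test_backend_with_wrong_shape_rejected(self):
        bad = lambda image: np.zeros((4, 4))
        with pytest.raises(ValueError, match="shape"):
            predict_image(bad, np.zeros((8, 8, 3)))

    def test_baseline_finds_dark_lumen(self, five_cyst_scene):
        prob = RedDarknessBaseline().predict_proba(five_cyst_scene.image)
        pred = binarize(prob, 0.5)
        gt = five_cyst_scene.gt_mask
        assert (pred & gt).sum() / gt.sum() > 0.9  # lumens are dark -> recalled

    def test_sklearn_get_set_params_round_trip(self):
        model = CystSegmenter(base_channels=4, patience=7)
        params = model.get_params()
        assert params["patience"] == 7
        clone = CystSegmenter(**params)
        assert clone.get_params() == params


class TestPersistence:
    def test_checkpoint_round_trip(self, rng, tmp_path):
        X, y = _tiny_data(rng)
        model = CystSegmenter(base_channels=2, max_epochs=1, seed=0)
        model.fit(X, y, X_val=X, y_val=y)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        back = CystSegmenter.load(path)
        np.testing.assert_array_equal(back.predict_proba(X[0]),
                                      model.predict_proba(X[0]))

    def test_missing_checkpoint_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            CystSegmenter.load(tmp_path / "nope.npz")
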