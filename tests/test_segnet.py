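"""Network contracts, loss closed forms and oracle, gradient correctness,
training descent / early stopping, sliding-window stitching."""

import itertools

import numpy as np
import pytest

import cuffseg._nn as _nn
from cuffseg.preprocess import PatchSpec, normalize_intensity
from cuffseg.segnet import (
    NetworkConfig,
    TrainConfig,
    UNet,
    _loss_and_grad,
    build_network,
    combined_loss,
    load_model,
    predict,
    save_model,
    softmax,
    train,
)

TOY2D = NetworkConfig(dimensionality=2, n_classes=3, base_channels=2, depth=1)


class TestBuildNetwork:
    def test_depth_too_large_for_patch(self):
        cfg = NetworkConfig(dimensionality=3, n_classes=5, base_channels=2, depth=5)
        with pytest.raises(ValueError, match="incompatible"):
            build_network(cfg, seed=0, patch_shape=(16, 64, 64))

    def test_output_shape_matches_input(self):
        net = build_network(TOY2D, seed=0)
        x = np.zeros((2, 1, 16, 16), dtype=np.float32)
        assert net.forward(x).shape == (2, 3, 16, 16)

    def test_seeded_init_reproducible(self):
        a = build_network(TOY2D, seed=5)
        b = build_network(TOY2D, seed=5)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_parameter_count_deterministic_in_config(self):
        a = build_network(TOY2D, seed=1)
        b = build_network(TOY2D, seed=99)
        assert a.n_parameters() == b.n_parameters() > 0

    def test_checkpoint_roundtrip(self, tmp_path):
        net = build_network(TOY2D, seed=2)
        x = np.random.default_rng(0).normal(size=(1, 1, 8, 8)).astype(np.float32)
        save_model(net, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        np.testing.assert_allclose(back.forward(x), net.forward(x), atol=1e-6)


class TestCombinedLoss:
    def test_empty_empty_class_dice_term_zero(self):
        # class 2 absent from both prediction and target: eps guard gives
        # dice ratio eps/eps = 1, contribution 0
        p = np.zeros((3, 1, 2, 2))
        p[0] = 1.0
        y = p.copy()
        loss_small_eps = combined_loss(p, y, epsilon=1e-7)
        loss_large_eps = combined_loss(p, y, epsilon=1e-3)
        assert loss_small_eps == pytest.approx(loss_large_eps, abs=1e-6)

    def test_perfect_overlap_near_zero(self):
        rng = np.random.default_rng(1)
        y_int = rng.integers(0, 3, size=(1, 4, 4, 4))
        y = np.moveaxis(np.eye(3)[y_int], -1, 1)
        delta = 1e-6
        p = np.clip(y, delta, 1 - delta)
        p /= p.sum(axis=1, keepdims=True)
        assert combined_loss(p, y) == pytest.approx(0.0, abs=1e-3)

    def test_binary_uniform_half_cross_entropy(self):
        """Uniform 0.5 prediction over N voxels gives CE term N ln 2."""
        N = 64
        y_int = np.random.default_rng(0).integers(0, 2, size=N)
        y = np.moveaxis(np.eye(2)[y_int], -1, 0).reshape(2, 1, 1, N)
        p = np.full((2, 1, 1, N), 0.5)
        loss = combined_loss(p, y, epsilon=1e-5)
        dice = (2 * 0.5 * y[1].sum() + 1e-5) / (0.5 * N + y[1].sum() + 1e-5)
        assert loss - (1 - dice) == pytest.approx(N * np.log(2), abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            combined_loss(np.zeros((2, 2, 2, 2)), np.zeros((2, 2, 2, 3)))

    def test_minimized_at_target_brute_force(self):
        """2-voxel, 2-class toy: grid search over the simplex confirms the
        loss is minimized arbitrarily close to p = y."""
        y = np.zeros((2, 1, 1, 2))
        y[1, 0, 0, 0] = 1.0
        y[0, 0, 0, 1] = 1.0
        best, best_q = np.inf, None
        for q0, q1 in itertools.product(np.linspace(0.01, 0.99, 50), repeat=2):
            p = np.array([[[[1 - q0, 1 - q1]]], [[[q0, q1]]]])
            val = combined_loss(p, y, epsilon=1e-6)
            if val < best:
                best, best_q = val, (q0, q1)
        assert best_q[0] > 0.95  # voxel 0 -> class 1
        assert best_q[1] < 0.05  # voxel 1 -> class 0


class TestGradients:
    def test_loss_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(2, 3, 5, 5))
        y = rng.integers(0, 3, size=(2, 5, 5))
        w = (0.5, 1.0, 2.0)
        _, g = _loss_and_grad(logits, y, w, 1e-5)
        for _ in range(25):
            idx = tuple(rng.integers(s) for s in logits.shape)
            eps = 1e-5
            old = logits[idx]
            logits[idx] = old + eps
            lp, _ = _loss_and_grad(logits, y, w, 1e-5)
            logits[idx] = old - eps
            lm, _ = _loss_and_grad(logits, y, w, 1e-5)
            logits[idx] = old
            assert (lp - lm) / (2 * eps) == pytest.approx(float(g[idx]), abs=1e-6)

    def test_full_network_gradient_matches_finite_differences(self, monkeypatch):
        """End-to-end backprop check in float64 on a small 2-level U-Net."""
        monkeypatch.setattr(_nn, "DTYPE", np.float64)
        rng = np.random.default_rng(0)
        cfg = NetworkConfig(dimensionality=2, n_classes=3, base_channels=2, depth=2)
        net = UNet(cfg, seed=3)
        x = rng.normal(size=(2, 1, 8, 8))
        y = rng.integers(0, 3, size=(2, 8, 8))

        def loss():
            return _loss_and_grad(net.forward(x), y, None, 1e-5)

        _, g = loss()
        for p in net.params():
            p.grad[...] = 0
        net.backward(g)
        params = net.params()
        check = np.random.default_rng(1)
        for _ in range(40):
            p = params[check.integers(len(params))]
            idx = tuple(check.integers(s) for s in p.value.shape)
            eps = 1e-6
            old = p.value[idx]
            p.value[idx] = old + eps
            lp, _ = loss()
            p.value[idx] = old - eps
            lm, _ = loss()
            p.value[idx] = old
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(float(p.grad[idx]), abs=1e-6, rel=1e-4)


class TestTrain:
    def test_early_stopping_with_frozen_model(self, small_cohort):
        """lr=0 keeps the tuning loss flat, so patience=1 stops after one
        epoch beyond the first."""
        cfg = TrainConfig(batch_size=2, max_epochs=50, steps_per_epoch=2,
                          learning_rate=0.0, momentum=0.0, patience=1, seed=0)
        net_cfg = NetworkConfig(dimensionality=3, n_classes=5, base_channels=2, depth=1)
        _, hist = train(small_cohort[:1], small_cohort[1:2], net_cfg, cfg,
                        PatchSpec(patch_shape=(4, 16, 16)))
        assert len(hist) == 2

    def test_deterministic_history(self, small_cohort):
        cfg = TrainConfig(batch_size=2, max_epochs=3, steps_per_epoch=2,
                          learning_rate=0.05, patience=5, seed=4)
        net_cfg = NetworkConfig(dimensionality=3, n_classes=5, base_channels=2, depth=1)
        spec = PatchSpec(patch_shape=(4, 16, 16))
        _, h1 = train(small_cohort[:1], small_cohort[1:2], net_cfg, cfg, spec)
        _, h2 = train(small_cohort[:1], small_cohort[1:2], net_cfg, cfg, spec)
        assert h1 == h2

    def test_loss_descends_on_single_case(self, small_cohort):
        cfg = TrainConfig(batch_size=2, max_epochs=10, steps_per_epoch=4,
                          learning_rate=0.1, patience=10, seed=2)
        net_cfg = NetworkConfig(dimensionality=3, n_classes=5, base_channels=2, depth=1)
        _, hist = train(small_cohort[:1], small_cohort[:1], net_cfg, cfg,
                        PatchSpec(patch_shape=(4, 16, 16), foreground_bias=0.7))
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_empty_case_lists_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            train([], small_cohort[:1], TOY2D, TrainConfig(), PatchSpec())


class TestPredict:
    def test_probabilities_sum_to_one(self, small_cohort):
        net = build_network(
            NetworkConfig(dimensionality=3, n_classes=5, base_channels=2, depth=1), seed=0
        )
        img = normalize_intensity(small_cohort[0].image)
        pred = predict(net, img, PatchSpec(patch_shape=(8, 32, 32)))
        np.testing.assert_allclose(pred.probabilities.sum(axis=0), 1.0, atol=1e-5)
        assert pred.argmax_labels.shape == img.shape

    def test_single_patch_equals_forward_pass(self, small_cohort):
        net = build_network(
            NetworkConfig(dimensionality=3, n_classes=5, base_channels=2, depth=1), seed=0
        )
        img = normalize_intensity(small_cohort[0].image)
        spec = PatchSpec(patch_shape=img.shape)  # exactly one window
        pred = predict(net, img, spec)
        direct = softmax(net.forward(img.values[None, None]), axis=1)[0]
        np.testing.assert_allclose(pred.probabilities, direct, atol=1e-5)

    def test_stitching_invariant_for_constant_model(self, small_cohort, monkeypatch):
        """If the model is a constant function, the argmax must not depend on
        the window layout."""
        net = build_network(
            NetworkConfig(dimensionality=3, n_classes=5, base_channels=2, depth=1), seed=0
        )
        const = np.array([0.1, 0.5, 0.2, 3.0, 0.4], dtype=np.float32)

        def fake_forward(x):
            out = np.zeros((x.shape[0], 5) + x.shape[2:], dtype=np.float32)
            out += const.reshape(1, 5, 1, 1, 1)
            return out

        monkeypatch.setattr(net, "forward", fake_forward)
        img = normalize_intensity(small_cohort[0].image)
        for shape in [(8, 32, 32), (4, 48, 48), img.shape]:
            pred = predict(net, img, PatchSpec(patch_shape=shape))
            assert np.all(pred.argmax_labels.labels == 3)

    def test_small_volume_zero_padded_and_cropped(self, small_cohort):
        net = build_network(
            NetworkConfig(dimensionality=3, n_classes=5, base_channels=2, depth=1), seed=0
        )
        from cuffseg.volio import ImageVolume

        tiny = ImageVolume(values=np.zeros((4, 16, 16), dtype=np.float32),
                           spacing_mm=(2.5, 0.29, 0.29))
        pred = predict(net, tiny, PatchSpec(patch_shape=(8, 32, 32)))
        assert pred.argmax_labels.shape == (4, 16, 16)

    def test_2d_mode_prediction(self, small_cohort):
        net = build_network(
            NetworkConfig(dimensionality=2, n_classes=5, base_channels=2, depth=1), seed=0
        )
        img = normalize_intensity(small_cohort[0].image)
        pred = predict(net, img, PatchSpec(patch_shape="full-slice"))
        assert pred.argmax_labels.shape == img.shape
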