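"""Neural-network engine: gradients, parameter counts, training behavior."""

import warnings

import numpy as np
import pytest

from nervetrace.core import Calibration, IVCMImage, TracingMap
from nervetrace.model import (
    AugmentConfig,
    ModelConfig,
    TrainConfig,
    TrainedModel,
    apply_geometric,
    augment,
    build_model,
    count_trainable_parameters,
    deep_unet_config,
    predict_probability,
    train,
)
from nervetrace.nn import (
    BatchNorm2D,
    Conv2D,
    MaxPool2x2,
    UpsampleNearest2x,
    softmax,
    softmax_cross_entropy,
)


def numerical_grad(f, x, eps=1e-3):
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


def rel_err(a, b):
    denom = max(np.abs(a).max(), np.abs(b).max(), 1e-8)
    return np.abs(a - b).max() / denom


class TestGradients:
    """Analytic backward passes against central finite differences.

    Each layer is probed with the linear readout loss sum(out * R) for a
    fixed random R, which exercises every output element.
    """

    def test_conv2d_weight_and_input_grads(self):
        rng = np.random.default_rng(0)
        conv = Conv2D(3, 4, 3, rng, bias=True)
        x = rng.normal(size=(2, 6, 6, 3)).astype(np.float32)
        r = rng.normal(size=(2, 6, 6, 4)).astype(np.float32)

        def loss():
            return float(np.sum(conv.forward(x, train=False) * r))

        conv.weight.grad[...] = 0
        conv.bias.grad[...] = 0
        conv.forward(x, train=True)
        dx = conv.backward(r)
        assert rel_err(dx, numerical_grad(loss, x)) < 1e-3
        assert rel_err(conv.weight.grad, numerical_grad(loss, conv.weight.value)) < 1e-3
        assert rel_err(conv.bias.grad, numerical_grad(loss, conv.bias.value)) < 1e-3

    def test_batchnorm_grads(self):
        rng = np.random.default_rng(1)
        bn = BatchNorm2D(3)
        x = rng.normal(size=(2, 4, 4, 3)).astype(np.float32)
        r = rng.normal(size=(2, 4, 4, 3)).astype(np.float32)

        def loss():
            bn2 = BatchNorm2D(3)
            bn2.gamma.value[...] = bn.gamma.value
            bn2.beta.value[...] = bn.beta.value
            return float(np.sum(bn2.forward(x, train=True) * r))

        bn.forward(x, train=True)
        dx = bn.backward(r)
        assert rel_err(dx, numerical_grad(loss, x)) < 5e-3
        assert rel_err(bn.gamma.grad, numerical_grad(loss, bn.gamma.value)) < 5e-3
        assert rel_err(bn.beta.grad, numerical_grad(loss, bn.beta.value)) < 5e-3

    def test_maxpool_grads(self):
        rng = np.random.default_rng(2)
        pool = MaxPool2x2()
        # well-separated values avoid ties crossing under finite differences
        x = (rng.permutation(2 * 4 * 4 * 2).reshape(2, 4, 4, 2) * 1.0).astype(np.float32)
        r = rng.normal(size=(2, 2, 2, 2)).astype(np.float32)

        def loss():
            return float(np.sum(pool.forward(x, train=False) * r))

        pool.forward(x, train=True)
        dx = pool.backward(r)
        assert rel_err(dx, numerical_grad(loss, x, eps=1e-2)) < 5e-3

    def test_upsample_grads(self):
        rng = np.random.default_rng(3)
        up = UpsampleNearest2x()
        x = rng.normal(size=(1, 3, 3, 2)).astype(np.float32)
        r = rng.normal(size=(1, 6, 6, 2)).astype(np.float32)

        def loss():
            return float(np.sum(up.forward(x) * r))

        up.forward(x)
        dx = up.backward(r)
        assert rel_err(dx, numerical_grad(loss, x)) < 1e-4

    def test_cross_entropy_grads(self):
        rng = np.random.default_rng(4)
        logits = rng.normal(size=(2, 3, 3, 2)).astype(np.float32)
        labels = rng.integers(0, 2, size=(2, 3, 3))
        weights = np.array([1.0, 4.0])

        def loss():
            return softmax_cross_entropy(logits, labels, weights)[0]

        _, dlogits = softmax_cross_entropy(logits, labels, weights)
        assert rel_err(dlogits, numerical_grad(loss, logits)) < 1e-3


class TestSoftmaxAndLoss:
    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        p = softmax(rng.normal(scale=10, size=(2, 4, 4, 2)))
        assert np.allclose(p.sum(axis=-1), 1.0)
        assert np.all(p >= 0)

    def test_unweighted_loss_is_pixel_mean(self):
        # uniform logits: loss = -log(1/2) per pixel regardless of labels
        logits = np.zeros((1, 4, 4, 2), dtype=np.float32)
        labels = np.zeros((1, 4, 4), dtype=np.int64)
        loss, _ = softmax_cross_entropy(logits, labels)
        assert loss == pytest.approx(np.log(2.0))

    def test_weighting_reduces_to_unweighted_when_equal(self):
        rng = np.random.default_rng(6)
        logits = rng.normal(size=(1, 4, 4, 2)).astype(np.float32)
        labels = rng.integers(0, 2, size=(1, 4, 4))
        plain, _ = softmax_cross_entropy(logits, labels)
        weighted, _ = softmax_cross_entropy(logits, labels, np.array([2.0, 2.0]))
        assert plain == pytest.approx(weighted)


def expected_parameter_count(cfg: ModelConfig) -> int:
    """Parameter count from the architecture definition, by direct arithmetic."""
    ch = [cfg.base_filters * 2**i for i in range(cfg.depth)]
    skips = cfg.architecture in ("unet", "unet_residual")
    residual = cfg.architecture == "unet_residual"

    def double_conv(cin, cout):
        # conv(no bias) + BN(gamma, beta), twice
        n = 9 * cin * cout + 2 * cout + 9 * cout * cout + 2 * cout
        if residual and cin != cout:
            n += cin * cout + cout  # 1x1 projection with bias
        return n

    total = 0
    cin = 1
    for lvl in range(cfg.depth):
        total += double_conv(cin, ch[lvl])
        cin = ch[lvl]
    for lvl in range(cfg.depth - 2, -1, -1):
        dec_in = cin + (ch[lvl] if skips else 0)
        total += double_conv(dec_in, ch[lvl])
        cin = ch[lvl]
    total += ch[0] * cfg.n_classes + cfg.n_classes  # final 1x1 conv with bias
    return total


class TestParameterCounts:
    def test_deep_unet_exact_anchor(self):
        model = build_model(deep_unet_config())
        assert count_trainable_parameters(model) == 487_730

    @pytest.mark.parametrize(
        "arch,depth,base",
        [
            ("unet", 4, 16),
            ("unet", 3, 8),
            ("autoencoder", 4, 16),
            ("autoencoder", 2, 4),
            ("unet_residual", 4, 16),
            ("unet_residual", 3, 8),
        ],
    )
    def test_count_matches_arithmetic_oracle(self, arch, depth, base):
        cfg = ModelConfig(
            architecture=arch, depth=depth, base_filters=base, input_size_px=64
        )
        assert count_trainable_parameters(build_model(cfg)) == expected_parameter_count(cfg)

    def test_skip_connections_add_parameters(self):
        unet = build_model(ModelConfig(architecture="unet"))
        plain = build_model(ModelConfig(architecture="autoencoder"))
        assert count_trainable_parameters(unet) > count_trainable_parameters(plain)
        assert count_trainable_parameters(plain) == 439_346

    def test_conv2d_unit_counts(self):
        rng = np.random.default_rng(0)
        assert sum(p.size for p in Conv2D(1, 4, 3, rng, bias=False).params()) == 36
        assert sum(p.size for p in Conv2D(1, 4, 3, rng, bias=True).params()) == 40
        assert sum(p.size for p in Conv2D(16, 2, 1, rng, bias=True).params()) == 34


class TestConfigValidation:
    def test_unknown_architecture(self):
        with pytest.raises(ValueError):
            ModelConfig(architecture="resnet")

    def test_indivisible_input_size(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(depth=4, input_size_px=100)

    def test_forward_rejects_bad_spatial_size(self):
        model = build_model(ModelConfig(depth=3, base_filters=4, input_size_px=64))
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 10, 10, 1), dtype=np.float32), train=False)

    def test_lr_schedule_modes(self):
        cfg = TrainConfig(lr_initial=1e-3, lr_drop_every_epochs=10)
        assert cfg.learning_rate(0) == pytest.approx(1e-3)
        # multiply mode halves the rate every 100 epochs
        assert cfg.learning_rate(100) == pytest.approx(5e-4)
        sub = TrainConfig(
            lr_initial=1e-3, lr_drop=5e-4, lr_drop_every_epochs=10,
            lr_schedule_mode="subtract_floor",
        )
        assert sub.learning_rate(10) == pytest.approx(5e-4)
        assert sub.learning_rate(1000) == pytest.approx(1e-5)  # floored


class TestAugmentation:
    def _pair(self, seed=0, size=33):
        rng = np.random.default_rng(seed)
        image = rng.uniform(size=(size, size))
        mask = np.zeros((size, size), dtype=np.int64)
        mask[size // 2, 4 : size - 4] = 1
        return image, mask

    def test_zero_transform_is_identity(self):
        image, mask = self._pair()
        out_i, out_m = apply_geometric(image, mask)
        assert np.array_equal(out_i, image) and np.array_equal(out_m, mask)

    def test_flips_are_exact_involutions(self):
        image, mask = self._pair()
        i1, m1 = apply_geometric(image, mask, flip_h=True)
        i2, m2 = apply_geometric(i1, m1, flip_h=True)
        assert np.array_equal(i2, image) and np.array_equal(m2, mask)
        i1, m1 = apply_geometric(image, mask, flip_v=True)
        i2, m2 = apply_geometric(i1, m1, flip_v=True)
        assert np.array_equal(i2, image) and np.array_equal(m2, mask)

    def test_mask_stays_binary(self):
        image, mask = self._pair()
        rng = np.random.default_rng(1)
        for _ in range(10):
            _, out_m = augment(image, mask, AugmentConfig(), rng)
            assert set(np.unique(out_m)) <= {0, 1}

    def test_foreground_roughly_preserved(self):
        image, mask = self._pair(size=65)
        rng = np.random.default_rng(2)
        base = mask.sum()
        for _ in range(10):
            _, out_m = augment(image, mask, AugmentConfig(), rng)
            assert abs(int(out_m.sum()) - base) / base < 0.30

    def test_disabled_augmentation_is_identity(self):
        image, mask = self._pair()
        rng = np.random.default_rng(3)
        out_i, out_m = augment(image, mask, AugmentConfig(enabled=False), rng)
        assert out_i is image and out_m is mask

    def test_image_and_mask_transform_together(self):
        # after a pure rotation, the mask ridge must still sit on the bright
        # image ridge: correlate transformed mask with transformed image
        image, mask = self._pair(size=65)
        image = image * 0.1
        image[mask == 1] = 5.0
        out_i, out_m = apply_geometric(image, mask, angle_deg=12.0)
        on = out_i[out_m == 1].mean()
        off = out_i[out_m == 0].mean()
        assert on > off + 2.0


def tiny_dataset(n=6, size=16, seed=0):
    rng = np.random.default_rng(seed)
    cal = Calibration(100.0, size)
    pairs = []
    for i in range(n):
        row = int(rng.integers(3, size - 3))
        mask = np.zeros((size, size), dtype=np.uint8)
        mask[row, 2 : size - 2] = 1
        image = rng.uniform(0, 20, size=(size, size))
        image[mask == 1] += 200.0
        pairs.append(
            (IVCMImage(image, cal, f"S{i}", f"img{i}"), TracingMap(mask, cal))
        )
    return pairs


def tiny_configs(epochs=3, seed=0):
    mcfg = ModelConfig(depth=2, base_filters=4, dropout_rate=0.0, input_size_px=16)
    tcfg = TrainConfig(
        epochs=epochs,
        batch_size=2,
        seed=seed,
        foreground_weight=4.0,
        augmentation=AugmentConfig(enabled=False),
    )
    return mcfg, tcfg


class TestTraining:
    def test_deterministic_bit_identical(self):
        mcfg, tcfg = tiny_configs()
        runs = []
        for _ in range(2):
            model = build_model(mcfg, seed=tcfg.seed)
            runs.append(train(model, tiny_dataset(), tcfg))
        assert runs[0].history == runs[1].history
        for a, b in zip(runs[0].model.state(), runs[1].model.state()):
            assert np.array_equal(a, b)

    def test_loss_decreases_on_learnable_task(self):
        mcfg, tcfg = tiny_configs(epochs=15)
        model = build_model(mcfg, seed=0)
        trained = train(model, tiny_dataset(), tcfg)
        assert trained.history["train_loss"][-1] < trained.history["train_loss"][0]

    def test_history_has_per_epoch_entries(self):
        mcfg, tcfg = tiny_configs(epochs=4)
        trained = train(build_model(mcfg), tiny_dataset(), tcfg)
        assert len(trained.history["train_loss"]) == 4
        assert len(trained.history["val_loss"]) == 4
        assert len(trained.history["lr"]) == 4

    def test_all_background_warns_and_predicts_background(self):
        cal = Calibration(100.0, 16)
        rng = np.random.default_rng(0)
        pairs = [
            (
                IVCMImage(rng.uniform(0, 10, (16, 16)), cal, f"S{i}"),
                TracingMap(np.zeros((16, 16), np.uint8), cal),
            )
            for i in range(4)
        ]
        mcfg, _ = tiny_configs()
        tcfg = TrainConfig(
            epochs=80,
            batch_size=2,
            seed=0,
            lr_initial=2e-3,
            foreground_weight=4.0,
            augmentation=AugmentConfig(enabled=False),
        )
        with pytest.warns(UserWarning, match="no foreground"):
            trained = train(build_model(mcfg), pairs, tcfg)
        prob = predict_probability(trained, pairs[0][0])
        assert prob.pixels.mean() < 0.2
        assert np.all(prob.pixels < 0.5)  # no pixel is classified as nerve

    def test_empty_dataset_rejected(self):
        mcfg, tcfg = tiny_configs()
        with pytest.raises(ValueError):
            train(build_model(mcfg), [], tcfg)

    def test_save_load_round_trip(self, tmp_path):
        mcfg, tcfg = tiny_configs(epochs=2)
        data = tiny_dataset()
        trained = train(build_model(mcfg, seed=0), data, tcfg)
        path = tmp_path / "model.npz"
        trained.save(path)
        loaded = TrainedModel.load(path)
        a = predict_probability(trained, data[0][0]).pixels
        b = predict_probability(loaded, data[0][0]).pixels
        assert np.array_equal(a, b)
        assert loaded.history == trained.history


class TestInference:
    def test_probability_map_shape_and_range(self):
        mcfg, tcfg = tiny_configs(epochs=2)
        data = tiny_dataset()
        trained = train(build_model(mcfg), data, tcfg)
        prob = predict_probability(trained, data[0][0])
        assert prob.shape == (16, 16)
        assert prob.pixels.min() >= 0 and prob.pixels.max() <= 1

    def test_non_stride_multiple_input_padded_and_cropped(self):
        mcfg, tcfg = tiny_configs(epochs=1)
        trained = train(build_model(mcfg), tiny_dataset(), tcfg)
        cal = Calibration(100.0, 21)
        odd = IVCMImage(np.random.default_rng(0).uniform(0, 50, (21, 21)), cal)
        prob = predict_probability(trained, odd)
        assert prob.shape == (21, 21)

    def test_eval_mode_deterministic(self):
        mcfg, tcfg = tiny_configs(epochs=2)
        data = tiny_dataset()
        trained = train(build_model(mcfg), data, tcfg)
        a = predict_probability(trained, data[1][0]).pixels
        b = predict_probability(trained, data[1][0]).pixels
        assert np.array_equal(a, b)
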