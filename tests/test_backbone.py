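"""Backbone architecture conformance, gradients, and transfer training."""

import numpy as np
import pytest

from eegcube.nn import (
    BackboneConfig,
    ConfigError,
    HeadConfig,
    LoadError,
    TrainConfig,
    TrainingError,
    attach_head,
    build_backbone,
    load_pretrained,
    parameter_checksum,
    propagate_shapes,
    save_checkpoint,
    softmax,
    train_transfer,
)

TINY = BackboneConfig(width_multiplier=0.125, input_shape=(3, 16, 32, 32), seed=3)


def shape_oracle(config):
    """Independent shape propagation: ceil division per strided dimension."""
    import math

    dims = list(config.input_shape[1:])
    out = []
    strides = [(1, 2, 2)] + [s for _, s, _ in config.stages]
    chans = [config.scaled(config.stem_channels)] + [
        config.scaled(c) for _, _, c in config.stages
    ]
    for stride, ch in zip(strides, chans):
        dims = [math.ceil(n / s) for n, s in zip(dims, stride)]
        out.append((ch, *dims))
    return out


class TestArchitecture:
    def test_reference_stage_shapes(self):
        shapes = dict(propagate_shapes(BackboneConfig()))
        assert shapes["stem"] == (32, 200, 32, 32)
        assert shapes["stage1"] == (64, 100, 16, 16)
        assert shapes["stage2"] == (128, 50, 8, 8)
        assert shapes["stage3"] == (256, 25, 4, 4)
        assert shapes["stage4"] == (512, 13, 2, 2)
        assert shapes["stage5"] == (1024, 13, 2, 2)
        assert shapes["pool"] == (1024,)

    @pytest.mark.parametrize("width,expected_dim", [(1.0, 1024), (0.25, 256)])
    def test_width_scaling_matches_oracle(self, width, expected_dim):
        cfg = BackboneConfig(width_multiplier=width)
        got = [s for name, s in propagate_shapes(cfg) if name != "input"][:-1]
        assert got == shape_oracle(cfg)
        assert cfg.feature_dim == expected_dim

    def test_actual_forward_shapes_match_propagation(self):
        cfg = BackboneConfig(width_multiplier=0.25, input_shape=(3, 20, 32, 32), seed=0)
        bb = build_backbone(cfg)
        x = np.random.default_rng(0).normal(size=(2, *cfg.input_shape)).astype(np.float32)
        expected = {name: s for name, s in propagate_shapes(cfg)}
        h = x
        reached = {}
        for name, layer in bb.layers:
            h = layer.forward(h)
            stage = name.split(".")[0]
            reached[stage] = h.shape[1:]
        assert reached["stem"] == expected["stem"]
        for i in range(1, 6):
            assert reached[f"stage{i}"] == expected[f"stage{i}"]
        assert reached["pool"] == expected["pool"]

    def test_parameter_count_matches_arithmetic(self):
        cfg = BackboneConfig()
        bb = build_backbone(cfg)
        total = sum(v.size for v in bb.params().values())
        # independent layer-by-layer arithmetic
        expected = 27 * 3 * 32 + 2 * 32  # stem conv + BN affine
        ch = 32
        for repeats, _, out_ch in cfg.stages:
            for _ in range(repeats):
                expected += 27 * ch + 2 * ch       # depthwise + its BN
                expected += ch * out_ch + 2 * out_ch  # pointwise + its BN
                ch = out_ch
        assert total == expected

    def test_too_small_input_names_failing_stage(self):
        with pytest.raises(ConfigError, match="stage3"):
            propagate_shapes(BackboneConfig(input_shape=(3, 200, 8, 8)))

    def test_seeded_build_reproducible(self):
        a = build_backbone(TINY)
        b = build_backbone(TINY)
        assert parameter_checksum(a.state()) == parameter_checksum(b.state())


class TestForward:
    def test_eval_forward_deterministic(self, rng):
        bb = build_backbone(TINY)
        x = rng.normal(size=(2, 3, 16, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(bb.forward(x), bb.forward(x))

    def test_identical_inputs_identical_features(self, rng):
        bb = build_backbone(TINY)
        one = rng.normal(size=(1, 3, 16, 32, 32)).astype(np.float32)
        f = bb.forward(np.concatenate([one, one]))
        np.testing.assert_array_equal(f[0], f[1])

    def test_zero_input_reproducible_and_finite(self):
        bb = build_backbone(TINY)
        x = np.zeros((1, 3, 16, 32, 32), dtype=np.float32)
        f1, f2 = bb.forward(x), bb.forward(x)
        assert np.all(np.isfinite(f1))
        np.testing.assert_array_equal(f1, f2)


class TestHead:
    def test_softmax_normalization(self, rng):
        bb = build_backbone(TINY)
        model = attach_head(bb, HeadConfig(3, seed=0))
        x = rng.normal(size=(4, 3, 16, 32, 32)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (4, 3)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_argmax_rule(self):
        probs = softmax(np.array([[2.0, 1.0, 0.0]]))
        assert probs.argmax() == 0

    def test_head_widths_for_four_classes(self):
        bb = build_backbone(BackboneConfig(width_multiplier=0.125,
                                           input_shape=(3, 16, 32, 32)))
        model = attach_head(bb, HeadConfig(4))
        widths = [lin.params["weight"].shape[0] for lin in model.head.dense]
        assert widths == [1024, 256, 120, 4]

    def test_feature_tap_is_dense1_output(self, rng):
        bb = build_backbone(TINY)
        model = attach_head(bb, HeadConfig(3, seed=0))
        x = rng.normal(size=(2, 3, 16, 32, 32)).astype(np.float32)
        feats = model.features(x)
        assert feats.shape == (2, 1024)
        pooled = bb.forward(x)
        d1 = model.head.dense[0]
        np.testing.assert_allclose(
            feats, pooled @ d1.params["weight"].T + d1.params["bias"], rtol=1e-5
        )

    def test_width_mismatch_rejected(self):
        from eegcube.nn import Classifier, MLPHead

        bb = build_backbone(TINY)
        with pytest.raises(ConfigError, match="features"):
            Classifier(bb, MLPHead(bb.feature_dim + 1, HeadConfig(3)))


class TestGradients:
    """Analytic backward passes against central finite differences."""

    @staticmethod
    def _check(layer, x, param=None, tol=1e-4):
        def loss(inp):
            out = layer.forward(inp, train=True)
            return float((out**2).sum() / 2)

        out = layer.forward(x, train=True)
        gx = layer.backward(out)
        target, analytic = (
            (x, gx) if param is None else (layer.params[param], layer.grads[param])
        )
        rng = np.random.default_rng(0)
        flat = target.reshape(-1)
        for i in rng.choice(flat.size, size=min(12, flat.size), replace=False):
            eps = 1e-3
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss(x)
            flat[i] = orig - eps
            lm = loss(x)
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - analytic.reshape(-1)[i]) <= tol * (1 + abs(num))

    def test_conv3d_gradients(self, rng):
        from eegcube.nn import Conv3d

        layer = Conv3d(2, 3, 3, stride=(2, 1, 2), bias=True,
                       rng=np.random.default_rng(1))
        for k in layer.params:
            layer.params[k] = layer.params[k].astype(np.float64)
        x = rng.normal(size=(2, 2, 5, 4, 4))
        self._check(layer, x)
        self._check(layer, x, "weight")
        self._check(layer, x, "bias")

    def test_depthwise_gradients(self, rng):
        from eegcube.nn import DepthwiseConv3d

        layer = DepthwiseConv3d(3, 3, stride=(1, 2, 1), rng=np.random.default_rng(1))
        layer.params["weight"] = layer.params["weight"].astype(np.float64)
        x = rng.normal(size=(2, 3, 4, 5, 4))
        self._check(layer, x)
        self._check(layer, x, "weight")

    def test_batchnorm_gradients(self, rng):
        from eegcube.nn import BatchNorm3d

        layer = BatchNorm3d(3)
        for k in layer.params:
            layer.params[k] = layer.params[k].astype(np.float64)
        x = rng.normal(size=(2, 3, 4, 3, 3))
        self._check(layer, x, tol=1e-3)
        self._check(layer, x, "gamma")
        self._check(layer, x, "beta")


def _toy_blocks(n_per=12, w=16, hw=24, seed=0):
    """Two-class blocks separated by a high-SNR amplitude/location pattern."""
    rng = np.random.default_rng(seed)
    t = np.arange(w) / 20.0
    yy, xx = np.mgrid[0:hw, 0:hw]
    blob0 = np.exp(-((yy - 3) ** 2 + (xx - 3) ** 2) / 8.0)
    blob1 = np.exp(-((yy - hw + 4) ** 2 + (xx - hw + 4) ** 2) / 8.0)
    xs, ys = [], []
    for c, (blob, amp) in enumerate([(blob0, 1.0), (blob1, 4.0)]):
        for _ in range(n_per):
            sig = amp * np.sin(2 * np.pi * 3 * t + rng.uniform(0, 2 * np.pi))
            xs.append(sig[:, None, None] * blob[None] +
                      0.05 * rng.standard_normal((w, hw, hw)))
            ys.append(c)
    x = np.repeat(np.array(xs, dtype=np.float32)[:, None], 3, axis=1)
    return x, np.array(ys)


class TestTrainTransfer:
    CFG = BackboneConfig(width_multiplier=0.125, input_shape=(3, 16, 24, 24), seed=5)

    def test_frozen_backbone_checksum_unchanged(self):
        x, y = _toy_blocks()
        bb = build_backbone(self.CFG)
        bb.calibrate_bn(x)
        model = attach_head(bb, HeadConfig(2, seed=0))
        before = parameter_checksum(bb.state())
        train_transfer(model, x, y, TrainConfig(max_epochs=5, seed=0,
                                                freeze_backbone=True))
        assert parameter_checksum(bb.state()) == before

    def test_fixed_seed_identical_history(self):
        x, y = _toy_blocks()

        def run():
            bb = build_backbone(self.CFG)
            bb.calibrate_bn(x)
            model = attach_head(bb, HeadConfig(2, seed=0))
            _, hist = train_transfer(
                model, x, y,
                TrainConfig(max_epochs=4, seed=9, freeze_backbone=True),
            )
            return hist["loss"]

        assert run() == run()

    def test_separable_blocks_reach_high_training_accuracy(self):
        x, y = _toy_blocks(n_per=16)
        bb = build_backbone(self.CFG)
        bb.calibrate_bn(x)
        model = attach_head(bb, HeadConfig(2, seed=0))
        _, hist = train_transfer(
            model, x, y,
            TrainConfig(learning_rate=3e-3, max_epochs=40, batch_size=8,
                        seed=0, freeze_backbone=True),
        )
        assert max(hist["accuracy"]) > 0.95

    def test_unfrozen_training_changes_backbone(self):
        x, y = _toy_blocks(n_per=4)
        bb = build_backbone(self.CFG)
        model = attach_head(bb, HeadConfig(2, seed=0))
        before = parameter_checksum(bb.state())
        train_transfer(model, x, y, TrainConfig(max_epochs=1, seed=0,
                                                freeze_backbone=False))
        assert parameter_checksum(bb.state()) != before

    def test_single_class_rejected(self):
        x, y = _toy_blocks(n_per=4)
        bb = build_backbone(self.CFG)
        model = attach_head(bb, HeadConfig(2, seed=0))
        with pytest.raises(TrainingError, match="class"):
            train_transfer(model, x, np.zeros_like(y),
                           TrainConfig(max_epochs=1, freeze_backbone=True))

    def test_best_checkpoint_restored(self):
        x, y = _toy_blocks()
        bb = build_backbone(self.CFG)
        bb.calibrate_bn(x)
        model = attach_head(bb, HeadConfig(2, seed=0))
        model, hist = train_transfer(
            model, x, y, TrainConfig(max_epochs=6, seed=0, freeze_backbone=True)
        )
        assert hist["best_epoch"] == int(np.argmin(hist["loss"]))


class TestCheckpoints:
    def test_save_load_round_trip(self, tmp_path):
        bb = build_backbone(TINY)
        model = attach_head(bb, HeadConfig(3, seed=1))
        path = tmp_path / "model.npz"
        save_checkpoint(path, model)
        bb2 = build_backbone(BackboneConfig(width_multiplier=0.125,
                                            input_shape=(3, 16, 32, 32), seed=99))
        model2 = attach_head(bb2, HeadConfig(3, seed=42))
        assert parameter_checksum(model2.state()) != parameter_checksum(model.state())
        load_pretrained(model2, path, strict=True)
        assert parameter_checksum(model2.state()) == parameter_checksum(model.state())

    def test_strict_shape_mismatch_raises(self, tmp_path):
        small = build_backbone(BackboneConfig(width_multiplier=0.125,
                                              input_shape=(3, 16, 32, 32)))
        big = build_backbone(BackboneConfig(width_multiplier=0.25,
                                            input_shape=(3, 16, 32, 32)))
        path = tmp_path / "small.npz"
        save_checkpoint(path, small)
        with pytest.raises(LoadError, match="mismatch"):
            load_pretrained(big, path, strict=True)

    def test_non_strict_partial_overlap(self, tmp_path):
        bb = build_backbone(TINY)
        path = tmp_path / "bb.npz"
        save_checkpoint(path, bb)
        model = attach_head(
            build_backbone(BackboneConfig(width_multiplier=0.125,
                                          input_shape=(3, 16, 32, 32), seed=77)),
            HeadConfig(3, seed=7),
        )
        head_before = parameter_checksum(model.head.state())
        # backbone-only checkpoint: names don't carry the "backbone." prefix,
        # so nothing matches the classifier's keys in non-strict mode
        load_pretrained(model, path, strict=False)
        assert parameter_checksum(model.head.state()) == head_before
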