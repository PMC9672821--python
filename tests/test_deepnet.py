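"""Segmentation models: architecture contracts, loss, training behaviour."""

import numpy as np
import pytest

from strokefate import deepnet, nn
from strokefate.deepnet import (
    TemporalBlockConfig,
    TrainConfig,
    UNetConfig,
    build_causal_block,
    build_model,
    build_param_unet,
    build_simple_block,
    soft_dice_loss,
)

SMALL_UNET = UNetConfig(in_channels=4, depth=2, base_filters=4)


class TestParamUNet:
    def test_softmax_sums_to_one(self, rng):
        model = build_param_unet(SMALL_UNET, seed=0)
        out = model.forward(rng.normal(size=(2, 4, 8, 8)))
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-5)

    def test_shape_preserved(self, rng):
        cfg = UNetConfig(in_channels=4, depth=4, base_filters=2)
        model = build_param_unet(cfg, seed=0)
        out = model.forward(rng.normal(size=(1, 4, 96, 64)))
        assert out.shape == (1, 2, 96, 64)

    def test_indivisible_shape_rejected(self, rng):
        model = build_param_unet(SMALL_UNET, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(rng.normal(size=(1, 4, 10, 8)))

    def test_parameter_count_matches_hand_formula(self):
        cfg = UNetConfig(in_channels=4, depth=2, base_filters=8)
        model = build_param_unet(cfg, seed=0)

        def conv_params(cin, cout, k):
            return cout * cin * k * k + cout

        f = [8, 16, 32]
        expected = 0
        # encoder blocks (two 3x3 convs each)
        cin = 4
        for i in range(2):
            expected += conv_params(cin, f[i], 3) + conv_params(f[i], f[i], 3)
            cin = f[i]
        # bottleneck
        expected += conv_params(f[1], f[2], 3) + conv_params(f[2], f[2], 3)
        # decoder: upsample conv + two convs after concat
        for i in (1, 0):
            expected += conv_params(f[i + 1], f[i], 3)
            expected += conv_params(2 * f[i], f[i], 3) + conv_params(f[i], f[i], 3)
        # 1x1 softmax head
        expected += conv_params(f[0], 2, 1)
        assert sum(p.value.size for p in model.parameters()) == expected


class TestSimpleBlock:
    def test_32_window_collapses_to_8_features(self, rng):
        block = build_simple_block(seed=0)
        out = block.forward(rng.normal(size=(5, 1, 32)))
        assert out.shape == (5, 8)

    def test_31_window_rejected_with_shape_trace(self, rng):
        block = build_simple_block(seed=0)
        with pytest.raises(ValueError, match=r"31"):
            block.forward(rng.normal(size=(2, 1, 31)))

    def test_incompatible_config_rejected(self):
        with pytest.raises(ValueError, match="collapse"):
            build_simple_block(TemporalBlockConfig(variant="simple", window_len=20))

    def test_zero_input_zero_features(self):
        block = build_simple_block(seed=1)
        out = block.forward(np.zeros((3, 1, 32)))
        np.testing.assert_array_equal(out, 0.0)

    def test_temporal_collapse_trace(self):
        from strokefate.deepnet import _simple_shape_trace

        trace = _simple_shape_trace(32, TemporalBlockConfig(variant="simple"))
        assert trace == [32, 30, 28, 14, 12, 10, 5, 3, 1]


class TestCausalBlock:
    def test_receptive_field_is_32(self):
        cfg = TemporalBlockConfig(variant="causal")
        assert cfg.receptive_field == 1 + (1 + 2 + 4 + 8 + 16) == 32
        assert cfg.receptive_field == cfg.window_len

    def test_output_is_8_features(self, rng):
        block = build_causal_block(seed=0)
        assert block.forward(rng.normal(size=(4, 1, 32))).shape == (4, 8)

    def test_zero_input_zero_features(self):
        block = build_causal_block(seed=0)
        np.testing.assert_array_equal(block.forward(np.zeros((2, 1, 32))), 0.0)

    def test_mismatched_receptive_field_warns(self):
        with pytest.warns(UserWarning, match="receptive field"):
            build_causal_block(
                TemporalBlockConfig(variant="causal", dilations=(1, 2, 4))
            )

    def test_causality_perturbation_probe(self, rng):
        """Last-element features react to sample 31; outputs at earlier
        positions never react to later inputs."""
        block = build_causal_block(seed=3)
        x = rng.normal(size=(1, 1, 32))
        base_seq = block.forward_sequence(x)
        x2 = x.copy()
        x2[0, 0, 31] += 1.0
        pert_seq = block.forward_sequence(x2)
        assert np.abs(pert_seq[0, :, 31] - base_seq[0, :, 31]).max() > 0
        np.testing.assert_allclose(pert_seq[0, :, :31], base_seq[0, :, :31],
                                   atol=1e-6)
        # perturbing a middle sample leaves strictly earlier outputs alone
        x3 = x.copy()
        x3[0, 0, 15] += 1.0
        pert3 = block.forward_sequence(x3)
        np.testing.assert_allclose(pert3[0, :, :15], base_seq[0, :, :15],
                                   atol=1e-6)

    def test_finite_difference_causality(self, monkeypatch, rng):
        """dOutput(t)/dInput(t') == 0 for all t' > t."""
        monkeypatch.setattr(nn, "DEFAULT_DTYPE", np.float64)
        block = build_causal_block(seed=5)
        x = rng.normal(size=(1, 1, 32))
        base = block.forward_sequence(x)
        eps = 1e-6
        for tprime in (8, 20, 31):
            x2 = x.copy()
            x2[0, 0, tprime] += eps
            diff = np.abs(block.forward_sequence(x2) - base)[0]
            assert diff[:, :tprime].max() == 0.0


class TestModularity:
    def test_all_variants_share_trunk_shapes(self):
        base = UNetConfig(in_channels=4, depth=2, base_filters=4)
        models = {
            v: build_model(v, unet_cfg=base, seed=1)
            for v in deepnet.MODEL_VARIANTS
        }
        trunks = {
            v: [p.shape for p in m.unet.trunk_parameters()]
            for v, m in models.items()
        }
        ref = trunks["param_unet"]
        assert all(t == ref for t in trunks.values())
        # the input convolutions differ only in their input-channel axis
        first_param = models["param_unet"].unet.parameters()[0]
        first_causal = models["ctc_causal"].unet.parameters()[0]
        assert first_param.shape[0] == first_causal.shape[0]
        assert first_param.shape[2:] == first_causal.shape[2:]
        assert (first_param.shape[1], first_causal.shape[1]) == (4, 8)

    def test_temporal_block_weight_sharing_across_voxels(self, rng):
        model = build_model(
            "rc_causal", unet_cfg=UNetConfig(depth=2, base_filters=4), seed=2
        )
        x = rng.normal(size=(24, 1, 32))
        feats = model.temporal_block.forward(x)
        perm = rng.permutation(24)
        np.testing.assert_allclose(
            model.temporal_block.forward(x[perm]), feats[perm], atol=1e-6
        )

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_model("transformer")


class TestSoftDice:
    def test_perfect_prediction_zero_loss(self):
        truth = np.zeros((1, 4, 4))
        truth[0, 1:3, 1:3] = 1.0
        loss, _ = soft_dice_loss(truth, truth, smooth=0.0)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_prediction_unit_loss(self):
        truth = np.ones((1, 3, 3))
        loss, _ = soft_dice_loss(np.zeros_like(truth), truth, smooth=0.0)
        assert loss == pytest.approx(1.0)

    def test_empty_truth_zero_smooth_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            soft_dice_loss(np.zeros((1, 2, 2)), np.zeros((1, 2, 2)), smooth=0.0)

    def test_matches_formula_oracle(self, rng):
        pred = rng.random((2, 5, 5))
        truth = (rng.random((2, 5, 5)) < 0.4).astype(float)
        s = 1.0
        loss, _ = soft_dice_loss(pred, truth, smooth=s)
        expected = 1 - (2 * (pred * truth).sum() + s) / (pred.sum() + truth.sum() + s)
        assert loss == pytest.approx(expected, abs=1e-7)

    def test_gradient_matches_finite_difference(self, rng):
        pred = rng.random((1, 4, 4)) * 0.8 + 0.1
        truth = (rng.random((1, 4, 4)) < 0.5).astype(float)
        _, grad = soft_dice_loss(pred, truth, smooth=1.0)
        eps = 1e-7
        for idx in [(0, 0, 0), (0, 2, 3), (0, 3, 1)]:
            p2 = pred.copy()
            p2[idx] += eps
            lp, _ = soft_dice_loss(p2, truth, smooth=1.0)
            p2[idx] -= 2 * eps
            lm, _ = soft_dice_loss(p2, truth, smooth=1.0)
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)


def tiny_training_problem(rng, n=6, size=16):
    """Slices where the lesion is where channel-0 is hot: learnable."""
    x = rng.normal(size=(n, 4, size, size)).astype(np.float32)
    y = np.zeros((n, size, size), dtype=np.float32)
    for i in range(n):
        a, b = 4 + (i % 3), 9 + (i % 4)
        y[i, a:b, a:b] = 1.0
        x[i, 0] += 4.0 * y[i]
    return x, y


class TestTraining:
    def test_overfit_single_slice(self, rng):
        """200 epochs on one synthetic slice reach training Dice >= 0.9."""
        x, y = tiny_training_problem(rng, n=1)
        model = build_param_unet(UNetConfig(in_channels=4, depth=2, base_filters=8), seed=0)
        cfg = TrainConfig(eps=1e-7, max_epochs=200, patience=200, batch_size=1, seed=0)
        deepnet.train(model, x, y, x, y, cfg)
        prob = model.forward(x)[:, 1]
        pred = prob > 0.5
        dice = 2 * (pred * y).sum() / (pred.sum() + y.sum())
        assert dice >= 0.9

    def test_empty_slices_omitted_from_training(self, rng):
        x, y = tiny_training_problem(rng, n=4)
        y[1] = 0.0  # empty slice
        model = build_param_unet(UNetConfig(in_channels=4, depth=2, base_filters=4), seed=0)
        cfg = TrainConfig(max_epochs=1, batch_size=2, seed=0)
        result = deepnet.train(model, x, y, x, y, cfg)
        assert result["n_train_slices"] == 3
        assert result["n_val_slices"] == 3

    def test_no_nonempty_slices_rejected(self, rng):
        x = rng.normal(size=(2, 4, 8, 8))
        y = np.zeros((2, 8, 8))
        model = build_param_unet(SMALL_UNET, seed=0)
        with pytest.raises(ValueError):
            deepnet.train(model, x, y, x, y, TrainConfig(max_epochs=1))

    def test_patience_semantics_and_best_restore(self, rng, monkeypatch):
        """Training stops after exactly `patience` non-improving epochs and
        restores the best-epoch weights."""
        x, y = tiny_training_problem(rng, n=2)
        model = build_param_unet(UNetConfig(in_channels=4, depth=2, base_filters=4), seed=0)

        losses = iter([0.5, 0.4] + [0.45] * 20)
        recorded = {}

        def fake_eval(m, xs, ys, cfg):
            v = next(losses)
            if v == 0.4 and "best" not in recorded:
                recorded["best"] = [p.value.copy() for p in m.parameters()]
            return v

        monkeypatch.setattr(deepnet, "_eval_loss", fake_eval)
        cfg = TrainConfig(max_epochs=50, patience=3, batch_size=2, seed=0)
        result = deepnet.train(model, x, y, x, y, cfg)
        assert len(result["history"]) == 5  # best at epoch 1 + 3 stale epochs
        assert result["best_epoch"] == 1
        for p, v in zip(model.parameters(), recorded["best"]):
            np.testing.assert_array_equal(p.value, v)

    def test_fixed_seed_identical_history(self, rng):
        x, y = tiny_training_problem(rng, n=4)

        def run():
            model = build_param_unet(
                UNetConfig(in_channels=4, depth=2, base_filters=4), seed=7
            )
            cfg = TrainConfig(max_epochs=3, batch_size=2, seed=7)
            return deepnet.train(model, x, y, x, y, cfg)["history"]

        h1, h2 = run(), run()
        assert h1 == h2

    def test_predict_volume_range_and_shape(self, rng):
        model = build_param_unet(SMALL_UNET, seed=0)
        slices = rng.normal(size=(5, 4, 8, 8))
        prob = deepnet.predict_volume(model, slices, batch_size=2)
        assert prob.shape == (5, 8, 8)
        assert prob.min() >= 0 and prob.max() <= 1


class TestCheckpoint:
    def test_save_load_round_trip(self, rng, tmp_path):
        cfg = UNetConfig(in_channels=8, depth=2, base_filters=4)
        bcfg = TemporalBlockConfig(variant="causal")
        model = build_model("ctc_causal", unet_cfg=cfg, block_cfg=bcfg, seed=4)
        x = rng.normal(size=(2, 8, 8, 32)).astype(np.float32)
        ref = model.forward(x)
        deepnet.save_model(model, tmp_path / "m", "ctc_causal",
                           UNetConfig(in_channels=8, depth=2, base_filters=4), bcfg)
        clone, sidecar = deepnet.load_model(tmp_path / "m")
        assert sidecar["variant"] == "ctc_causal"
        np.testing.assert_allclose(clone.forward(x), ref, atol=1e-6)
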