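"""Network contracts: shapes, seeded init, exact gradients, schedule, training."""

import numpy as np
import pytest

from fernmask.segnet import AugmentConfig, TrainConfig, build_model, one_cycle_lr, predict_mask, train
from fernmask.segnet.model import load_checkpoint, save_checkpoint, to_input
from fernmask.segnet.train import bce_with_logits, soft_dice_loss

TINY = TrainConfig(image_size=32, encoder_depth=2, base_channels=4,
                   epochs=2, batch_size=2, seed=3)


class TestBuildModel:
    def test_forward_shape_and_finiteness(self):
        m = build_model(TINY)
        out = m.forward(np.zeros((2, 3, 32, 32), dtype=np.float32))
        assert out.shape == (2, 1, 32, 32)
        assert np.isfinite(out).all()

    @pytest.mark.parametrize("depth", [3, 4])
    def test_output_matches_input_size_at_256(self, depth):
        cfg = TrainConfig(image_size=256, encoder_depth=depth, base_channels=2, seed=0)
        m = build_model(cfg)
        out = m.forward(np.zeros((1, 3, 256, 256), dtype=np.float32))
        assert out.shape == (1, 1, 256, 256)

    def test_seeded_init_reproducible(self):
        a = build_model(TINY)
        b = build_model(TINY)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)
        c = build_model(TrainConfig(**{**TINY.__dict__, "seed": 4}))
        assert any((pa.value != pc.value).any()
                   for pa, pc in zip(a.parameters(), c.parameters()))

    def test_indivisible_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            TrainConfig(image_size=100, encoder_depth=3).validate()


class TestGradients:
    @pytest.mark.parametrize("loss_fn", [bce_with_logits, soft_dice_loss])
    def test_backprop_matches_finite_differences(self, loss_fn):
        """Exact analytic gradients: finite-difference check in float64
        on a sample of parameters from every layer family."""
        m = build_model(TINY)
        for p in m.parameters():
            p.value = p.value.astype(np.float64)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 3, 32, 32))
        y = (rng.random((2, 32, 32)) > 0.5).astype(np.float64)
        logits = m.forward(x)[:, 0]
        _, g = loss_fn(logits, y)
        m.backward(g[:, None].astype(np.float64))
        params = m.parameters()
        for pi in range(0, len(params), 3):
            p = params[pi]
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            eps = 1e-6
            old = float(p.value[idx])
            p.value[idx] = old + eps
            l1, _ = loss_fn(m.forward(x)[:, 0], y)
            p.value[idx] = old - eps
            l2, _ = loss_fn(m.forward(x)[:, 0], y)
            p.value[idx] = old
            num = (l1 - l2) / (2 * eps)
            assert p.grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestOneCycle:
    CFG = TrainConfig(lr_max=1e-2, warmup_fraction=0.3, div_factor=25.0,
                      final_div_factor=2.5e4)

    def test_endpoints_and_peak(self):
        total = 101
        assert one_cycle_lr(0, total, self.CFG) == pytest.approx(1e-2 / 25.0)
        peak_step = round(0.3 * (total - 1))
        assert one_cycle_lr(peak_step, total, self.CFG) == pytest.approx(1e-2)
        assert one_cycle_lr(total - 1, total, self.CFG) == pytest.approx(1e-2 / 2.5e4, abs=1e-9)

    def test_single_interior_maximum_and_continuity(self):
        total = 200
        lrs = np.array([one_cycle_lr(s, total, self.CFG) for s in range(total)])
        assert lrs.argmax() == round(0.3 * (total - 1))
        diffs = np.sign(np.diff(lrs))
        # monotone up then monotone down
        change_points = np.flatnonzero(np.diff(diffs) != 0)
        assert len(change_points) == 1
        assert np.abs(np.diff(lrs)).max() < self.CFG.lr_max * 0.1

    def test_out_of_range_step_errors(self):
        with pytest.raises(ValueError):
            one_cycle_lr(10, 10, self.CFG)


class TestTraining:
    def test_loss_decreases_on_synthetic_sheets(self, default_sheets):
        images = [s.image for s in default_sheets]
        masks = [s.truth for s in default_sheets]
        cfg = TrainConfig(image_size=32, encoder_depth=2, base_channels=4,
                          epochs=2, batch_size=4, seed=0)
        model = build_model(cfg)
        model, hist = train(model, images, masks, cfg, AugmentConfig())
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert len(hist.train_loss) == cfg.epochs
        assert len(hist.lr_trace) == cfg.epochs * int(np.ceil(16 / 4))

    def test_lr_trace_matches_schedule_pointwise(self, default_sheets):
        images = [s.image for s in default_sheets][:10]
        masks = [s.truth for s in default_sheets][:10]
        cfg = TrainConfig(image_size=32, encoder_depth=2, base_channels=4,
                          epochs=2, batch_size=4, seed=0)
        model = build_model(cfg)
        _, hist = train(model, images, masks, cfg, AugmentConfig.identity())
        total = len(hist.lr_trace)
        for s, lr in enumerate(hist.lr_trace):
            assert lr == pytest.approx(one_cycle_lr(s, total, cfg))

    def test_all_background_targets_converge_to_empty_prediction(self, rng):
        images = [rng.integers(0, 256, size=(48, 48, 3), dtype=np.uint8) for _ in range(10)]
        masks = [np.zeros((48, 48), dtype=np.uint8) for _ in range(10)]
        cfg = TrainConfig(image_size=32, encoder_depth=2, base_channels=4,
                          epochs=5, batch_size=4, seed=1)
        model = build_model(cfg)
        model, hist = train(model, images, masks, cfg, AugmentConfig.identity())
        # predictions converge toward empty; pixel accuracy toward 1
        fg_fraction = np.mean([(predict_mask(model, img) > 0).mean()
                               for img in images[:3]])
        assert fg_fraction < 0.005
        assert hist.val_loss[-1] < hist.val_loss[0]

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            train(build_model(TINY), [], [], TINY, AugmentConfig())


class TestPredictMask:
    @pytest.mark.parametrize("shape", [(91, 68), (50, 50), (37, 101)])
    def test_output_size_binarity_any_input_geometry(self, rng, shape):
        model = build_model(TINY)
        img = rng.integers(0, 256, size=(*shape, 3), dtype=np.uint8)
        mask = predict_mask(model, img)
        assert mask.shape == (32, 32)
        assert set(np.unique(mask)) <= {0, 255}

    def test_deterministic(self, rng):
        model = build_model(TINY)
        img = rng.integers(0, 256, size=(40, 40, 3), dtype=np.uint8)
        np.testing.assert_array_equal(predict_mask(model, img), predict_mask(model, img))


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        model = build_model(TINY)
        img = rng.integers(0, 256, size=(40, 40, 3), dtype=np.uint8)
        before = predict_mask(model, img)
        path = save_checkpoint(model, AugmentConfig(), tmp_path / "ckpt.npz")
        loaded, aug = load_checkpoint(path)
        assert loaded.cfg == model.cfg
        assert aug == AugmentConfig()
        np.testing.assert_array_equal(predict_mask(loaded, img), before)
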