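"""Dice / pixel-accuracy identities and report aggregation."""

import numpy as np
import pandas as pd
import pytest

from fernmask.evaluate import (count_pixel_predictions, dice, evaluate_model,
                               pixel_accuracy, summarize)


def as_mask(bool_arr):
    return np.where(bool_arr, 255, 0).astype(np.uint8)


class TestDice:
    def test_identical_nonempty_masks(self, rng):
        m = as_mask(rng.random((16, 16)) < 0.4)
        assert dice(m, m) == 1.0

    def test_disjoint_nonempty_masks(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = 255
        b[3, 3] = 255
        assert dice(a, b) == 0.0

    def test_half_overlap_worked_example(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = a[0, 1] = 255       # two foreground pixels
        b[0, 1] = b[0, 2] = 255       # two foreground pixels, one shared
        assert dice(a, b) == 0.5

    def test_complement_gives_zero(self, rng):
        a = as_mask(rng.random((10, 10)) < 0.5)
        assert dice(a, 255 - a) == 0.0

    def test_symmetry(self, rng):
        for _ in range(20):
            a = as_mask(rng.random((12, 12)) < rng.uniform(0.1, 0.9))
            b = as_mask(rng.random((12, 12)) < rng.uniform(0.1, 0.9))
            assert dice(a, b) == dice(b, a)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((5, 5), dtype=np.uint8)
        assert dice(z, z) == 1.0

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4), dtype=np.uint8), np.zeros((4, 5), dtype=np.uint8))


class TestPixelAccuracy:
    def test_identities(self, rng):
        a = as_mask(rng.random((8, 8)) < 0.5)
        assert pixel_accuracy(a, a) == 1.0
        assert pixel_accuracy(a, 255 - a) == 0.0

    def test_655_differing_pixels_at_256(self, rng):
        a = as_mask(rng.random((256, 256)) < 0.3)
        b = a.copy()
        flat = b.reshape(-1)
        idx = rng.choice(flat.size, size=655, replace=False)
        flat[idx] = 255 - flat[idx]
        assert pixel_accuracy(a, b) == pytest.approx(1.0 - 655 / 65536)

    def test_accuracy_exceeds_dice_by_at_most_shared_background(self, rng):
        """The two metrics diverge only through the shared-background mass:
        pixel_accuracy - dice <= fraction of pixels background in both."""
        for _ in range(200):
            a = as_mask(rng.random((16, 16)) < rng.uniform(0.05, 0.95))
            b = as_mask(rng.random((16, 16)) < rng.uniform(0.05, 0.95))
            shared_bg = float(((a == 0) & (b == 0)).mean())
            assert pixel_accuracy(a, b) - dice(a, b) <= shared_bg + 1e-12


class TestCountPixelPredictions:
    @pytest.mark.parametrize("n,size,expected", [
        (1, 256, 65_536),
        (320, 256, 20_971_520),
        (80, 256, 5_242_880),
        (0, 256, 0),
    ])
    def test_counts(self, n, size, expected):
        assert count_pixel_predictions(n, size) == expected


class TestSummarize:
    def test_injected_scores_arithmetic(self):
        per_image = pd.DataFrame({
            "catalog_number": ["a", "b", "c", "d"],
            "family": ["F1", "F1", "F2", "F2"],
            "dice": [1.0, 0.8, 0.6, 0.6],
            "pixel_accuracy": [1.0, 0.9, 0.7, 0.7],
        })
        report = summarize(per_image, size=256)
        fam = report.per_family.set_index("family")
        assert fam.loc["F1", "mean_dice"] == pytest.approx(0.9)
        assert fam.loc["F2", "mean_dice"] == pytest.approx(0.6)
        assert report.overall["mean_dice"] == pytest.approx(0.75)
        assert fam["n_images"].sum() == report.overall["n_images"] == 4
        assert report.overall["total_pixel_predictions"] == 4 * 65536

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(columns=["family", "dice", "pixel_accuracy"]), 256)


@pytest.fixture(scope="module")
def trained_setup(tmp_path_factory):
    from fernmask.segnet import AugmentConfig, TrainConfig, build_model, train
    from fernmask.synthetic import SheetConfig, generate_dataset
    from fernmask.imaging import read_image, read_mask

    out = tmp_path_factory.mktemp("eval_ds")
    manifest = generate_dataset(12, SheetConfig(seed=77), out)
    cfg = TrainConfig(image_size=64, encoder_depth=3, base_channels=8,
                      epochs=3, batch_size=4, seed=0)
    images = [read_image(out / r.image) for r in manifest.itertuples()]
    masks = [read_mask(out / r.mask) for r in manifest.itertuples()]
    model = build_model(cfg)
    model, _ = train(model, images, masks, cfg, AugmentConfig.identity())
    return model, manifest, out


class TestEvaluateModel:
    def test_report_shape_and_invariants(self, trained_setup):
        model, manifest, out = trained_setup
        report = evaluate_model(model, manifest, base_dir=out)
        assert len(report.per_image) == 12
        assert report.per_family["n_images"].sum() == 12
        assert ((report.per_image["dice"] >= 0) & (report.per_image["dice"] <= 1)).all()
        assert report.overall["total_pixel_predictions"] == 12 * 64 * 64
        assert report.per_family["family"].is_unique

    def test_deterministic_on_repeat(self, trained_setup):
        model, manifest, out = trained_setup
        r1 = evaluate_model(model, manifest, base_dir=out)
        r2 = evaluate_model(model, manifest, base_dir=out)
        pd.testing.assert_frame_equal(r1.per_image, r2.per_image)

    def test_missing_file_collected_run_continues(self, trained_setup):
        model, manifest, out = trained_setup
        broken = manifest.copy()
        broken.loc[0, "image"] = "does_not_exist.png"
        report = evaluate_model(model, broken, base_dir=out)
        assert len(report.errors) == 1
        assert len(report.per_image) == 11

    def test_empty_manifest_errors(self, trained_setup):
        model, manifest, out = trained_setup
        with pytest.raises(ValueError):
            evaluate_model(model, manifest.iloc[:0], base_dir=out)
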