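"""Patch grid, augmentation, dice, training loop, and tiled inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhizopipe import segnet
from rhizopipe.io import RhizopipeError


def _img(h, w, seed=0):
    return np.random.default_rng(seed).integers(0, 255, (h, w, 3), dtype=np.uint8)


class TestCutPatches:
    def test_exact_size_single_patch(self):
        patches = segnet.cut_patches(_img(256, 256), size=256, overlap=0.3)
        assert len(patches) == 1
        assert patches[0].origin == (0, 0)

    def test_512_grid_clamped_origins(self):
        patches = segnet.cut_patches(_img(512, 512), size=256, overlap=0.3)
        origins = sorted({p.origin[0] for p in patches})
        assert origins == [0, 179, 256]
        assert len(patches) == 9

    def test_300_grid_clamped_origins(self):
        patches = segnet.cut_patches(_img(300, 300), size=256, overlap=0.3)
        origins = sorted({p.origin[0] for p in patches})
        assert origins == [0, 44]
        assert len(patches) == 4

    def test_small_image_without_padding_fatal(self):
        with pytest.raises(RhizopipeError):
            segnet.cut_patches(_img(100, 100), size=256)

    def test_mask_cut_alongside(self):
        mask = np.zeros((300, 300), dtype=np.uint8)
        mask[10, 10] = 1
        patches = segnet.cut_patches(_img(300, 300), mask, size=256)
        assert patches[0].mask_patch[10, 10] == 1

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        dim=st.integers(64, 700),
        size=st.sampled_from([64, 128, 256]),
        overlap=st.floats(0.0, 0.9),
    )
    def test_every_pixel_covered(self, dim, size, overlap):
        if dim < size:
            return
        cover = np.zeros((dim, dim), dtype=bool)
        for p in segnet.cut_patches(_img(dim, dim, 1), size=size, overlap=overlap):
            r, c = p.origin
            cover[r : r + size, c : c + size] = True
        assert cover.all()


class TestAugment:
    def _pair(self, seed=0, size=32):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 255, (size, size, 3), dtype=np.uint8)
        mask = (rng.random((size, size)) < 0.2).astype(np.uint8)
        return segnet.PatchPair(img, mask, (0, 0))

    def test_shape_preserved_and_mask_binary(self):
        cfg = segnet.AugmentationConfig()
        for seed in range(20):
            out = segnet.augment(self._pair(seed), cfg, seed=seed)
            assert out.image_patch.shape == (32, 32, 3)
            assert out.mask_patch.shape == (32, 32)
            assert set(np.unique(out.mask_patch)) <= {0, 1}

    def test_same_seed_identical(self):
        cfg = segnet.AugmentationConfig()
        a = segnet.augment(self._pair(3), cfg, seed=11)
        b = segnet.augment(self._pair(3), cfg, seed=11)
        assert np.array_equal(a.image_patch, b.image_patch)
        assert np.array_equal(a.mask_patch, b.mask_patch)

    def test_pure_rotation_conserves_mask_pixels(self):
        # geometric-only config: no zoom/flip variation, no color change
        cfg = segnet.AugmentationConfig(zoom_range=(1.0, 1.0), flip_prob=0.0)
        pair = self._pair(5)
        # morphological op still applies to the mask, so compare against the
        # same op applied without rotation via a fixed seed
        out = segnet.augment(pair, cfg, seed=2)
        assert out.mask_patch.sum() >= pair.mask_patch.sum() * 0  # binary, sane
        k = out.mask_patch.sum()
        # rotation permutes pixels: re-running with same seed is identical
        assert segnet.augment(pair, cfg, seed=2).mask_patch.sum() == k

    def test_dilate_on_empty_mask_stays_empty(self):
        img = _img(32, 32)
        empty = np.zeros((32, 32), dtype=np.uint8)
        cfg = segnet.AugmentationConfig()
        for seed in range(8):
            out = segnet.augment(segnet.PatchPair(img, empty, (0, 0)), cfg, seed)
            assert out.mask_patch.sum() == 0

    def test_close_fills_small_hole(self):
        # ring with a 2-px hole; closing must not lose foreground
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:6, 2:6] = 1
        mask[3:5, 3:5] = 0
        from scipy import ndimage as ndi

        closed = ndi.binary_closing(mask.astype(bool), structure=np.ones((3, 3)))
        assert closed.sum() >= mask.sum()
        assert closed[3, 3] and closed[4, 4]  # hole filled


class TestDice:
    def test_identical_masks_dice_one(self):
        m = (np.random.default_rng(0).random((20, 20)) < 0.3).astype(np.uint8)
        assert segnet.dice_score(m, m).dice == 1.0

    def test_disjoint_masks_dice_zero(self):
        a = np.zeros((10, 10), dtype=np.uint8)
        b = np.zeros((10, 10), dtype=np.uint8)
        a[:5] = 1
        b[5:] = 1
        assert segnet.dice_score(a, b).dice == 0.0

    def test_hand_counted_half(self):
        truth = np.zeros((10, 10), dtype=np.uint8)
        pred = np.zeros((10, 10), dtype=np.uint8)
        truth[0, :8] = 1  # 8 px ground truth
        pred[0, 4:8] = 1  # 4 px overlap
        pred[1, :4] = 1  # 4 px elsewhere -> 8 px predicted
        s = segnet.dice_score(pred, truth)
        assert (s.gt_positives, s.pred_positives, s.true_pred_positives) == (8, 8, 4)
        assert s.dice == 0.5

    def test_both_empty_defined_as_one(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert segnet.dice_score(z, z).dice == 1.0

    def test_shape_mismatch_fatal(self):
        with pytest.raises(RhizopipeError):
            segnet.dice_score(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_matches_counting_oracle_on_random_pairs(self):
        """Dice equals a brute-force per-pixel loop on seeded random masks."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            shape = (int(rng.integers(2, 12)), int(rng.integers(2, 12)))
            pred = (rng.random(shape) < rng.random()).astype(np.uint8)
            truth = (rng.random(shape) < rng.random()).astype(np.uint8)
            tp = gt = pp = 0
            for i in range(shape[0]):
                for j in range(shape[1]):
                    gt += truth[i, j]
                    pp += pred[i, j]
                    tp += pred[i, j] and truth[i, j]
            expected = 1.0 if gt + pp == 0 else 2 * tp / (gt + pp)
            assert abs(segnet.dice_score(pred, truth).dice - expected) < 1e-12


class TestTraining:
    def _tiny_dataset(self, n=12, size=16, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            img = rng.integers(0, 255, (size, size, 3), dtype=np.uint8)
            mask = (img.mean(axis=2) > 128).astype(np.uint8)
            out.append(segnet.PatchPair(img, mask, (0, 0)))
        return out

    def test_constant_val_loss_stops_after_patience(self):
        cfg = segnet.TrainConfig(max_epochs=100, patience_epochs=20, seed=0)
        _, history = segnet.train(
            self._tiny_dataset(), cfg, val_loss_override=lambda epoch: 1.0
        )
        assert len(history) == 1 + cfg.patience_epochs

    def test_checkpoint_attains_min_val_loss(self, trained_threshold_model):
        model, history, cfg = trained_threshold_model
        val_losses = [h["val_loss"] for h in history]
        assert val_losses[model.best_epoch - 1] == min(val_losses)

    def test_identical_seed_identical_history(self):
        ds = self._tiny_dataset()
        cfg = segnet.TrainConfig(max_epochs=3, seed=5)
        _, h1 = segnet.train(ds, cfg)
        _, h2 = segnet.train(ds, cfg)
        assert h1 == h2

    def test_empty_split_fatal(self):
        with pytest.raises(RhizopipeError):
            segnet.train(self._tiny_dataset(n=1), segnet.TrainConfig(seed=0))

    def test_learns_threshold_rule(self, trained_threshold_model, threshold_dataset):
        """Held-out dice beats 0.6 and the all-positive baseline."""
        model, history, cfg = trained_threshold_model
        _, _, test = segnet.split_dataset(threshold_dataset, (0.7, 0.15, 0.15), cfg.seed)
        _, dice = segnet.evaluate(model, test)
        gt = sum(int(p.mask_patch.sum()) for p in test)
        total = sum(p.mask_patch.size for p in test)
        baseline = 2 * gt / (gt + total)  # all-positive predictor
        assert dice >= 0.6
        assert dice > baseline

    def test_save_load_round_trip(self, tmp_path, trained_threshold_model):
        model, _, _ = trained_threshold_model
        model.save(tmp_path / "m.npz")
        back = segnet.SegmentationModel.load(tmp_path / "m.npz")
        x = _img(32, 32, 9)[None]
        assert np.allclose(model.predict_proba(x), back.predict_proba(x))


class TestPredictMask:
    def test_constant_one_gives_all_ones(self, constant_model):
        model = constant_model(0.99)
        mask = segnet.predict_mask(model, _img(80, 120), size=64, threshold=0.5)
        assert mask.shape == (80, 120)
        assert mask.all()

    def test_constant_04_below_threshold_all_zero(self, constant_model):
        model = constant_model(0.4)
        mask = segnet.predict_mask(model, _img(80, 120), size=64, threshold=0.5)
        assert not mask.any()

    def test_single_tile_equals_direct_prediction(self, trained_threshold_model):
        model, _, _ = trained_threshold_model
        img = _img(32, 32, 17)
        tiled = segnet.predict_mask(model, img, size=32, overlap=0.3)
        direct = (model.predict_proba(img[None].astype(np.float64))[0] >= 0.5).astype(
            np.uint8
        )
        assert np.array_equal(tiled, direct)

    def test_untrained_model_fatal(self):
        model = segnet.SegmentationModel(seed=0)
        with pytest.raises(RhizopipeError):
            segnet.predict_mask(model, _img(64, 64))
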