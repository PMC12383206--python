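"""Metrics, classic augmentations and the segmentation training loop."""

import numpy as np
import pytest

from cardiacdiff.phantoms import PhantomSpec, generate_phantom
from cardiacdiff.segmentation import (AugmentedPair, affine_augment,
                                      cutmix_augment, dice_iou,
                                      elastic_augment, evaluate_masks,
                                      intensity_augment, toy_seg_config,
                                      train_unet_seg)


class TestDiceIou:
    def test_perfect_overlap(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[2:5, 2:5] = 1
        assert dice_iou(m, m, 1) == (1.0, 1.0)

    def test_disjoint_regions(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.zeros((8, 8), dtype=np.uint8)
        a[0, 0] = 1
        b[7, 7] = 1
        assert dice_iou(a, b, 1) == (0.0, 0.0)

    def test_hand_counted_example(self):
        """|P|=4, |G|=2, overlap 2: DSC = 2·2/6 = 2/3, IoU = 2/4 = 1/2."""
        p = np.zeros((4, 4), dtype=np.uint8)
        g = np.zeros((4, 4), dtype=np.uint8)
        p[0, :4] = 1
        g[0, :2] = 1
        dsc, iou = dice_iou(p, g, 1)
        assert dsc == pytest.approx(2 / 3, abs=1e-12)
        assert iou == pytest.approx(0.5, abs=1e-12)

    def test_empty_class_conventions(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        o = np.zeros((4, 4), dtype=np.uint8)
        o[0, 0] = 2
        assert dice_iou(z, z, 2) == (1.0, 1.0)
        assert dice_iou(o, z, 2) == (0.0, 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_iou(np.zeros((2, 2)), np.zeros((3, 3)), 1)

    def test_dice_iou_identity_random_masks(self):
        """D = 2I/(1+I) holds for every class on 1000 random mask pairs."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.integers(0, 4, (8, 8)).astype(np.uint8)
            g = rng.integers(0, 4, (8, 8)).astype(np.uint8)
            cid = int(rng.integers(1, 4))
            dsc, iou = dice_iou(p, g, cid)
            assert dsc == pytest.approx(2 * iou / (1 + iou), abs=1e-12)


class TestAugmentations:
    @pytest.fixture(scope="class")
    def pair(self):
        p = generate_phantom(PhantomSpec(grid_size=32, seed=1))
        return AugmentedPair(p.image, p.mask, "real")

    def test_affine_identity_parameters(self, pair):
        out = affine_augment(pair, seed=0, max_rotate=0.0, scale_range=(1.0, 1.0),
                             max_shift=0.0)
        assert np.allclose(out.image, pair.image, atol=1e-6)
        assert np.array_equal(out.mask, pair.mask)

    def test_rotation_matches_index_remap(self, pair):
        """A 90° rotation through our transform equals np.rot90 exactly."""
        from cardiacdiff.segmentation import _spatial_transform
        theta = np.deg2rad(90.0)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        center = np.array([15.5, 15.5])
        offset = center - rot @ center
        _, got = _spatial_transform(pair.image, pair.mask, rot, offset)
        assert np.array_equal(got, np.rot90(pair.mask, k=-1))

    def test_spatial_transforms_keep_masks_valid(self, pair):
        for fn, kw in ((affine_augment, {}), (elastic_augment, {})):
            out = fn(pair, seed=3, **kw)
            assert set(np.unique(out.mask)) <= {0, 1, 2, 3}
            assert out.mask.shape == pair.mask.shape

    def test_intensity_leaves_mask_untouched(self, pair):
        out = intensity_augment(pair, seed=5)
        assert np.array_equal(out.mask, pair.mask)
        assert not np.array_equal(out.image, pair.image)

    def test_augment_deterministic_per_seed(self, pair):
        for fn in (affine_augment, elastic_augment, intensity_augment):
            a, b = fn(pair, seed=9), fn(pair, seed=9)
            assert np.array_equal(a.image, b.image)
            assert np.array_equal(a.mask, b.mask)

    def test_cutmix_full_box_returns_b(self, pair):
        other = AugmentedPair(*_phantom_arrays(2), "real")
        out = cutmix_augment(pair, other, box=(0, 0, 32, 32))
        assert np.array_equal(out.image, other.image)
        assert np.array_equal(out.mask, other.mask)

    def test_cutmix_half_box_positional(self, pair):
        other = AugmentedPair(*_phantom_arrays(2), "real")
        out = cutmix_augment(pair, other, box=(0, 0, 16, 32))
        assert np.array_equal(out.image[:16], other.image[:16])
        assert np.array_equal(out.image[16:], pair.image[16:])
        assert np.array_equal(out.mask[:16], other.mask[:16])
        assert np.array_equal(out.mask[16:], pair.mask[16:])

    def test_cutmix_empty_box_rejected(self, pair):
        with pytest.raises(ValueError):
            cutmix_augment(pair, pair, box=(4, 4, 4, 10))


def _phantom_arrays(seed):
    p = generate_phantom(PhantomSpec(grid_size=32, seed=seed))
    return p.image, p.mask


class TestTraining:
    def test_overfit_single_pair(self):
        p = generate_phantom(PhantomSpec(grid_size=32, seed=4))
        pair = AugmentedPair(p.image, p.mask, "real")
        cfg = toy_seg_config(channels=(8, 16), epochs=150, batch_size=1)
        model, _ = train_unet_seg([pair], [pair], cfg, seed=0)
        pred = model.predict(p.image[None])[0]
        m = evaluate_masks([pred], [p.mask])
        assert m.mean_dice > 0.95

    def test_metric_trajectory_deterministic(self, toy_dataset):
        pairs = [AugmentedPair(p.image, p.mask, "real") for p in toy_dataset.train[:6]]
        val = toy_dataset.val
        cfg = toy_seg_config(channels=(4, 8), norm_groups=2, epochs=3, batch_size=2)
        _, h1 = train_unet_seg(pairs, val, cfg, seed=1)
        _, h2 = train_unet_seg(pairs, val, cfg, seed=1)
        assert h1 == h2

    def test_empty_train_set_rejected(self):
        with pytest.raises(ValueError):
            train_unet_seg([], [], toy_seg_config(), seed=0)
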