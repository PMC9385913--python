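"""Preprocessing and augmentation: crops, normalization, contour surgery."""

import numpy as np
import pytest
from scipy import stats

from contourqa.core import Volume
from contourqa.datapipe import (
    AugmentConfig,
    GeometricTransform,
    center_crop,
    default_crop_shape,
    geometric_augment,
    make_training_batch,
    normalize_intensity,
    preprocess_pair,
    sample_transform,
    scale_contour,
    stack_channels,
    swap_contour,
)
from contourqa.metrics import dice


class TestCenterCrop:
    def test_half_inplane_crop_offsets(self):
        vol = np.arange(320 * 320 * 28, dtype=float).reshape(320, 320, 28)
        out = center_crop(vol, (160, 160, 28))
        assert out.shape == (160, 160, 28)
        assert np.array_equal(out, vol[80:240, 80:240, :])

    def test_identity_crop(self, rng):
        vol = rng.random((7, 6, 5))
        assert np.array_equal(center_crop(vol, (7, 6, 5)), vol)

    def test_odd_margin_drops_high_side(self):
        vol = np.arange(5 * 5 * 5, dtype=float).reshape(5, 5, 5)
        out = center_crop(vol, (2, 2, 2))
        assert np.array_equal(out, vol[1:3, 1:3, 1:3])

    def test_too_large_raises(self):
        with pytest.raises(ValueError, match="crop"):
            center_crop(np.zeros((4, 4, 4)), (5, 4, 4))

    def test_volume_keeps_spacing(self, rng):
        v = Volume(rng.random((8, 8, 4)), (1.0, 2.0, 3.0))
        out = center_crop(v, (4, 4, 4))
        assert isinstance(out, Volume) and out.spacing == (1.0, 2.0, 3.0)


class TestNormalizeIntensity:
    def test_percentile_affine_map(self, rng):
        data = rng.uniform(10, 50, (20, 20, 10))
        out = normalize_intensity(Volume(data)).data
        p0, p99 = data.min(), np.percentile(data, 99)
        assert np.allclose(out, (data - p0) * 255.0 / (p99 - p0), atol=1e-9)
        assert out.min() == pytest.approx(0.0, abs=1e-9)
        # values above p99 keep following the affine map (no clipping)
        assert out.max() > 255.0

    def test_clip_flag(self, rng):
        data = rng.uniform(0, 100, (15, 15, 6))
        out = normalize_intensity(Volume(data), clip=True).data
        assert out.max() <= 255.0 and out.min() >= 0.0

    def test_order_preserving(self, rng):
        data = rng.normal(100, 30, (12, 12, 6))
        out = normalize_intensity(Volume(data)).data
        assert np.array_equal(np.argsort(data.ravel(), kind="stable"),
                              np.argsort(out.ravel(), kind="stable"))

    def test_idempotent_on_fixed_point(self):
        # an image already spanning [0, 255] with p99 = 255 is a fixed point
        data = np.linspace(0, 255, 12 * 12 * 8).reshape(12, 12, 8)
        data[-1, -1, -1] = 255.0
        once = normalize_intensity(Volume(data)).data
        twice = normalize_intensity(Volume(once)).data
        assert np.allclose(once, twice, atol=1e-9)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="percentile"):
            normalize_intensity(Volume(np.full((5, 5, 5), 7.0)))


class TestStackChannels:
    def test_shape_and_bit_exact_channels(self, rng):
        img = Volume(rng.random((16, 16, 8)) * 255)
        con = rng.random((16, 16, 8)) < 0.3
        t = stack_channels(img, con)
        assert t.shape == (16, 16, 8, 2)
        assert np.array_equal(t[..., 0], img.data)
        assert np.array_equal(t[..., 1].astype(bool), con)
        assert set(np.unique(t[..., 1])) <= {0.0, 1.0}

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="shape"):
            stack_channels(Volume(rng.random((4, 4, 4))), np.ones((5, 4, 4), bool))


class TestSwapContour:
    def test_pool_of_two_always_other(self, small_cohort, rng):
        pool = small_cohort[:2]
        for _ in range(20):
            _, donor = swap_contour(pool[0].case_id, pool, rng)
            assert donor == pool[1].case_id

    def test_own_contour_never_drawn(self, small_cohort, rng):
        for _ in range(1000):
            _, donor = swap_contour(small_cohort[0].case_id, small_cohort, rng)
            assert donor != small_cohort[0].case_id

    def test_donor_frequency_roughly_uniform(self, small_cohort, rng):
        counts = {}
        n_draws = 700
        for _ in range(n_draws):
            _, donor = swap_contour(small_cohort[0].case_id, small_cohort, rng)
            counts[donor] = counts.get(donor, 0) + 1
        observed = [counts.get(c.case_id, 0) for c in small_cohort[1:]]
        _, p = stats.chisquare(observed)
        assert p > 1e-3  # sanity, not strict uniformity

    def test_single_case_pool_raises(self, small_cohort, rng):
        with pytest.raises(ValueError, match="pool"):
            swap_contour(small_cohort[0].case_id, small_cohort[:1], rng)


class TestScaleContour:
    @staticmethod
    def centered_cube(shape=(32, 32, 8), half=4):
        m = np.zeros(shape, bool)
        cx, cy, cz = shape[0] // 2, shape[1] // 2, shape[2] // 2
        m[cx - half:cx + half, cy - half:cy + half, cz - 2:cz + 2] = True
        return m

    def test_factor_one_identity(self):
        m = self.centered_cube()
        assert np.array_equal(scale_contour(m, 1.0), m)

    def test_doubling_quadruples_cross_section(self):
        m = self.centered_cube()
        out = scale_contour(m, 2.0)
        ratio = out[:, :, 4].sum() / m[:, :, 4].sum()
        assert ratio == pytest.approx(4.0, rel=0.15)
        # z extent untouched
        assert np.array_equal(out.any(axis=(0, 1)), m.any(axis=(0, 1)))

    def test_shrink_monotone(self):
        m = self.centered_cube()
        assert scale_contour(m, 0.55).sum() < m.sum()

    def test_degenerate_raises(self):
        m = np.zeros((8, 8, 4), bool)
        with pytest.raises(ValueError, match="empty"):
            scale_contour(m, 0.5)
        m[4, 4, 2] = True
        with pytest.raises(ValueError):
            scale_contour(m, -1.0)


class TestGeometricTransform:
    def test_identity_ranges_are_identity(self, small_case, rng):
        cfg = AugmentConfig().identity()
        img, (gt,) = geometric_augment(small_case.image, [small_case.gt], cfg, rng)
        assert np.array_equal(img.data, small_case.image.data)
        assert np.array_equal(gt, small_case.gt)

    def test_flip_is_involution(self, small_case):
        t = GeometricTransform(shape=small_case.gt.shape, flip=True)
        once = t.apply_mask(small_case.gt)
        twice = t.apply_mask(once)
        assert np.array_equal(twice, small_case.gt)
        assert np.array_equal(once, np.flip(small_case.gt, axis=0))

    def test_masks_stay_binary_and_shapes_kept(self, small_case, rng):
        cfg = AugmentConfig(elastic_sigma=3.0, elastic_alpha=1.5)
        img, masks = geometric_augment(small_case.image,
                                       [small_case.gt, ~small_case.gt], cfg, rng)
        assert img.shape == small_case.image.shape
        for m in masks:
            assert m.shape == small_case.gt.shape and m.dtype == bool

    def test_rigid_transform_preserves_overlap(self, small_cohort, rng):
        """Rigid-only transforms applied to both masks barely change their
        Dice (nearest-neighbor discretization only)."""
        cfg = AugmentConfig(elastic_alpha=0.0)  # rigid + zoom only
        case = small_cohort[0]
        contour = case.auto_contours[0][0]
        base = dice(contour, case.gt)
        for _ in range(100):
            t = sample_transform(case.gt.shape, cfg, rng)
            gt_t = t.apply_mask(case.gt)
            con_t = t.apply_mask(contour)
            if gt_t.any() or con_t.any():
                assert abs(dice(con_t, gt_t) - base) < 0.05


class TestTrainingBatches:
    def test_targets_exact_after_all_transforms(self, small_cohort, rng):
        cfg = AugmentConfig(elastic_sigma=3.0, elastic_alpha=1.5)
        samples, gts = make_training_batch(
            small_cohort[0], small_cohort, cfg, rng, n_pairs=4, return_gts=True
        )
        assert len(samples) == 8
        for s, gt in zip(samples, gts):
            con = s.tensor[..., 1].astype(bool)
            expected = dice(con, gt) if (con.any() or gt.any()) else 1.0
            assert s.target == expected  # exact, machine precision

    def test_real_fake_ratio_and_flags(self, small_cohort, rng):
        cfg = AugmentConfig()
        samples = make_training_batch(small_cohort[0], small_cohort, cfg, rng,
                                      n_pairs=3)
        assert [s.is_fake for s in samples] == [False, True] * 3

    def test_no_augment_real_pair_matches_manifest(self, small_cohort):
        case = small_cohort[0]
        mask, true_dice = case.auto_contours[0]
        sample = preprocess_pair(case, mask)
        assert sample.target == true_dice
        assert sample.tensor.shape[:3] == default_crop_shape(case.image.shape)

    def test_normalize_order_option_changes_scale_only(self, small_cohort):
        case = small_cohort[0]
        mask, _ = case.auto_contours[0]
        after = preprocess_pair(case, mask)
        before = preprocess_pair(case, mask, normalize_before_crop=True)
        # same target and contour; percentiles from different fields of view
        assert before.target == after.target
        assert np.array_equal(before.tensor[..., 1], after.tensor[..., 1])
        assert not np.array_equal(before.tensor[..., 0], after.tensor[..., 0])

    def test_fake_targets_widen_the_band(self, small_cohort, rng):
        cfg = AugmentConfig(elastic_sigma=3.0, elastic_alpha=1.0)
        fake_targets = []
        for _ in range(150):
            samples = make_training_batch(small_cohort[0], small_cohort, cfg, rng)
            fake_targets.extend(s.target for s in samples if s.is_fake)
        span = max(fake_targets) - min(fake_targets)
        assert min(fake_targets) < 0.847
        assert span > 0.943 - 0.847

    def test_small_pool_raises(self, small_cohort, rng):
        with pytest.raises(ValueError, match="pool"):
            make_training_batch(small_cohort[0], small_cohort[:1],
                                AugmentConfig(), rng)


def test_full_pipeline_determinism(small_cohort):
    cfg = AugmentConfig(elastic_sigma=3.0, elastic_alpha=1.0)
    out = []
    for _ in range(2):
        rng = np.random.default_rng(77)
        samples = make_training_batch(small_cohort[1], small_cohort, cfg, rng,
                                      n_pairs=2)
        out.append(samples)
    for a, b in zip(*out):
        assert np.array_equal(a.tensor, b.tensor) and a.target == b.target
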