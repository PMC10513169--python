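"""The balloon signal model, phantom generator and dataset builder."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cathtrack import (
    DatasetConfig,
    GaussianCatheterParams,
    build_dataset,
    build_dynamic_dataset,
    gaussian_profile,
    generate_phantom,
    make_gt_mask,
    sample_catheter_params,
    simulate_catheter,
)
from cathtrack.synthetic import gaussian_field, generate_phantom_stack


def brute_force_mask(params, shape):
    """Independent oracle: per-pixel Mahalanobis distance via the explicit
    inverse covariance of the rotated Gaussian."""
    th = math.radians(params.theta_deg)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    cov = R @ np.diag([params.sigma_x**2, params.sigma_y**2]) @ R.T
    cov_inv = np.linalg.inv(cov)
    mask = np.zeros(shape, dtype=np.uint8)
    for r in range(shape[0]):
        for c in range(shape[1]):
            d = np.array([r - params.center_row, c - params.center_col])
            if math.sqrt(d @ cov_inv @ d) <= params.mask_radius_sd:
                mask[r, c] = 1
    return mask


class TestGaussianProfile:
    def test_peak_at_center(self):
        p = GaussianCatheterParams(30, 40, 2.5, 1.5, 137, 300)
        assert gaussian_profile(p, (30, 40)) == pytest.approx(1.0)

    def test_isotropic_closed_form(self):
        # isotropic sigma=1.5: any pixel at Euclidean distance 2.25 sits at
        # 1.5 standard deviations -> exp(-1.5^2/2)
        p = GaussianCatheterParams(32, 32, 1.5, 1.5, 45, 200)
        expected = math.exp(-0.5 * (2.25 / 1.5) ** 2)
        assert gaussian_profile(p, (32, 32 + 2.25)) == pytest.approx(expected, rel=1e-12)
        d = 2.25 / math.sqrt(2)
        assert gaussian_profile(p, (32 + d, 32 - d)) == pytest.approx(expected, rel=1e-12)

    def test_rotation_moves_major_axis(self):
        # theta=90 with offset along columns equals theta=0 with the same
        # offset along rows
        a = GaussianCatheterParams(32, 32, 2.5, 1.5, 90, 200)
        b = GaussianCatheterParams(32, 32, 2.5, 1.5, 0, 200)
        for k in (1.0, 2.0, 3.5):
            assert gaussian_profile(a, (32, 32 + k)) == \
                pytest.approx(gaussian_profile(b, (32 + k, 32)), rel=1e-9)

    def test_brute_force_rotated_covariance(self):
        # exp(-d^2/2) with d from the explicit inverse-covariance quadratic form
        p = GaussianCatheterParams(20, 25, 2.5, 1.5, 73, 400)
        th = math.radians(73)
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        cov_inv = np.linalg.inv(R @ np.diag([2.5**2, 1.5**2]) @ R.T)
        for px in [(20, 25), (22, 24), (17.5, 28.0), (25, 25)]:
            d = np.array([px[0] - 20, px[1] - 25])
            expected = math.exp(-0.5 * float(d @ cov_inv @ d))
            assert gaussian_profile(p, px) == pytest.approx(expected, rel=1e-9)


class TestGroundTruthMask:
    def test_isotropic_small_sigma_pixel_count(self):
        # 21 pixels lie within Euclidean distance 2.25 of the centre
        p = GaussianCatheterParams(64, 64, 1.5, 1.5, 0, 200)
        assert make_gt_mask(p, (128, 128)).sum() == 21

    def test_isotropic_rotation_invariance(self):
        a = GaussianCatheterParams(64, 64, 1.5, 1.5, 0, 200)
        b = GaussianCatheterParams(64, 64, 1.5, 1.5, 137, 200)
        assert np.array_equal(make_gt_mask(a, (128, 128)), make_gt_mask(b, (128, 128)))

    def test_monotone_in_sigma(self):
        small = GaussianCatheterParams(64, 64, 1.5, 1.5, 0, 200)
        big = GaussianCatheterParams(64, 64, 2.5, 2.5, 0, 200)
        assert make_gt_mask(big, (128, 128)).sum() > make_gt_mask(small, (128, 128)).sum()

    @pytest.mark.parametrize("sx", [1.5, 2.5])
    @pytest.mark.parametrize("sy", [1.5, 2.5])
    @pytest.mark.parametrize("theta", list(range(0, 360, 30)))
    def test_matches_bruteforce_mahalanobis_oracle(self, sx, sy, theta):
        p = GaussianCatheterParams(16, 17, sx, sy, theta, 200)
        assert np.array_equal(make_gt_mask(p, (32, 32)), brute_force_mask(p, (32, 32)))

    def test_center_inside_and_connected(self):
        from skimage.measure import label
        p = GaussianCatheterParams(10, 12, 2.5, 1.5, 30, 200)
        m = make_gt_mask(p, (32, 32))
        assert m[10, 12] == 1
        assert label(m, connectivity=2).max() == 1


class TestPhantom:
    def test_deterministic_for_fixed_seed(self):
        a = generate_phantom((128, 128), 7)
        b = generate_phantom((128, 128), 7)
        assert np.array_equal(a, b)

    def test_seed_sensitivity(self):
        a = generate_phantom((128, 128), 7)
        b = generate_phantom((128, 128), 8)
        assert (a != b).any()

    def test_intensity_range(self):
        img = generate_phantom((128, 128), 3)
        assert img.min() >= 0 and img.max() > img.min()

    def test_contains_hyperintense_band_and_midlevel_structure(self):
        img = generate_phantom((128, 128), 11)
        assert img.max() > 0.8  # fat-like band
        mid = (img > 0.3) & (img < 0.6)
        assert mid.sum() > 100  # chamber/vessel-like structures

    def test_rejects_too_small_shape(self):
        with pytest.raises(ValueError, match="64x64"):
            generate_phantom((32, 32), 0)

    def test_stack_slices_share_anatomy_but_differ(self):
        stack = generate_phantom_stack((64, 64), 5, 3)
        assert stack.shape == (3, 64, 64)
        assert (stack[0] != stack[1]).any()
        # jittered slices of one anatomy stay strongly correlated
        r = np.corrcoef(stack[0].ravel(), stack[2].ravel())[0, 1]
        assert r > 0.7


class TestSimulateCatheter:
    def test_peak_amplitude_relative_to_center_pixel(self):
        img = np.full((64, 64), 0.4)
        p = GaussianCatheterParams(32, 32, 1.5, 1.5, 0, 200)
        frame = simulate_catheter(img, p)
        assert frame.image[32, 32] == pytest.approx(0.4 + 2 * 0.4, rel=1e-12)

    def test_added_signal_linear_in_amplitude(self):
        img = generate_phantom((64, 64), 1) + 0.1
        lo = simulate_catheter(img, GaussianCatheterParams(30, 30, 1.5, 2.5, 20, 200))
        hi = simulate_catheter(img, GaussianCatheterParams(30, 30, 1.5, 2.5, 20, 400))
        np.testing.assert_allclose(hi.image - img, 2 * (lo.image - img), atol=1e-12)

    def test_additive_and_nonnegative(self):
        img = generate_phantom((64, 64), 2) + 0.1
        p = GaussianCatheterParams(30, 35, 2.5, 2.5, 300, 300)
        frame = simulate_catheter(img, p)
        assert (frame.image - img >= 0).all()

    def test_subtracting_background_recovers_scaled_profile(self):
        img = generate_phantom((64, 64), 4) + 0.1
        p = GaussianCatheterParams(28, 33, 2.5, 1.5, 77, 300)
        frame = simulate_catheter(img, p)
        amp = 3.0 * img[28, 33]
        np.testing.assert_allclose(frame.image - img, amp * gaussian_field(p, img.shape),
                                   atol=1e-12)

    def test_zero_center_intensity_rejected(self):
        img = np.zeros((64, 64))
        p = GaussianCatheterParams(32, 32, 1.5, 1.5, 0, 200)
        with pytest.raises(ValueError, match="zero"):
            simulate_catheter(img, p)


class TestParameterSampling:
    def test_marginal_frequencies(self, rng):
        draws = [sample_catheter_params((10, 10), rng) for _ in range(10_000)]
        f_sx = np.mean([d.sigma_x == 1.5 for d in draws])
        assert abs(f_sx - 0.5) < 0.02  # 3-sigma binomial bound at n=10000
        assert {d.amplitude_pct for d in draws} == {200, 300, 400}
        assert all(0 <= d.theta_deg <= 359 for d in draws)

    def test_deterministic_sequence_under_fixed_seed(self):
        a = [sample_catheter_params((5, 5), np.random.default_rng(9)) for _ in range(20)]
        b = [sample_catheter_params((5, 5), np.random.default_rng(9)) for _ in range(20)]
        assert a == b

    @given(st.integers(0, 2**31 - 1))
    def test_sampled_params_always_valid(self, seed):
        p = sample_catheter_params((20, 20), np.random.default_rng(seed))
        assert p.sigma_x in (1.5, 2.5) and p.sigma_y in (1.5, 2.5)
        assert p.amplitude_pct in (200, 300, 400)


class TestDatasetBuilder:
    def test_negative_share_exact(self):
        cfg = DatasetConfig(n_subjects_train=10, n_subjects_val=2, frames_per_subject=10,
                            negative_fraction=0.10, image_shape=(64, 64), rng_seed=0)
        train, _ = build_dataset(cfg)
        assert len(train) == 100
        assert sum(not f.has_catheter for f in train) == 10

    def test_subject_split_disjoint(self, small_dataset):
        train, val = small_dataset
        train_subjects = {f.subject_id for f in train}
        val_subjects = {f.subject_id for f in val}
        assert len(train_subjects) == 4 and len(val_subjects) == 2
        assert train_subjects.isdisjoint(val_subjects)

    def test_frame_invariants(self, small_dataset):
        for f in small_dataset[0] + small_dataset[1]:
            assert f.image.shape == f.gt_mask.shape
            assert f.has_catheter == bool(f.gt_mask.any())
            assert f.image.min() >= 0

    def test_bit_reproducible(self):
        cfg = DatasetConfig(n_subjects_train=2, n_subjects_val=1, frames_per_subject=5,
                            image_shape=(64, 64), rng_seed=77)
        t1, v1 = build_dataset(cfg)
        t2, v2 = build_dataset(cfg)
        for a, b in zip(t1 + v1, t2 + v2):
            assert np.array_equal(a.image, b.image)
            assert np.array_equal(a.gt_mask, b.gt_mask)

    def test_invalid_negative_fraction(self):
        with pytest.raises(ValueError, match="negative_fraction"):
            DatasetConfig(negative_fraction=1.5)

    def test_dynamics_have_one_balloon_slice_at_most(self):
        dyns = build_dynamic_dataset(12, image_shape=(64, 64), rng_seed=5,
                                     negative_fraction=0.25)
        assert len(dyns) == 12
        n_neg = sum(d.catheter_slice == -1 for d in dyns)
        assert n_neg == 3
        for d in dyns:
            per_slice = [d.gt_masks[k].any() for k in range(3)]
            assert sum(per_slice) == (0 if d.catheter_slice == -1 else 1)
            if d.catheter_slice >= 0:
                assert per_slice[d.catheter_slice]
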