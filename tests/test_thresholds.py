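import numpy as np
import pytest

import oracles
from cytonuclei import (DegenerateHistogramError, adaptive_threshold,
                        apply_threshold, compute_histogram,
                        cross_entropy_threshold, fuzzy_entropy_threshold,
                        isodata_threshold, max_entropy_threshold,
                        min_error_threshold, otsu_threshold)

SELECTOR_ORACLES = [
    (otsu_threshold, oracles.oracle_within_class_variance, False),
    (max_entropy_threshold, oracles.oracle_kapur_entropy, True),
    (cross_entropy_threshold, oracles.oracle_li_cross_entropy, False),
    (fuzzy_entropy_threshold, oracles.oracle_fuzzy_entropy, False),
    (min_error_threshold, oracles.oracle_kittler_criterion, False),
]

ALL_SELECTORS = [otsu_threshold, isodata_threshold, max_entropy_threshold,
                 cross_entropy_threshold, fuzzy_entropy_threshold,
                 min_error_threshold]


def two_delta_hist():
    p = np.zeros(256)
    p[50] = p[200] = 0.5
    return p


class TestHistogram:
    def test_constant_image_single_bin(self):
        p = compute_histogram(np.full((5, 5), 7))
        assert p[7] == 1.0 and p.sum() == 1.0

    def test_half_and_half(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 255
        p = compute_histogram(img)
        assert p[0] == p[255] == 0.5

    def test_normalization_on_random_image(self):
        img = np.random.default_rng(0).integers(0, 256, (33, 41))
        assert compute_histogram(img).sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            compute_histogram(np.empty((0, 0)))


class TestSpecificSelectors:
    def test_otsu_two_delta_tie_breaks_low(self):
        assert otsu_threshold(two_delta_hist()).t == 50

    def test_isodata_two_delta_converges_to_midpoint(self):
        # t0 = 125; mu_below = 50, mu_above = 200 -> t1 = 125: converged
        assert isodata_threshold(two_delta_hist()).t == 125

    def test_max_entropy_uniform_histogram_splits_at_127(self):
        assert max_entropy_threshold(np.full(256, 1 / 256)).t == 127

    def test_max_entropy_two_delta_smallest_separating(self):
        assert max_entropy_threshold(two_delta_hist()).t == 50

    def test_fuzzy_entropy_two_delta_reaches_zero_entropy(self):
        result = fuzzy_entropy_threshold(two_delta_hist())
        assert result.t == 50
        assert result.criterion_value == 0.0

    def test_min_error_rejects_two_delta_histogram(self):
        # both class variances are zero at every split: no admissible candidate
        with pytest.raises(DegenerateHistogramError):
            min_error_threshold(two_delta_hist())

    def test_min_error_shifts_toward_minority_mode(self):
        rng = np.random.default_rng(0)
        x = oracles.LEVELS
        balanced = np.exp(-((x - 60) ** 2) / 200) + np.exp(-((x - 180) ** 2) / 200)
        skewed = 0.9 * np.exp(-((x - 60) ** 2) / 200) + 0.1 * np.exp(-((x - 180) ** 2) / 200)
        t_bal = min_error_threshold(balanced / balanced.sum()).t
        t_skew = min_error_threshold(skewed / skewed.sum()).t
        assert t_skew > t_bal  # boundary moves toward the minority (bright) mode

    @pytest.mark.parametrize("selector", ALL_SELECTORS)
    def test_single_bin_histogram_rejected(self, selector):
        p = np.zeros(256)
        p[99] = 1.0
        with pytest.raises(DegenerateHistogramError):
            selector(p)


class TestOracleEquivalence:
    @pytest.mark.parametrize("selector,criterion,maximize", SELECTOR_ORACLES)
    def test_selector_matches_exhaustive_search(self, selector, criterion, maximize):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(25):
            p = oracles.random_histogram(rng)
            expected = oracles.exhaustive_argopt(criterion, p, maximize)
            try:
                got = selector(p).t
            except DegenerateHistogramError:
                assert expected is None
                continue
            assert got == expected
            checked += 1
        assert checked >= 20

    def test_isodata_returns_a_fixed_point(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            p = oracles.random_histogram(rng)
            t = isodata_threshold(p).t
            assert abs(t - oracles.isodata_midpoint(p, t)) < 1.0

    def test_thresholds_are_spatially_invariant(self):
        rng = np.random.default_rng(5)
        img = rng.normal(120, 40, (40, 40)).clip(0, 255)
        shuffled = rng.permutation(img.ravel()).reshape(img.shape)
        p1, p2 = compute_histogram(img), compute_histogram(shuffled)
        for selector in ALL_SELECTORS:
            assert selector(p1).t == selector(p2).t


class TestAdaptiveThreshold:
    def test_constant_image_gives_empty_mask(self):
        assert not adaptive_threshold(np.full((30, 30), 99.0)).any()

    def test_dark_disk_detected_against_bright_field(self):
        rr, cc = np.mgrid[0:100, 0:100]
        disk = (rr - 50) ** 2 + (cc - 50) ** 2 <= 30 ** 2
        img = np.where(disk, 70.0, 220.0)
        mask = adaptive_threshold(img, window=12, offset=5)
        assert not mask[~disk & ((rr - 50) ** 2 + (cc - 50) ** 2 > 45 ** 2)].any()
        rim = disk & ((rr - 50) ** 2 + (cc - 50) ** 2 > 20 ** 2)
        assert mask[rim].mean() > 0.5  # boundary band is flagged dark

    def test_whole_image_window_equals_global_mean_rule(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(0, 255, (24, 24))
        mask = adaptive_threshold(img, window=64, offset=5)
        assert np.array_equal(mask, img < img.mean() - 5)

    def test_offset_zero_on_noise_flags_about_half(self):
        rng = np.random.default_rng(8)
        img = rng.normal(128, 20, (64, 64)).clip(0, 255)
        frac = adaptive_threshold(img, window=12, offset=0).mean()
        assert 0.4 < frac < 0.6


class TestApplyThreshold:
    def test_dark_pixels_are_foreground(self):
        img = np.array([[10.0, 200.0]])
        assert np.array_equal(apply_threshold(img, 100), [[True, False]])

    def test_boundary_values(self):
        img = np.array([[5.0, 100.0, 255.0]])
        assert apply_threshold(img, 255).all()
        assert not apply_threshold(img, 0).any()

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_threshold(np.zeros((2, 2)), 300)


def test_global_selectors_cover_nuclei_on_standard_scene(preprocessed_scene, standard_scene):
    """Dark-foreground polarity: every global selector's raw mask covers at
    least 90% of the ground-truth nuclei pixels."""
    p = compute_histogram(preprocessed_scene)
    gt = standard_scene.gt_mask
    for selector in ALL_SELECTORS:
        mask = apply_threshold(preprocessed_scene, selector(p))
        assert (mask & gt).sum() / gt.sum() >= 0.9
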