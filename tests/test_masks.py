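"""Thresholding and category mask arithmetic against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from reoxquant.io import to_8bit
from reoxquant.masks import (
    Category,
    classify_categories,
    integrated_density,
    otsu_threshold,
    percent_area,
    preset_threshold,
)


def brute_force_otsu(values: np.ndarray) -> int:
    """Exhaustive 256-candidate between-class-variance search (the oracle)."""
    counts = np.bincount(values.ravel(), minlength=256).astype(float)
    n = counts.sum()
    best_t, best_s = None, -np.inf
    for t in range(1, 256):
        w0 = counts[:t].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:t] * np.arange(t)).sum() / w0
        mu1 = (counts[t:] * np.arange(t, 256)).sum() / w1
        s = w0 * w1 * (mu0 - mu1) ** 2
        if s > best_s:  # strict: ties keep the lower threshold
            best_s, best_t = s, t
    return best_t


def truth_table_labels(cci: np.ndarray, pimo: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Per-pixel category assignment by explicit case enumeration."""
    out = np.empty(roi.shape, dtype=np.uint8)
    for r in range(roi.shape[0]):
        for c in range(roi.shape[1]):
            if not roi[r, c]:
                out[r, c] = Category.OUTSIDE_ROI
            elif cci[r, c] and pimo[r, c]:
                out[r, c] = Category.NO_CHANGE
            elif cci[r, c]:
                out[r, c] = Category.REOXYGENATED
            elif pimo[r, c]:
                out[r, c] = Category.NEW_HYPOXIA
            else:
                out[r, c] = Category.BACKGROUND
    return out


class TestPresetThreshold:
    def test_uniform_above_threshold_fills_roi(self):
        img = np.full((8, 8), 100, dtype=np.uint8)
        roi = np.zeros((8, 8), dtype=bool)
        roi[2:6, 2:6] = True
        m = preset_threshold(img, roi, 50)
        np.testing.assert_array_equal(m.mask, roi)

    def test_uniform_below_threshold_empty(self):
        img = np.full((8, 8), 100, dtype=np.uint8)
        roi = np.ones((8, 8), dtype=bool)
        assert preset_threshold(img, roi, 101).mask.sum() == 0

    def test_two_level_phantom_recovered_exactly(self, section_phantom):
        _, image, truth = section_phantom
        cci8 = to_8bit(image.channels["cci103f"], 16)
        m = preset_threshold(cci8, truth.roi_mask, 110)
        np.testing.assert_array_equal(m.mask, truth.true_cci_mask)

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError, match="empty ROI"):
            preset_threshold(np.zeros((4, 4), dtype=np.uint8), np.zeros((4, 4), bool), 10)


class TestOtsuThreshold:
    def test_two_value_histogram_separated_exactly(self):
        img = np.array([[40] * 6 + [180] * 2] * 4, dtype=np.uint8)
        roi = np.ones_like(img, dtype=bool)
        m = otsu_threshold(img, roi)
        np.testing.assert_array_equal(m.mask, img == 180)
        assert 40 < m.threshold_value <= 180

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # bimodal-ish random 8-bit image with arbitrary spread
        lo = rng.integers(0, 120)
        hi = rng.integers(lo + 10, 256)
        img = np.where(
            rng.uniform(size=(32, 32)) < rng.uniform(0.2, 0.8),
            rng.integers(0, lo + 1, size=(32, 32)),
            rng.integers(lo, hi, size=(32, 32)),
        ).astype(np.uint8)
        roi = np.ones_like(img, dtype=bool)
        m = otsu_threshold(img, roi)
        assert m.threshold_value == brute_force_otsu(img)

    def test_noiseless_phantom_mask_equals_ground_truth(self, section_phantom):
        _, image, truth = section_phantom
        cci8 = to_8bit(image.channels["cci103f"], 16)
        m = otsu_threshold(cci8, truth.roi_mask)
        np.testing.assert_array_equal(m.mask, truth.true_cci_mask)

    def test_constant_image_raises(self):
        img = np.full((8, 8), 77, dtype=np.uint8)
        with pytest.raises(ValueError, match="no threshold exists"):
            otsu_threshold(img, np.ones_like(img, dtype=bool))

    def test_histogram_restricted_to_roi(self):
        # values outside the ROI must not influence the threshold
        img = np.full((8, 8), 40, dtype=np.uint8)
        img[:, 4:] = 180
        roi = np.zeros_like(img, dtype=bool)
        roi[:, :4] = True
        img[0, 0] = 41  # two distinct values inside the ROI
        m = otsu_threshold(img, roi)
        assert m.threshold_value == 41


def _as_marker(mask, roi):
    return preset_threshold(mask.astype(np.uint8), roi, 1)


class TestClassifyCategories:
    def test_identical_masks_all_no_change(self, rng):
        roi = np.ones((8, 8), dtype=bool)
        m = rng.uniform(size=(8, 8)) < 0.4
        cmap = classify_categories(_as_marker(m, roi), _as_marker(m, roi), roi)
        assert not cmap.mask(Category.REOXYGENATED).any()
        assert not cmap.mask(Category.NEW_HYPOXIA).any()
        np.testing.assert_array_equal(cmap.mask(Category.NO_CHANGE), m)

    def test_disjoint_masks_no_overlap_category(self, rng):
        roi = np.ones((8, 8), dtype=bool)
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[:4], b[4:] = True, True
        cmap = classify_categories(_as_marker(a, roi), _as_marker(b, roi), roi)
        assert not cmap.mask(Category.NO_CHANGE).any()
        np.testing.assert_array_equal(cmap.mask(Category.REOXYGENATED), a)
        np.testing.assert_array_equal(cmap.mask(Category.NEW_HYPOXIA), b)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_truth_table_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        roi = rng.uniform(size=(8, 8)) < 0.9
        if not roi.any():
            roi[0, 0] = True
        a = (rng.uniform(size=(8, 8)) < 0.5) & roi
        b = (rng.uniform(size=(8, 8)) < 0.5) & roi
        cmap = classify_categories(_as_marker(a, roi), _as_marker(b, roi), roi)
        np.testing.assert_array_equal(cmap.labels, truth_table_labels(a, b, roi))

    def test_exhaustive_all_2x2_mask_pairs(self):
        roi = np.ones((2, 2), dtype=bool)
        for i in range(16):
            for j in range(16):
                a = np.array([[i & 1, i & 2], [i & 4, i & 8]], dtype=bool)
                b = np.array([[j & 1, j & 2], [j & 4, j & 8]], dtype=bool)
                cmap = classify_categories(_as_marker(a, roi), _as_marker(b, roi), roi)
                np.testing.assert_array_equal(cmap.labels, truth_table_labels(a, b, roi))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=hnp.arrays(bool, (6, 6)),
        b=hnp.arrays(bool, (6, 6)),
    )
    def test_partition_identity_property(self, a, b):
        roi = np.ones((6, 6), dtype=bool)
        cmap = classify_categories(_as_marker(a, roi), _as_marker(b, roi), roi)
        union = (a | b).sum()
        total = (
            cmap.mask(Category.REOXYGENATED).sum()
            + cmap.mask(Category.NEW_HYPOXIA).sum()
            + cmap.mask(Category.NO_CHANGE).sum()
        )
        assert total == union

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=hnp.arrays(bool, (6, 6)), b=hnp.arrays(bool, (6, 6)))
    def test_swapping_masks_swaps_mismatch_categories(self, a, b):
        roi = np.ones((6, 6), dtype=bool)
        ab = classify_categories(_as_marker(a, roi), _as_marker(b, roi), roi)
        ba = classify_categories(_as_marker(b, roi), _as_marker(a, roi), roi)
        np.testing.assert_array_equal(
            ab.mask(Category.REOXYGENATED), ba.mask(Category.NEW_HYPOXIA)
        )
        np.testing.assert_array_equal(ab.mask(Category.NO_CHANGE), ba.mask(Category.NO_CHANGE))

    def test_growing_pimo_never_increases_reoxygenated_area(self, rng):
        roi = np.ones((16, 16), dtype=bool)
        a = rng.uniform(size=(16, 16)) < 0.5
        b = rng.uniform(size=(16, 16)) < 0.3
        b_grown = b | (rng.uniform(size=(16, 16)) < 0.3)
        r1 = classify_categories(_as_marker(a, roi), _as_marker(b, roi), roi)
        r2 = classify_categories(_as_marker(a, roi), _as_marker(b_grown, roi), roi)
        assert r2.mask(Category.REOXYGENATED).sum() <= r1.mask(Category.REOXYGENATED).sum()

    def test_shape_mismatch_raises(self):
        roi = np.ones((4, 4), dtype=bool)
        a = _as_marker(np.ones((4, 4), bool), roi)
        b = _as_marker(np.ones((4, 4), bool), roi)
        with pytest.raises(ValueError, match="shape mismatch"):
            classify_categories(a, b, np.ones((5, 5), dtype=bool))


class TestAreaAndDensity:
    def test_percent_area_full_and_empty(self):
        roi = np.ones((10, 10), dtype=bool)
        assert percent_area(roi, roi) == 100.0
        assert percent_area(np.zeros_like(roi), roi) == 0.0

    def test_phantom_baseline_percent_matches_request(self, section_phantom):
        params, _, truth = section_phantom
        pct = percent_area(truth.true_cci_mask, truth.roi_mask)
        assert pct == pytest.approx(100 * params.baseline_hypoxic_fraction, abs=2.0)

    def test_integrated_density_uniform(self):
        img = np.full((20, 20), 10, dtype=np.uint8)
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10, :10] = True  # 100 px at 10
        assert integrated_density(img, mask) == 1000.0

    def test_integrated_density_empty_mask_is_zero(self):
        assert integrated_density(np.ones((4, 4)), np.zeros((4, 4), bool)) == 0.0

    def test_integrated_density_matches_double_loop(self, rng):
        img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        mask = rng.uniform(size=(8, 8)) < 0.5
        naive = sum(
            int(img[r, c]) for r in range(8) for c in range(8) if mask[r, c]
        )
        assert integrated_density(img, mask) == naive
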