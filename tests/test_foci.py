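"""Region selection, nuclei segmentation, foci counting and stratified scoring."""

import numpy as np
import pytest

from reoxquant.foci import (
    CellFociScore,
    aggregate_foci,
    classify_count,
    count_foci,
    score_cells,
    segment_nuclei,
    select_reoxygenated_regions,
)
from reoxquant.masks import Category
from reoxquant.phantoms import (
    FociCountDistribution,
    FociPhantomParams,
    generate_foci_phantom,
)


class _FakeMap:
    def __init__(self, labels):
        self.labels = labels


def _map_with_reox_windows(n_windows, size=64, grid=4):
    """Category map whose first n tiling windows are fully reoxygenated."""
    labels = np.full((grid * size, grid * size), int(Category.BACKGROUND), dtype=np.uint8)
    placed = 0
    for r in range(grid):
        for c in range(grid):
            if placed < n_windows:
                labels[r * size : (r + 1) * size, c * size : (c + 1) * size] = int(
                    Category.REOXYGENATED
                )
                placed += 1
    return _FakeMap(labels)


class TestRegionSelection:
    def test_exactly_six_qualifying_windows_all_returned(self):
        cmap = _map_with_reox_windows(6)
        regions = select_reoxygenated_regions(cmap, n_regions=6, region_size_px=64, seed=0)
        assert len(regions) == 6
        assert len({r.bbox for r in regions}) == 6  # non-overlapping by tiling

    def test_no_reoxygenated_pixels_raises_with_count(self):
        cmap = _map_with_reox_windows(0)
        with pytest.raises(ValueError, match="found 0"):
            select_reoxygenated_regions(cmap, n_regions=6, region_size_px=64, seed=0)

    def test_selection_deterministic_under_seed(self):
        cmap = _map_with_reox_windows(14)
        a = select_reoxygenated_regions(cmap, n_regions=6, region_size_px=64, seed=5)
        b = select_reoxygenated_regions(cmap, n_regions=6, region_size_px=64, seed=5)
        assert [r.bbox for r in a] == [r.bbox for r in b]


class TestSegmentNuclei:
    def test_well_separated_phantom_nuclei_all_found(self, foci_phantom_fixed4):
        params, image, truth = foci_phantom_fixed4
        labels = segment_nuclei(image.channels["nuclei"])
        assert labels.max() == params.n_nuclei

    def test_blank_field_yields_zero_labels(self):
        labels = segment_nuclei(np.full((64, 64), 500, dtype=np.uint16))
        assert labels.max() == 0

    def test_two_touching_nuclei_split_by_watershed(self):
        img = np.full((60, 60), 1000, dtype=np.uint16)
        yy, xx = np.mgrid[0:60, 0:60]
        # two discs of radius 10 whose centres are 19 px apart (overlapping rims)
        d1 = (yy - 30) ** 2 + (xx - 20) ** 2 <= 100
        d2 = (yy - 30) ** 2 + (xx - 39) ** 2 <= 100
        img[d1 | d2] = 30000
        labels = segment_nuclei(img)
        assert labels.max() == 2


class TestCountFoci:
    def test_zero_foci_nucleus_counts_zero(self, foci_phantom_fixed4):
        params, _, truth = foci_phantom_fixed4
        p = FociPhantomParams(
            n_nuclei=6, image_height_px=120, image_width_px=120,
            foci_count_distribution=FociCountDistribution(name="fixed", mean=0), seed=2,
        )
        image, t = generate_foci_phantom(p)
        for lab in range(1, 7):
            assert count_foci(image.channels["phospho_atm"], t.nucleus_labels == lab) == 0

    @pytest.mark.parametrize("k", [1, 3, 5, 6, 8, 10])
    def test_exact_recovery_k_foci(self, k):
        p = FociPhantomParams(
            n_nuclei=6, image_height_px=120, image_width_px=120,
            foci_count_distribution=FociCountDistribution(name="fixed", mean=k),
            seed=300 + k,
        )
        image, truth = generate_foci_phantom(p)
        for lab in range(1, 7):
            got = count_foci(image.channels["phospho_atm"], truth.nucleus_labels == lab)
            assert got == truth.true_foci_counts[lab - 1] == k

    def test_dim_foci_below_prominence_not_counted(self):
        p = FociPhantomParams(
            n_nuclei=4, image_height_px=100, image_width_px=100,
            foci_count_distribution=FociCountDistribution(name="fixed", mean=3),
            foci_intensity=1500.0,  # ~2% of range, below the 8% prominence floor
            seed=4,
        )
        image, truth = generate_foci_phantom(p)
        for lab in range(1, 5):
            assert count_foci(image.channels["phospho_atm"], truth.nucleus_labels == lab) == 0

    def test_empty_nucleus_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            count_foci(np.zeros((10, 10), dtype=np.uint16), np.zeros((10, 10), bool))

    def test_noisy_counts_close_to_truth(self):
        # noise at 10% of the foci amplitude
        p = FociPhantomParams(
            n_nuclei=30, image_height_px=240, image_width_px=240,
            foci_count_distribution=FociCountDistribution(mean=4.0),
            noise_sd=2400.0, seed=11,
        )
        image, truth = generate_foci_phantom(p)
        got = np.array(
            [
                count_foci(image.channels["phospho_atm"], truth.nucleus_labels == lab)
                for lab in range(1, 31)
            ]
        )
        assert np.abs(got - truth.true_foci_counts).mean() <= 0.5


class TestScoreCells:
    def test_classification_boundary_at_six_foci(self):
        assert classify_count(5) == "low"
        assert classify_count(6) == "high"
        assert classify_count(0) == "none"

    def test_majority_rule_cci_status(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[0:2, 0:5] = 1  # fully inside the CCI mask
        labels[5:7, 0:5] = 2  # fully outside
        cci = np.zeros((10, 10), dtype=bool)
        cci[0:2] = True
        cells = score_cells(labels, [2, 7], cci)
        assert cells[0].cci_status == "positive"
        assert cells[1].cci_status == "negative"
        assert cells[0].foci_class == "low"
        assert cells[1].foci_class == "high"

    def test_count_label_mismatch_raises(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[0, 0] = 1
        labels[2, 2] = 2
        with pytest.raises(ValueError, match="foci counts"):
            score_cells(labels, [1], np.zeros((4, 4), bool))

    def test_scores_on_phantom_match_ground_truth_strata(self, foci_phantom_fixed4):
        params, image, truth = foci_phantom_fixed4
        counts = truth.true_foci_counts
        cells = score_cells(truth.nucleus_labels, list(counts), truth.true_cci_mask)
        got_status = np.array([c.cci_status == "positive" for c in cells])
        np.testing.assert_array_equal(got_status, truth.cci_status)


def _cell(i, status, count, region=1, fld=1):
    return CellFociScore(
        nucleus_id=i, centroid=(0.0, 0.0), area_px=50, cci_status=status,
        foci_count=count, foci_class=classify_count(count), region_id=region, field_id=fld,
    )


class TestAggregateFoci:
    def test_pooled_percentage_matches_arithmetic(self):
        # 100 CCI-negative cells in one field, 41 of them with >5 foci
        cells = [_cell(i, "negative", 7) for i in range(41)]
        cells += [_cell(41 + i, "negative", 1) for i in range(59)]
        report = aggregate_foci(cells, min_cells_per_field=50, min_fields_per_region=1)
        assert report.per_stratum["negative"]["pct_high_foci"] == pytest.approx(41.0)
        assert report.per_stratum["negative"]["n_cells"] == 100

    def test_small_field_flagged_and_excluded(self):
        big = [_cell(i, "negative", 7, fld=1) for i in range(60)]
        small = [_cell(100 + i, "negative", 0, fld=2) for i in range(10)]
        report = aggregate_foci(big + small, min_cells_per_field=50, min_fields_per_region=1)
        assert any("field" in f and "excluded" in f for f in report.qc_flags)
        assert report.per_stratum["negative"]["n_cells"] == 60
        assert report.per_stratum["negative"]["pct_high_foci"] == pytest.approx(100.0)

    def test_empty_stratum_absent_not_zero(self):
        cells = [_cell(i, "negative", 2) for i in range(60)]
        report = aggregate_foci(cells, min_cells_per_field=50, min_fields_per_region=1)
        assert "positive" not in report.per_stratum

    def test_all_fields_excluded_raises(self):
        cells = [_cell(i, "negative", 1) for i in range(10)]
        with pytest.raises(ValueError, match="excluded"):
            aggregate_foci(cells, min_cells_per_field=50)

    def test_invariant_to_cell_ordering_and_relabelling(self, rng):
        cells = [
            _cell(i, "negative" if i % 3 else "positive", int(rng.poisson(4)), fld=1 + i % 2)
        for i in range(120)
        ]
        shuffled = [cells[i] for i in rng.permutation(len(cells))]
        relabelled = [
            CellFociScore(
                nucleus_id=1000 - c.nucleus_id, centroid=c.centroid, area_px=c.area_px,
                cci_status=c.cci_status, foci_count=c.foci_count, foci_class=c.foci_class,
                region_id=c.region_id, field_id=c.field_id,
            )
            for c in shuffled
        ]
        r1 = aggregate_foci(cells, min_cells_per_field=50, min_fields_per_region=1)
        r2 = aggregate_foci(relabelled, min_cells_per_field=50, min_fields_per_region=1)
        assert r1.per_stratum == r2.per_stratum
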