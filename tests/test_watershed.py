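"""Watershed separation tests: mask cleaning, distance transform against a
brute-force oracle, marker selection, flooding equivalence with a
Dijkstra oracle, region measurement and the post-filters."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from oracles import brute_force_distance, flood_oracle
from smearkit.watershed import (
    WatershedParams,
    apply_watershed,
    clean_mask,
    euclidean_distance_map,
    extract_cell_images,
    filter_regions,
    region_properties,
    select_markers,
    separate_cells,
)


def _disc(h, w, cy, cx, r):
    yy, xx = np.mgrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestCleanMask:
    def test_isolated_pixel_removed_by_opening(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        assert not clean_mask(m).any()

    def test_large_solid_square_unchanged(self):
        m = np.zeros((16, 16), bool)
        m[3:13, 3:13] = True
        assert np.array_equal(clean_mask(m), m)

    def test_single_pixel_hole_filled(self):
        m = np.zeros((13, 13), bool)
        m[2:11, 2:11] = True
        m[6, 6] = False
        out = clean_mask(m, WatershedParams(fill_holes=True))
        assert out[6, 6]


class TestDistanceMap:
    def test_all_background_gives_zero_map(self):
        assert not euclidean_distance_map(np.zeros((5, 5), bool)).any()

    def test_edge_pixel_distance_one(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert euclidean_distance_map(m)[2, 2] == 1.0

    def test_matches_brute_force_on_random_masks(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = rng.random((12, 12)) > 0.5
            assert np.allclose(euclidean_distance_map(m), brute_force_distance(m))

    def test_centre_of_5x5_block_is_three(self):
        m = np.zeros((15, 15), bool)
        m[5:10, 5:10] = True
        d = euclidean_distance_map(m)
        assert d[7, 7] == brute_force_distance(m)[7, 7] == 3.0


class TestSelectMarkers:
    def test_two_far_discs_give_two_foreground_markers(self):
        m = _disc(60, 100, 30, 25, 12) | _disc(60, 100, 30, 65, 12)
        d = euclidean_distance_map(m)
        markers, unknown = select_markers(d, m)
        assert markers.max() - 1 == 2  # labels 2 and 3 are the cell seeds
        assert not (unknown & (markers > 0)).any()

    def test_nearby_peaks_merge_into_one_marker(self):
        # two discs whose centres are 3 px apart share one 7x7 peak window
        m = _disc(40, 40, 20, 19, 10) | _disc(40, 40, 20, 22, 10)
        d = euclidean_distance_map(m)
        markers, _ = select_markers(d, m)
        assert markers.max() - 1 == 1

    def test_empty_mask_yields_no_foreground_markers(self):
        m = np.zeros((10, 10), bool)
        markers, unknown = select_markers(np.zeros((10, 10)), m)
        assert markers.max() == 1  # background only
        assert not unknown.any()

    def test_raising_threshold_never_increases_marker_count(self):
        rng = np.random.default_rng(1)
        for trial in range(8):
            m = np.zeros((64, 64), bool)
            for _ in range(3):
                m |= _disc(64, 64, rng.uniform(12, 52), rng.uniform(12, 52), rng.uniform(6, 12))
            d = euclidean_distance_map(m)
            counts = []
            for frac in (0.2, 0.3, 0.4, 0.6, 0.8):
                markers, _ = select_markers(d, m, WatershedParams(dt_threshold_frac=frac))
                counts.append(int(markers.max()) - 1)
            assert all(a >= b for a, b in zip(counts, counts[1:])), counts


class TestApplyWatershed:
    def test_single_marker_floods_whole_blob(self):
        m = _disc(30, 30, 15, 15, 9)
        d = euclidean_distance_map(m)
        markers, _ = select_markers(d, m)
        labels = apply_watershed(m, markers)
        assert np.array_equal(labels > 0, m)
        assert labels.max() == 1

    def test_labels_never_assigned_outside_mask(self):
        m = _disc(40, 40, 20, 14, 9) | _disc(40, 40, 20, 27, 9)
        d = euclidean_distance_map(m)
        markers, _ = select_markers(d, m)
        labels = apply_watershed(m, markers)
        assert not labels[~m].any()

    def test_dumbbell_splits_into_two_regions_crossing_the_neck(self):
        m = _disc(44, 60, 22, 20, 11) | _disc(44, 60, 22, 37, 11)
        d = euclidean_distance_map(m)
        markers, _ = select_markers(d, m)
        labels = apply_watershed(m, markers)
        assert labels.max() == 2
        assert np.array_equal(labels > 0, m)
        # the two basins sit on opposite sides of the neck
        assert labels[22, 20] != labels[22, 37]

    def test_no_markers_returns_mask_as_single_region(self):
        m = _disc(20, 20, 10, 10, 5)
        labels = apply_watershed(m, np.zeros_like(m, dtype=np.int32))
        assert np.array_equal(labels, m.astype(np.int32))

    def test_matches_dijkstra_flooding_oracle_on_small_grids(self):
        # library flooding vs independent priority-flood implementation
        p = WatershedParams()
        for seed in range(6):
            rng = np.random.default_rng(seed)
            h = w = int(rng.integers(25, 50))
            m = np.zeros((h, w), bool)
            for _ in range(3):
                m |= _disc(h, w, rng.uniform(8, h - 8), rng.uniform(8, w - 8), rng.uniform(4, 9))
            d = euclidean_distance_map(m)
            markers, _ = select_markers(d, m, p)
            fg = np.where(markers > 1, markers - 1, 0).astype(np.int32)
            fg[~m] = 0
            if not fg.any():
                continue
            got = apply_watershed(m, markers, p)
            ref = flood_oracle(-d, fg, m, compactness=p.compactness)
            # apply_watershed relabels consecutively; compare partitions
            for lab in np.unique(ref[ref > 0]):
                region = ref == lab
                assert len(np.unique(got[region])) == 1
            assert np.array_equal(got > 0, ref > 0)


class TestRegionMeasurement:
    def test_solid_square_area_is_pixel_count(self):
        m = np.zeros((10, 10), np.int32)
        m[3:7, 3:7] = 1
        (r,) = region_properties(m)
        assert r.area == 16
        assert r.bbox == (3, 3, 7, 7)
        assert not r.touches_border

    def test_circularity_formula_on_ideal_measurements(self):
        # with the ideal-disc perimeter P = 2*sqrt(pi*A) the definition
        # 4*pi*A/P^2 gives exactly 1; a continuous square gives pi/4
        A = 500.0
        assert 4 * np.pi * A / (2 * np.sqrt(np.pi * A)) ** 2 == pytest.approx(1.0)
        s = 20.0
        assert 4 * np.pi * s**2 / (4 * s) ** 2 == pytest.approx(np.pi / 4)

    def test_rasterized_discs_measure_near_unit_circularity(self):
        for radius in (10, 15, 25):
            m = _disc(2 * radius + 8, 2 * radius + 8, radius + 4, radius + 4, radius)
            (r,) = region_properties(m.astype(np.int32))
            assert 0.9 <= r.circularity <= 1.0

    def test_border_touching_flagged(self):
        m = np.zeros((10, 10), np.int32)
        m[0:4, 2:6] = 1
        (r,) = region_properties(m)
        assert r.touches_border


class TestFilterRegions:
    @pytest.mark.parametrize("area,reason", [(50, "too_small"), (7000, "too_large")])
    def test_area_gates(self, area, reason):
        from smearkit.watershed import RegionProps

        r = RegionProps(1, area, 100.0, 0.8, (10, 10, 20, 20), False, (15.0, 15.0))
        kept, removed = filter_regions([r])
        assert not kept and removed[0][1] == (reason,)

    def test_low_circularity_gate(self):
        from smearkit.watershed import RegionProps

        r = RegionProps(1, 500, 200.0, 0.2, (10, 10, 20, 20), False, (15.0, 15.0))
        _, removed = filter_regions([r])
        assert removed[0][1] == ("low_circularity",)

    def test_compact_interior_region_kept(self):
        from smearkit.watershed import RegionProps

        r = RegionProps(1, 500, 80.0, 0.9, (10, 10, 30, 30), False, (20.0, 20.0))
        kept, removed = filter_regions([r])
        assert kept == [r] and not removed

    def test_label_conservation(self):
        m = np.zeros((100, 100), np.int32)
        m[_disc(100, 100, 30, 30, 12)] = 1
        m[_disc(100, 100, 70, 70, 4)] = 2
        m[0:3, 40:60] = 3
        props = region_properties(m)
        kept, removed = filter_regions(props)
        assert len(kept) + len(removed) == len(props) == 3


class TestExtractCells:
    def test_crop_pixels_outside_mask_are_exactly_zero(self, rng):
        img = rng.integers(1, 256, (60, 60, 3)).astype(np.uint8)
        labels = np.zeros((60, 60), np.int32)
        labels[_disc(60, 60, 30, 30, 12)] = 1
        props = region_properties(labels)
        (roi,) = extract_cell_images(img, labels, props, roi_size=32)
        assert roi.crop.shape == (32, 32, 3)
        assert np.all(roi.crop[~roi.mask] == 0)
        assert roi.crop[roi.mask].any()

    def test_two_kept_regions_give_two_rois_with_distinct_ids(self, rng):
        img = rng.integers(1, 256, (80, 80, 3)).astype(np.uint8)
        labels = np.zeros((80, 80), np.int32)
        labels[_disc(80, 80, 25, 25, 10)] = 1
        labels[_disc(80, 80, 55, 55, 10)] = 2
        rois = extract_cell_images(img, labels, region_properties(labels), roi_size=32)
        assert sorted(r.source_id for r in rois) == [1, 2]

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            extract_cell_images(np.zeros((4, 4, 3)), np.zeros((5, 5), np.int32), [])


def test_dense_profile_matches_documented_preset():
    p = WatershedParams.profile("dense")
    assert p.min_peak_distance == 9 and p.dt_threshold_frac == 0.25
    assert WatershedParams.profile("default") == WatershedParams()
    with pytest.raises(ValueError):
        WatershedParams.profile("nope")


def test_invalid_parameter_combinations_rejected():
    with pytest.raises(ValueError):
        WatershedParams(dt_threshold_frac=1.5)
    with pytest.raises(ValueError):
        WatershedParams(area_min=500, area_max=100)
    with pytest.raises(ValueError):
        WatershedParams(tau=1.5)


def test_separate_cells_on_synthetic_smear_recovers_most_instances(clean_smear):
    mask = clean_smear.instances > 0
    labels, rois, removed = separate_cells(clean_smear.image, mask, roi_size=64)
    n_true = len(clean_smear.labels)
    # platelets (area < 80 px) are filtered by design; all larger cells and
    # the overlapping pair should come back as separate ROIs
    n_platelets = sum(1 for v in clean_smear.labels.values() if v == "Platelet")
    assert n_true - n_platelets - 1 <= len(rois) <= n_true
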