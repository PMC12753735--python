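"""Tests of the synthetic smear generator: determinism, placement and
overlap control, ground-truth consistency, and the ROI dataset writer."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from smearkit.classifier import CLASS_NAMES
from smearkit.synthetic import (
    BACKGROUND_RGB,
    DEFAULT_CLASS_SPECS,
    REFERENCE_CLASS_COUNTS,
    CellClassSpec,
    PlacementError,
    SmearSpec,
    generate_roi_arrays,
    generate_roi_dataset,
    generate_smear,
    render_cell,
)


class TestRenderCell:
    def test_zero_granularity_anucleate_cell_is_constant_color_disc(self):
        spec = CellClassSpec("x", (8, 8), (200, 100, 50), nucleus_lobes=0, granularity=0.0)
        sprite, mask = render_cell(spec, seed=1)
        assert np.array_equal(np.unique(sprite[mask], axis=0), [[200, 100, 50]])
        assert np.all(sprite[~mask] == 0)

    def test_same_seed_gives_bit_identical_output(self):
        spec = DEFAULT_CLASS_SPECS["Neutrophil"]
        s1, m1 = render_cell(spec, seed=7)
        s2, m2 = render_cell(spec, seed=7)
        assert np.array_equal(s1, s2) and np.array_equal(m1, m2)

    def test_fixed_radius_mask_area_matches_rasterized_disc_bounds(self):
        # a rasterized disc of radius 10 has between pi*9^2 and pi*11^2 pixels
        spec = CellClassSpec("x", (10, 10), (200, 100, 50))
        _, mask = render_cell(spec, seed=0)
        assert np.pi * 81 <= mask.sum() <= np.pi * 121

    def test_mask_is_single_connected_blob(self):
        for name, spec in DEFAULT_CLASS_SPECS.items():
            _, mask = render_cell(spec, seed=3)
            _, n = ndi.label(mask, structure=np.ones((3, 3)))
            assert n == 1, name

    def test_degenerate_radius_rejected(self):
        with pytest.raises(ValueError):
            CellClassSpec("x", (0, 5), (1, 2, 3))
        with pytest.raises(ValueError):
            CellClassSpec("x", (5, 4), (1, 2, 3))


class TestGenerateSmear:
    def test_zero_cells_gives_pure_background(self):
        spec = SmearSpec(cells_per_class={n: 0 for n in CLASS_NAMES},
                         noise_sigma=0.0, illumination_gradient=0.0, seed=0)
        s = generate_smear(spec)
        assert not s.instances.any() and not s.labels
        assert np.array_equal(np.unique(s.image.reshape(-1, 3), axis=0), [list(BACKGROUND_RGB)])

    def test_zero_overlap_means_disjoint_instance_masks(self):
        spec = SmearSpec(height=200, width=200, overlap_fraction=0.0, seed=5)
        s = generate_smear(spec)
        assert s.achieved_overlap_fraction == 0.0
        # disjointness by construction: every instance is a full disc, so the
        # sum of per-instance areas equals the foreground area
        ids, counts = np.unique(s.instances[s.instances > 0], return_counts=True)
        assert len(ids) == sum(spec.cells_per_class.values())

    def test_requested_counts_yield_distinct_labelled_instances(self):
        spec = SmearSpec(height=360, width=360,
                         cells_per_class={n: 5 for n in CLASS_NAMES}, seed=7)
        s = generate_smear(spec)
        ids = np.unique(s.instances)
        ids = ids[ids > 0]
        assert len(ids) == 45
        assert sorted(s.labels) == sorted(ids.tolist())
        for name in CLASS_NAMES:
            assert sum(1 for v in s.labels.values() if v == name) == 5

    def test_achieved_overlap_within_tolerance_of_target(self):
        for target in (0.0, 0.2, 0.4):
            spec = SmearSpec(height=300, width=300, overlap_fraction=target,
                             cells_per_class={n: 2 for n in CLASS_NAMES}, seed=11)
            s = generate_smear(spec)
            assert abs(s.achieved_overlap_fraction - target) <= 0.1

    def test_instances_are_connected_under_8_connectivity(self, small_smear):
        ids = np.unique(small_smear.instances)
        for i in ids[ids > 0]:
            _, n = ndi.label(small_smear.instances == i, structure=np.ones((3, 3)))
            assert n == 1

    def test_determinism_bit_identical_samples(self):
        spec = SmearSpec(seed=9)
        a, b = generate_smear(spec), generate_smear(spec)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.instances, b.instances)
        assert a.labels == b.labels

    def test_ground_truth_pixels_match_composited_sprites(self, clean_smear):
        # without noise/illumination, foreground pixels differ from the
        # background and the label map is exactly the visible sprite extent
        fg = clean_smear.instances > 0
        bg_color = np.array(BACKGROUND_RGB)
        assert np.all(clean_smear.image[~fg] == bg_color)
        assert not np.any(np.all(clean_smear.image[fg] == bg_color, axis=-1))

    def test_placement_failure_names_the_class(self):
        spec = SmearSpec(height=48, width=48,
                         cells_per_class={"Monocyte": 30}, attempt_cap=20, seed=0)
        with pytest.raises(PlacementError, match="Monocyte"):
            generate_smear(spec)


class TestRoiDataset:
    def test_manifest_rows_equal_requested_counts(self, tmp_path):
        manifest = generate_roi_dataset(tmp_path, n_per_class=2, seed=0)
        assert len(manifest) == 18
        assert (manifest.groupby("class").size() == 2).all()
        # conservation: every manifest row corresponds to a written file
        for p in manifest["path"]:
            assert (tmp_path / p).exists()

    def test_regeneration_with_same_seed_is_bit_identical(self, tmp_path):
        import hashlib

        m1 = generate_roi_dataset(tmp_path / "a", n_per_class=2, seed=3)
        m2 = generate_roi_dataset(tmp_path / "b", n_per_class=2, seed=3)
        h = lambda root, m: [hashlib.sha256((root / p).read_bytes()).hexdigest()
                             for p in m["path"]]
        assert h(tmp_path / "a", m1) == h(tmp_path / "b", m2)

    def test_reference_distribution_counts_are_honoured_exactly(self):
        # scaled-down version of the reference class imbalance
        counts = {k: max(v // 100, 1) for k, v in REFERENCE_CLASS_COUNTS.items()}
        x, y = generate_roi_arrays(counts, seed=0)
        got = {CLASS_NAMES[i]: int(n) for i, n in zip(*np.unique(y, return_counts=True))}
        assert got == counts
        assert counts["Erythrocyte"] / counts["Basophil"] == pytest.approx(1200 / 969, rel=0.1)

    def test_roi_too_small_for_largest_cell_rejected(self):
        with pytest.raises(ValueError, match="roi_size"):
            generate_roi_arrays(1, roi_size=16)

    def test_roi_background_is_exactly_zero(self):
        x, _ = generate_roi_arrays(1, seed=0)
        for img in x:
            fg = img.any(axis=-1)
            assert np.all(img[~fg] == 0)


def test_default_specs_are_pairwise_distinguishable():
    sigs = {(s.radius_range, s.body_color, s.nucleus_lobes)
            for s in DEFAULT_CLASS_SPECS.values()}
    assert len(sigs) == len(DEFAULT_CLASS_SPECS) == 9
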