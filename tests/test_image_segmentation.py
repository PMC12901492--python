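"""Segmentation recipe: background subtraction, nuclei detection, region
growth with border removal — each checked against simple geometric oracles."""
import numpy as np
import pytest

from acidoquant.image_segmentation import detect_nuclei, grow_cells, subtract_background
from acidoquant.images import Image2D, LabelMap
from acidoquant.synthetic_data._placement import BlurredDiskProfile, add_disk_spot


def _disk_image(shape, centers, radius, amplitude=1.0, px=0.5):
    img = np.zeros(shape)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cr, ccen in centers:
        img[(rr - cr) ** 2 + (cc - ccen) ** 2 <= radius**2] = amplitude
    return Image2D(img, px)


class TestSubtractBackground:
    def test_constant_image_maps_to_zero(self):
        img = Image2D(np.full((64, 64), 3.7), 0.5)
        out = subtract_background(img, 5.0)
        np.testing.assert_allclose(out.pixels, 0.0, atol=1e-12)

    def test_small_bright_dot_is_preserved_on_flat_background(self):
        img = np.full((128, 128), 0.2)
        prof = BlurredDiskProfile(24.0, 1.3)
        add_disk_spot(img, (64.0, 64.0), prof, 1.0)
        peak_above_background = img.max() - 0.2
        out = subtract_background(Image2D(img, 0.5), 15.0)
        assert out.pixels.max() == pytest.approx(peak_above_background, rel=0.01)

    def test_output_is_nonnegative_for_noisy_input(self, rng):
        img = Image2D(np.abs(rng.normal(1.0, 0.3, (96, 96))), 0.5)
        out = subtract_background(img, 6.0)
        assert out.pixels.min() >= 0.0

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(Image2D(np.zeros((32, 32)), 1.0), 0.2)


class TestDetectNuclei:
    def test_counts_well_separated_nuclei_exactly(self, small_tissue_field):
        nuclei = detect_nuclei(small_tissue_field.channels["nuclei"], 0.5)
        assert nuclei.n_labels == small_tissue_field.config.n_cells

    def test_all_zero_image_yields_no_labels(self):
        assert detect_nuclei(Image2D(np.zeros((64, 64)), 0.5), 0.5).n_labels == 0

    def test_touching_nuclei_are_not_declumped(self):
        # two overlapping disks form one connected blob -> one label
        img = _disk_image((128, 128), [(60, 60), (60, 72)], radius=8)
        assert detect_nuclei(img, 0.5).n_labels == 1

    def test_small_specks_filtered_by_min_area(self):
        img = np.zeros((64, 64))
        img[10, 10] = 1.0  # single-pixel speck: 0.25 um^2 at 0.5 um/px
        img[40:48, 40:48] = 1.0
        assert detect_nuclei(Image2D(img, 0.5), 0.5, min_area_um2=10.0).n_labels == 1


class TestGrowCells:
    def test_single_nucleus_grows_to_disk_of_max_radius(self):
        nuclear = _disk_image((201, 201), [(100, 100)], radius=8)
        nuclei = detect_nuclei(nuclear, 0.5)
        guide = Image2D(np.ones((201, 201)), 0.5)
        seg = grow_cells(nuclei, guide, max_radius_um=10.0, intensity_floor=0.0)
        # oracle: pixels within 20 px (10 um) of the nucleus mask
        rr, cc = np.mgrid[0:201, 0:201]
        dist_to_centre = np.hypot(rr - 100, cc - 100)
        expected = dist_to_centre <= 8 + 20 + 0.5  # nucleus radius + growth
        got = seg.cells.labels > 0
        assert (got ^ (dist_to_centre <= 28)).sum() <= expected.sum() * 0.02

    def test_two_symmetric_nuclei_split_along_perpendicular_bisector(self):
        nuclear = _disk_image((161, 161), [(80, 50), (80, 110)], radius=6)
        nuclei = detect_nuclei(nuclear, 0.5)
        guide = Image2D(np.ones((161, 161)), 0.5)
        seg = grow_cells(nuclei, guide, max_radius_um=12.0, intensity_floor=0.0)
        lab = seg.cells.labels
        # brute-force nearest-seed oracle, +-1 px at the boundary
        both = np.nonzero(lab > 0)
        for r, c in zip(*both):
            if abs(c - 80) > 1:  # skip the bisector itself
                expected = 1 if c < 80 else 2
                assert lab[r, c] == expected

    def test_border_touching_cell_is_removed_and_recorded(self):
        nuclear = _disk_image((101, 101), [(8, 50), (60, 50)], radius=6)
        nuclei = detect_nuclei(nuclear, 0.5)
        guide = Image2D(np.ones((101, 101)), 0.5)
        seg = grow_cells(nuclei, guide, max_radius_um=8.0, intensity_floor=0.0)
        assert seg.removed_border_labels == [1]
        assert set(np.unique(seg.cells.labels)) == {0, 2}

    def test_nucleus_pixels_contained_in_own_cell(self, small_tissue_field):
        field = small_tissue_field
        nuclei = detect_nuclei(field.channels["nuclei"], 0.5)
        seg = grow_cells(nuclei, field.channels["PACC1"], 8.0, intensity_floor=0.0)
        for lab in seg.cells.label_ids:
            nucleus = nuclei.labels == lab
            assert np.all(seg.cells.labels[nucleus] == lab)

    def test_cell_regions_are_pairwise_disjoint_by_construction(self, small_tissue_field):
        field = small_tissue_field
        nuclei = detect_nuclei(field.channels["nuclei"], 0.5)
        seg = grow_cells(nuclei, field.channels["PACC1"], 8.0, intensity_floor=0.0)
        # a label raster is disjoint by construction; verify no cell region
        # exceeds the growth disk area (overlap would inflate a region)
        max_area = np.pi * (8 / 0.5 + 9) ** 2
        areas = np.bincount(seg.cells.labels.ravel())[1:]
        assert (areas[areas > 0] <= max_area).all()

    def test_shape_mismatch_signaled(self):
        nuclei = LabelMap(np.zeros((32, 32), np.int32), 0.5)
        with pytest.raises(ValueError):
            grow_cells(nuclei, Image2D(np.zeros((64, 64)), 0.5), 5.0)

    def test_intensity_floor_restricts_growth_to_bright_pixels(self):
        nuclear = _disk_image((101, 101), [(50, 50)], radius=6)
        nuclei = detect_nuclei(nuclear, 0.5)
        guide = np.zeros((101, 101))
        guide[:, :50] = 1.0  # only the left half is admissible
        seg = grow_cells(nuclei, Image2D(guide, 0.5), 10.0, intensity_floor=0.5)
        cells = seg.cells.labels > 0
        right = cells[:, 60:]
        assert right.sum() == 0
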