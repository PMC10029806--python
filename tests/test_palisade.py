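"""Palisade geometry: frustum formulas, 2D cell segmentation, summaries."""

import math

import numpy as np
import pytest
from scipy import ndimage
from scipy.integrate import quad
from skimage.segmentation import watershed

from leafvox import palisade as pal
from leafvox.phantom import PhantomSpec, generate_leaf_phantom
from leafvox.stack_io import DEFAULT_LEGEND

from conftest import make_stack

L = DEFAULT_LEGEND


class TestFrustumFormulas:
    def test_cylinder_limits(self):
        assert pal.frustum_volume(2, 2, 5) == pytest.approx(20 * math.pi)
        assert pal.frustum_lateral_area(1, 1, 5) == pytest.approx(10 * math.pi)

    def test_cone_limits(self):
        assert pal.frustum_volume(2, 0, 3) == pytest.approx(4 * math.pi)
        # slant of a 3-4-5 cone
        assert pal.frustum_lateral_area(3, 0, 4) == pytest.approx(15 * math.pi)

    def test_known_frustum_values(self):
        assert pal.frustum_volume(3, 1, 3) == pytest.approx(13 * math.pi)
        assert pal.frustum_lateral_area(2, 1, 4) == pytest.approx(
            3 * math.pi * math.sqrt(17)
        )

    @pytest.mark.parametrize("r_a", [0.5, 2.0, 7.0])
    @pytest.mark.parametrize("r_b", [0.0, 1.0, 5.0])
    @pytest.mark.parametrize("h", [0.5, 4.0, 30.0])
    def test_against_integration_oracle(self, r_a, r_b, h):
        # independent oracle: slice integrals of disk area / circumference
        def radius(z):
            return r_a + (r_b - r_a) * z / h

        vol, _ = quad(lambda z: math.pi * radius(z) ** 2, 0, h)
        slope = (r_b - r_a) / h
        lat, _ = quad(
            lambda z: 2 * math.pi * radius(z) * math.sqrt(1 + slope**2), 0, h
        )
        assert pal.frustum_volume(r_a, r_b, h) == pytest.approx(vol, rel=1e-6)
        assert pal.frustum_lateral_area(r_a, r_b, h) == pytest.approx(lat, rel=1e-6)

    def test_monotone_in_height(self):
        volumes = [pal.frustum_volume(3, 2, h) for h in (1, 2, 5, 10)]
        areas = [pal.frustum_lateral_area(3, 2, h) for h in (1, 2, 5, 10)]
        assert volumes == sorted(volumes) and len(set(volumes)) == 4
        assert areas == sorted(areas) and len(set(areas)) == 4

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            pal.frustum_volume(-1, 1, 1)
        with pytest.raises(ValueError):
            pal.frustum_lateral_area(1, 1, 0)


def disk_image(centers, radius, shape):
    img = np.zeros(shape, dtype=bool)
    i, k = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    for ci, ck in centers:
        img |= (i - ci) ** 2 + (k - ck) ** 2 <= radius**2
    return img


class TestLabelCells:
    def test_disjoint_disks_each_get_one_label(self):
        centers = [(10 + 16 * a, 10 + 16 * b) for a in range(5) for b in range(5)]
        mask = disk_image(centers, 6, (96, 96))
        labels = pal.label_cells_2d(mask)
        assert labels.max() == 25
        # each label matches one disk's pixel set
        comp, n = ndimage.label(mask)
        assert n == 25
        for lab in range(1, 26):
            sel = labels == lab
            owners = np.unique(comp[sel])
            assert len(owners) == 1
            assert sel.sum() == (comp == owners[0]).sum()

    def test_overlapping_disks_split_like_seeded_oracle(self):
        centers = [(20, 20), (20, 32)]
        mask = disk_image(centers, 8, (40, 52))
        labels = pal.label_cells_2d(mask)
        assert labels.max() == 2
        # oracle: watershed seeded at the true centers
        markers = np.zeros(mask.shape, dtype=int)
        markers[20, 20], markers[20, 32] = 1, 2
        dist = ndimage.distance_transform_edt(mask)
        oracle = watershed(-dist, markers, mask=mask)
        counts = sorted(np.bincount(labels.ravel())[1:])
        oracle_counts = sorted(np.bincount(oracle.ravel())[1:])
        assert counts == oracle_counts

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pal.label_cells_2d(np.zeros((10, 10), dtype=bool))


class TestCellDensity:
    def test_interior_cells_per_area(self):
        # 10 interior cells in a 100x100 um image = 0.01 mm^2
        centers = [(15 + 20 * a, 25 + 25 * b) for a in range(4) for b in range(3)]
        labels, _ = ndimage.label(disk_image(centers[:10], 5, (100, 100)))
        assert pal.cell_density(labels, 1.0) == pytest.approx(1000.0)

    def test_cell_touching_bottom_excluded(self):
        labels, _ = ndimage.label(disk_image([(95, 50)], 6, (100, 100)))
        assert pal.cell_density(labels, 1.0) == 0.0

    def test_translation_recovers_excluded_cells(self):
        # cells touching left/bottom become countable once shifted inward
        centers = [(50, 3), (97, 50), (30, 30)]
        img = disk_image(centers, 5, (100, 100))
        labels, _ = ndimage.label(img)
        n_before = pal.cell_density(labels, 1.0) * 0.01
        shifted = np.roll(np.roll(img, -10, axis=0), 10, axis=1)
        labels_shifted, _ = ndimage.label(shifted)
        n_after = pal.cell_density(labels_shifted, 1.0) * 0.01
        assert round(n_after - n_before) == 2  # the two edge cells

    def test_transposition_symmetry_of_interior_pattern(self):
        centers = [(30, 40), (60, 20), (50, 70)]
        labels, _ = ndimage.label(disk_image(centers, 6, (100, 100)))
        assert pal.cell_density(labels, 1.0) == pal.cell_density(labels.T, 1.0)


class TestEquivalentDiameters:
    def test_inverse_formula(self):
        # one enclosed square cell of area 100 um^2
        img = np.zeros((30, 30), dtype=int)
        img[10:20, 10:20] = 1
        (d,) = pal.equivalent_diameters(img, 1.0)
        assert d == pytest.approx(2 * math.sqrt(100 / math.pi))
        assert d == pytest.approx(11.2838, abs=1e-4)

    def test_square_and_disk_of_equal_area_match(self):
        img = np.zeros((60, 60), dtype=int)
        img[5:14, 5:14] = 1  # 81 pixels
        disk = disk_image([(40, 40)], 5.05, (60, 60))  # 81 pixels
        assert disk.sum() == 81
        img[disk] = 2
        d1, d2 = pal.equivalent_diameters(img, 1.0)
        assert d1 == pytest.approx(d2)

    def test_edge_touching_cells_skipped(self):
        img = np.zeros((20, 20), dtype=int)
        img[0:5, 8:12] = 1  # touches top edge
        assert pal.equivalent_diameters(img, 1.0) == []


class TestSliceSelection:
    def test_explicit_bounds_with_computed_middle(self, small_leaf):
        stack, _ = small_leaf
        assert pal.select_paradermal_slices(stack, bounds=(20, 80)) == (20, 50, 80)

    def test_detection_matches_ground_truth(self, small_leaf):
        stack, truth = small_leaf
        top, mid, bot = pal.select_paradermal_slices(stack)
        t_top, t_bot = truth.palisade_bounds
        assert top == t_top
        assert abs(bot - t_bot) <= 1
        assert mid == (top + bot) // 2

    def test_too_thin_palisade_rejected(self, small_leaf):
        stack, _ = small_leaf
        with pytest.raises(ValueError, match="thinner"):
            pal.select_paradermal_slices(stack, bounds=(20, 21))


class TestPalisadeSummary:
    @pytest.fixture(scope="class")
    @staticmethod
    def cylinder_phantom():
        spec = PhantomSpec(
            palisade_radius_top_um=5.0,
            palisade_radius_bottom_um=5.0,
            leaf_thickness_um=136.0,
            epidermis_thickness_um=8.0,
            palisade_fraction=0.5,
            palisade_pitch_um=16.0,
            lateral_extent_um=(96, 96),
            stoma_pitch_um=48.0,
            stoma_radius_um=3.0,
        )
        return generate_leaf_phantom(spec)

    def test_cylinder_cells_recovered(self, cylinder_phantom):
        stack, truth = cylinder_phantom
        s = pal.palisade_summary(stack, bounds=truth.palisade_bounds)
        h = s.h_top_mid_um + s.h_mid_bot_um
        assert s.V_pal_um3 == pytest.approx(math.pi * 25 * h, rel=0.05)
        assert s.S_pal_um2 == pytest.approx(2 * math.pi * 5 * h, rel=0.05)
        # cylinder ratio S/V = 2/r
        assert s.S_over_V_per_um == pytest.approx(2 / 5, rel=0.05)

    def test_frustum_radii_within_one_voxel(self, small_leaf):
        stack, truth = small_leaf
        s = pal.palisade_summary(stack, bounds=truth.palisade_bounds)
        r_top, r_bot = truth.palisade_radii_um
        v = stack.voxel_size_um
        assert abs(s.r_top_um - r_top) <= v
        assert abs(s.r_bot_um - r_bot) <= v
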