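"""Segmentation masks and the four attenuation-map constructions."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phantomac import (
    ACMethod,
    BilinearScaling,
    BinaryMask,
    MU_MATERIAL,
    MU_SOFT_TISSUE,
    MU_WATER,
    SegmentationParams,
    VoxelGrid,
    build_nowall_mrac,
    build_phantom_mrac,
    build_standard_mrac,
    ct_to_mu,
    material_mask,
    simulate_dixon,
    total_phantom_mask,
    water_mask,
)
from phantomac.dixon import DixonSimParams

from test_phantom import analytic_volumes_ml

GRID733 = VoxelGrid((7, 7, 3), (2.0, 2.0, 2.0))


class TestTotalPhantomMask:
    def test_hand_executed_morphology_on_toy_block(self):
        """5x5x3 block at 500 a.u.: threshold keeps the block, closing and
        largest-component leave it intact, and the 6-connected 1-voxel
        erosion strips every face -> the central 3x3x1 block remains."""
        vol = np.full(GRID733.shape, 50.0)
        vol[1:6, 1:6, :] = 500.0
        mask = total_phantom_mask(vol, GRID733)
        expect = np.zeros(GRID733.shape, dtype=bool)
        expect[2:5, 2:5, 1] = True
        assert np.array_equal(mask.values, expect)

    def test_all_zero_volume_is_an_error(self):
        with pytest.raises(ValueError, match="empty phantom mask"):
            total_phantom_mask(np.zeros(GRID733.shape), GRID733)

    def test_largest_component_drops_edge_artifacts(self):
        vol = np.zeros((12, 12, 3))
        vol[2:9, 2:9, :] = 500.0
        vol[11, 11, 2] = 900.0     # lone hot pixel at the FOV edge
        mask = total_phantom_mask(vol, VoxelGrid((12, 12, 3), (2, 2, 2)))
        assert not mask.values[11, 11, 2]
        assert mask.values.any()

    def test_volume_matches_outer_phantom_analytics(self, spec, noisy_study):
        mask = total_phantom_mask(noisy_study.opposed_phase, noisy_study.grid)
        outer = math.pi * (spec.outer_radius_mm / 10) ** 2 * spec.outer_length
        assert mask.volume_ml == pytest.approx(outer, rel=0.03)


class TestWaterMask:
    def test_fat_enhancement_arithmetic(self):
        """OP 1000 with filtered fat 200 -> enhanced 200, excluded; the
        same OP without fat stays in; a polymer-level OP of 333 is out."""
        grid = VoxelGrid((9, 9, 3), (2, 2, 2))
        op = np.full(grid.shape, 1000.0)
        op[6:, :, :] = 333.0
        fat = np.zeros(grid.shape)
        fat[:3, :, :] = 200.0           # constant block survives filtering
        mask = water_mask(op, fat, grid)
        assert not mask.values[1, 4, 1]       # 1000 - 4*200 = 200 < 400
        assert mask.values[4, 4, 1]           # 1000 > 400
        assert not mask.values[7, 4, 1]       # 333 < 400

    def test_grid_mismatch_is_an_error(self):
        grid = VoxelGrid((4, 4, 2), (2, 2, 2))
        with pytest.raises(ValueError, match="share one grid"):
            water_mask(np.zeros(grid.shape), np.zeros((5, 4, 2)), grid)

    def test_raising_thresholds_never_grows_masks(self, noiseless_study):
        op, fat = noiseless_study.opposed_phase, noiseless_study.fat
        grid = noiseless_study.grid
        lo = SegmentationParams()
        hi_w = dataclasses.replace(lo, water_threshold=600.0)
        hi_p = dataclasses.replace(lo, phantom_threshold=200.0)
        assert not (water_mask(op, fat, grid, hi_w).values
                    & ~water_mask(op, fat, grid, lo).values).any()
        assert not (total_phantom_mask(op, grid, hi_p).values
                    & ~total_phantom_mask(op, grid, lo).values).any()


class TestMaskAlgebra:
    def test_water_equals_total_gives_empty_material(self):
        grid = VoxelGrid((4, 4, 2), (2, 2, 2))
        m = np.zeros(grid.shape, dtype=bool)
        m[1:3, 1:3, :] = True
        out = material_mask(BinaryMask(grid, m), BinaryMask(grid, m.copy()))
        assert not out.values.any()

    def test_subtraction_is_set_difference(self):
        grid = VoxelGrid((4, 4, 2), (2, 2, 2))
        total = np.zeros(grid.shape, dtype=bool)
        total[1:3, 1:3, :] = True
        water = np.zeros(grid.shape, dtype=bool)
        water[0, 0, 0] = True       # outside total
        out = material_mask(BinaryMask(grid, total), BinaryMask(grid, water))
        assert np.array_equal(out.values, total)

    def test_partition_on_simulated_phantom(self, segmentation):
        total, water, material = segmentation
        assert not (material.values & water.values).any()
        assert np.array_equal(material.values | water.values, total.values)

    def test_material_overestimation_is_subpixel_to_one_pixel(self, spec, segmentation):
        """The housing mask overshoots into the water by a fraction of a
        pixel up to about one pixel of equivalent shell, as seen on the
        scanner (never an underestimation)."""
        _, _, material = segmentation
        _, mat_an = analytic_volumes_ml(spec)
        inner_surface = (
            2 * math.pi * 12.0 * spec.inner_length + 2 * math.pi * 12.0 ** 2
            + sum(math.pi * (d / 10.0) * spec.rod_length
                  for d in spec.rod_diameters_mm))
        shell_px = (material.volume_ml - mat_an) / inner_surface * 10.0 / 2.6
        assert 0.0 < shell_px < 1.5


class TestMapBuilders:
    @pytest.fixture()
    def masks(self):
        grid = VoxelGrid((6, 6, 2), (2, 2, 2))
        total = np.zeros(grid.shape, dtype=bool)
        total[1:5, 1:5, :] = True
        water = np.zeros(grid.shape, dtype=bool)
        water[2:4, 2:4, :] = True
        return BinaryMask(grid, total), BinaryMask(grid, water)

    def test_phantom_mrac_values(self, masks):
        total, water = masks
        amap = build_phantom_mrac(total, water)
        assert amap.method_tag is ACMethod.PHANTOM_MRAC
        assert amap.mu[2, 2, 0] == pytest.approx(MU_WATER)
        assert amap.mu[1, 1, 0] == pytest.approx(MU_MATERIAL)
        assert amap.mu[0, 0, 0] == 0.0

    def test_nowall_zeroes_exactly_the_material(self, masks):
        total, water = masks
        phantom = build_phantom_mrac(total, water)
        nowall = build_nowall_mrac(total, water)
        assert nowall.mu[2, 2, 0] == pytest.approx(MU_WATER)
        assert nowall.mu[1, 1, 0] == 0.0
        diff_support = phantom.mu != nowall.mu
        assert np.array_equal(diff_support, total.values & ~water.values)

    def test_standard_mrac_dilates_by_one_pixel(self, masks):
        total, _ = masks
        amap = build_standard_mrac(total)
        assert amap.mu[2, 2, 0] == pytest.approx(MU_SOFT_TISSUE)
        assert amap.mu[5, 2, 0] == pytest.approx(MU_SOFT_TISSUE)  # 1 px outside
        assert amap.mu[0, 0, 0] == 0.0

    def test_tissue_swaps_do_not_change_the_phantom_mrac(self, study_label):
        """Swap artifacts live inside the housing; away from compartment
        borders the phantom MR-AC is unchanged by them."""
        from scipy import ndimage

        base = DixonSimParams(noise_sigma=0.0, swap_patch_count=0)
        swapped = dataclasses.replace(base, swap_patch_count=4, seed=9)
        grid = study_label.grid
        maps = []
        for par in (base, swapped):
            study = simulate_dixon(study_label, par)
            total = total_phantom_mask(study.opposed_phase, grid)
            water = water_mask(study.opposed_phase, study.fat, grid)
            water = BinaryMask(grid, water.values & total.values)
            maps.append(build_phantom_mrac(total, water))
        border = (study_label.frac_material > 0) & (study_label.frac_material < 1)
        near_border = ndimage.binary_dilation(border, iterations=2)
        same = maps[0].mu == maps[1].mu
        assert np.all(same | near_border)


class TestCtToMu:
    def test_printed_anchor_points(self):
        s = BilinearScaling()
        assert s.mu(0.0) == pytest.approx(0.096)
        assert s.mu(-1000.0) == pytest.approx(0.0)
        assert s.mu(s.hu_for_mu(MU_MATERIAL)) == pytest.approx(MU_MATERIAL)

    def test_continuous_at_break(self):
        s = BilinearScaling()
        assert s.mu(s.break_hu - 1e-9) == pytest.approx(s.mu(s.break_hu + 1e-9),
                                                        abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1000, 3000), min_size=2, max_size=30))
    def test_nondecreasing_in_hu(self, hus):
        s = BilinearScaling()
        hus = np.sort(np.asarray(hus))
        mu = s.mu(hus)
        assert (np.diff(mu) >= -1e-12).all()

    def test_map_construction(self):
        grid = VoxelGrid((3, 3, 1), (2, 2, 2))
        hu = np.array([[[-1000.0], [0.0], [109.5]]] * 3)
        amap = ct_to_mu(hu, grid)
        assert amap.method_tag is ACMethod.CT_AC
        assert amap.mu[0, 0, 0] == 0.0
        assert amap.mu[0, 1, 0] == pytest.approx(0.096)
        assert amap.mu[0, 2, 0] == pytest.approx(MU_MATERIAL, abs=1e-4)
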