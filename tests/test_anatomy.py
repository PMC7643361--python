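"""Vim splitting, stereotactic targeting, sphere targets, label fusion."""

import numpy as np
import pytest

from vimtarget.anatomy import (
    StereotacticLandmarks,
    StereotacticRule,
    majority_vote,
    sphere_target,
    split_vlp,
    standard_target,
    target_landmark_distances,
)
from vimtarget.grids import BinaryMask, LabelVolume, VoxelGrid


def _vlp_on_slices(z_slices, grid_dims=(8, 8, 24)):
    grid = VoxelGrid(grid_dims)
    data = np.zeros(grid.dims, dtype=bool)
    for z in z_slices:
        data[2:5, 2:5, z] = True
    return BinaryMask(grid, data)


class TestSplitVlp:
    def test_even_slice_count_splits_in_half(self):
        vlp = _vlp_on_slices(range(10, 18))
        dorsal, vim = split_vlp(vlp)
        assert sorted(set(vim.indices()[:, 2])) == [10, 11, 12, 13]
        assert sorted(set(dorsal.indices()[:, 2])) == [14, 15, 16, 17]

    def test_odd_slice_count_midplane_slice_goes_ventral(self):
        vlp = _vlp_on_slices(range(10, 17))  # z* = 13; slice 13 -> vim
        dorsal, vim = split_vlp(vlp)
        assert sorted(set(vim.indices()[:, 2])) == [10, 11, 12, 13]
        assert sorted(set(dorsal.indices()[:, 2])) == [14, 15, 16]

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError, match="single"):
            split_vlp(_vlp_on_slices([5]))

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        grid = VoxelGrid((10, 10, 16))
        data = rng.random(grid.dims) < 0.3
        data[:, :, :4] = False
        data[:, :, 12:] = False
        data[4, 4, 4] = data[4, 4, 11] = True  # ensure >= 2 slices
        vlp = BinaryMask(grid, data)
        dorsal, vim = split_vlp(vlp)
        assert vim.count + dorsal.count == vlp.count
        assert not (vim.data & dorsal.data).any()
        assert vim.indices()[:, 2].max() < dorsal.indices()[:, 2].min()


LM = StereotacticLandmarks(
    AC=(0.0, 12.0, 0.0),
    PC=(0.0, -12.0, 0.0),
    third_ventricle_wall_x=-2.5,
    treated_side="left",
)


class TestStandardTarget:
    def test_left_treated_example(self):
        np.testing.assert_allclose(standard_target(LM), [-13.5, -6.0, 0.0])

    def test_right_treated_mirror(self):
        np.testing.assert_allclose(standard_target(LM.mirrored()), [13.5, -6.0, 0.0])

    def test_flip_equivariance(self):
        p = standard_target(LM)
        p_m = standard_target(LM.mirrored())
        np.testing.assert_allclose(p_m, [-p[0], p[1], p[2]])

    def test_small_acpc_fraction_approaches_pc(self):
        rule = StereotacticRule(acpc_fraction=1e-9)
        assert standard_target(LM, rule)[1] == pytest.approx(LM.PC[1], abs=1e-6)

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            StereotacticRule(acpc_fraction=0.0)
        with pytest.raises(ValueError):
            StereotacticRule(lateral_offset=-1.0)


class TestLandmarkDistances:
    def test_standard_target_report(self):
        rep = target_landmark_distances(standard_target(LM), LM)
        assert rep.midline_dist == pytest.approx(13.5)
        assert rep.pc_dist_y == pytest.approx(6.0)
        assert rep.acpc_percent == pytest.approx(25.0)
        assert rep.acpc_plane_dist_z == pytest.approx(0.0)

    def test_midline_point(self):
        rep = target_landmark_distances((0.0, 3.0, 1.0), LM)
        assert rep.midline_dist == 0.0

    def test_point_at_ac_is_100_percent(self):
        rep = target_landmark_distances(LM.AC, LM)
        assert rep.acpc_percent == pytest.approx(100.0)

    def test_degenerate_landmarks_rejected(self):
        with pytest.raises(ValueError):
            StereotacticLandmarks(
                AC=(0, 5, 0), PC=(0, 5, 0), third_ventricle_wall_x=-2, treated_side="left"
            )


class TestSphereTarget:
    def test_single_voxel(self):
        grid = VoxelGrid((9, 9, 9))
        mask = sphere_target((4.2, 4.0, 3.9), 1.0, grid)
        assert mask.indices().tolist() == [[4, 4, 4]]

    def test_exact_20_voxels_within_radius(self):
        grid = VoxelGrid((21, 21, 21))
        mask = sphere_target((10.0, 10.0, 10.0), 20.0, grid)
        assert mask.count == 20
        d = np.linalg.norm(mask.grid.index_to_world(mask.indices()) - 10.0, axis=1)
        assert d.max() <= 1.8

    def test_volume_7_on_voxel_center_is_cross(self):
        grid = VoxelGrid((9, 9, 9))
        mask = sphere_target((4.0, 4.0, 4.0), 7.0, grid)
        expected = {(4, 4, 4), (3, 4, 4), (5, 4, 4), (4, 3, 4), (4, 5, 4), (4, 4, 3), (4, 4, 5)}
        assert {tuple(i) for i in mask.indices()} == expected

    def test_exact_count_for_anisotropic_spacing(self):
        grid = VoxelGrid((15, 15, 15), spacing=(1.0, 1.0, 2.0))
        mask = sphere_target((7.0, 7.0, 14.0), 20.0, grid)
        assert mask.count == round(20.0 / 2.0)

    def test_excessive_volume_rejected(self):
        grid = VoxelGrid((4, 4, 4))
        with pytest.raises(ValueError):
            sphere_target((2, 2, 2), 1000.0, grid)


class TestMajorityVote:
    def _lv(self, grid, arr):
        return LabelVolume(grid, arr, {1: "VLp", 2: "MD", 3: "Pul"})

    def test_identical_labelings_pass_through(self):
        grid = VoxelGrid((4, 4, 4))
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 4, grid.dims)
        fused = majority_vote([self._lv(grid, arr)] * 3)
        np.testing.assert_array_equal(fused.labels, arr)

    def test_two_versus_one_majority(self):
        grid = VoxelGrid((2, 2, 2))
        a = np.full(grid.dims, 1)
        b = np.full(grid.dims, 2)
        fused = majority_vote([self._lv(grid, a), self._lv(grid, a), self._lv(grid, b)])
        assert (fused.labels == 1).all()

    def test_three_way_tie_gives_background(self):
        grid = VoxelGrid((2, 2, 2))
        arrs = [np.full(grid.dims, c) for c in (1, 2, 3)]
        fused = majority_vote([self._lv(grid, a) for a in arrs])
        assert (fused.labels == 0).all()

    def test_grid_mismatch_rejected(self):
        a = self._lv(VoxelGrid((2, 2, 2)), np.zeros((2, 2, 2), int))
        b = self._lv(VoxelGrid((3, 3, 3)), np.zeros((3, 3, 3), int))
        with pytest.raises(ValueError):
            majority_vote([a, b])
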