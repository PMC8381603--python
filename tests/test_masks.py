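"""Voxelization of node clouds and the DICE overlap metric."""

import numpy as np
import pytest

from cardiogrowth.masks import (
    BinaryMask3D,
    GridSpec,
    dice,
    grid_for_points,
    mask_from_nodes,
    mesh_sample_points,
    spherical_element,
)


def lattice_cube(side, origin=(0.0, 0.0, 0.0)):
    ax = [np.arange(float(side)) + o for o in origin]
    return np.stack(np.meshgrid(*ax, indexing="ij"), -1).reshape(-1, 3)


class TestMaskFromNodes:
    def test_solid_cube_volume_oracle(self):
        """A dense 1-voxel lattice of side 20 rasterizes to ~20^3 voxels."""
        pts = lattice_cube(20)
        mask = mask_from_nodes(pts, grid_for_points(pts, 1.0))
        assert abs(mask.volume_voxels - 20**3) / 20**3 < 0.10

    def test_single_node_compact_blob(self):
        pts = np.tile([[10.0, 10.0, 10.0]], (8, 1))
        grid = grid_for_points(pts, 1.0)
        mask = mask_from_nodes(pts, grid)
        idx = np.argwhere(mask.grid)
        extent = idx.max(axis=0) - idx.min(axis=0) + 1
        # diameter bounded by kernel support (4) + closing element (6)
        assert mask.volume_voxels >= 1
        assert extent.max() <= 10
        center_voxel = np.round((np.array([10.0, 10, 10]) - grid.origin) / grid.spacing)
        assert mask.grid[tuple(center_voxel.astype(int))]

    def test_parallel_sheets_gap_closed(self):
        """Two node sheets 3 voxels apart merge after the 6-voxel closing."""
        xy = np.stack(np.meshgrid(np.arange(12.0), np.arange(12.0), indexing="ij"), -1).reshape(-1, 2)
        a = np.column_stack([xy, np.zeros(len(xy))])
        b = np.column_stack([xy, np.full(len(xy), 3.0)])
        grid = grid_for_points(np.vstack([a, b]), 1.0)
        closed = mask_from_nodes(np.vstack([a, b]), grid)
        open_ = mask_from_nodes(np.vstack([a, b]), grid, closing_diameter=0)
        # the sheets occupy voxel planes z=8 and z=11 (margin 8); probe the
        # two gap planes over the central footprint of the sheets
        gap_closed = closed.grid[10:18, 10:18, 9:11]
        gap_open = open_.grid[10:18, 10:18, 9:11]
        assert gap_closed.all()
        assert not gap_open.any()

    def test_translation_equivariance_whole_voxels(self):
        pts = lattice_cube(10)
        grid = GridSpec((30, 30, 30), 1.0, (-8.0, -8.0, -8.0))
        m0 = mask_from_nodes(pts, grid)
        m1 = mask_from_nodes(pts + [3.0, 0.0, 0.0], grid)
        np.testing.assert_array_equal(m1.grid[3:], m0.grid[:-3])

    def test_empty_after_threshold_is_an_error(self):
        pts = np.random.default_rng(0).uniform(0, 40, (8, 3))  # 8 sparse points
        grid = GridSpec((10, 10, 10), 8.0, (0.0, 0.0, 0.0))  # very coarse
        with pytest.raises(ValueError, match="too coarse|at least 8"):
            mask_from_nodes(pts[:4], grid)

    def test_spherical_element_diameter(self):
        se = spherical_element(6)
        assert se.shape == (6, 6, 6)
        assert se[0, 2, 2] or se[0, 3, 3]  # spans the full 6-voxel diameter


class TestDice:
    def _mask(self, grid):
        return BinaryMask3D(grid, 1.0, (0.0, 0.0, 0.0))

    def test_self_dice_is_one(self):
        g = np.zeros((10, 10, 10), bool)
        g[2:7, 3:8, 1:5] = True
        assert dice(self._mask(g), self._mask(g)) == 1.0

    def test_disjoint_masks_zero(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[:3], b[7:] = True, True
        assert dice(self._mask(a), self._mask(b)) == 0.0

    def test_half_overlapping_cubes_by_voxel_count(self):
        """Equal cubes overlapping in exactly half of each score 0.5."""
        a = np.zeros((20, 10, 10), bool)
        b = np.zeros((20, 10, 10), bool)
        a[0:8] = True
        b[4:12] = True
        inter = np.logical_and(a, b).sum()
        assert inter == a.sum() / 2 == b.sum() / 2  # construction check
        assert dice(self._mask(a), self._mask(b)) == pytest.approx(0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.random((12, 12, 12)) > 0.5
        b = rng.random((12, 12, 12)) > 0.5
        assert dice(self._mask(a), self._mask(b)) == dice(self._mask(b), self._mask(a))

    def test_both_empty_is_zero_with_warning(self):
        z = np.zeros((5, 5, 5), bool)
        with pytest.warns(RuntimeWarning):
            assert dice(self._mask(z), self._mask(z)) == 0.0

    def test_mismatched_grids_rejected(self):
        a = self._mask(np.ones((5, 5, 5), bool))
        b = BinaryMask3D(np.ones((5, 5, 5), bool), 2.0, (0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            dice(a, b)


def test_nifti_roundtrip(tmp_path):
    g = np.zeros((8, 9, 10), bool)
    g[2:5, 3:6, 4:8] = True
    mask = BinaryMask3D(g, 0.5, (1.0, -2.0, 3.0))
    mask.to_nifti(tmp_path / "m.nii.gz")
    back = BinaryMask3D.from_nifti(tmp_path / "m.nii.gz")
    np.testing.assert_array_equal(back.grid, g)
    assert back.spacing == 0.5
    np.testing.assert_allclose(back.origin, (1.0, -2.0, 3.0))


def test_mesh_sample_points_cover_elements(tiny_lv_mesh):
    pts = mesh_sample_points(tiny_lv_mesh.nodes, tiny_lv_mesh.elements, 1.0)
    assert pts.shape[0] > tiny_lv_mesh.n_nodes
    # all samples stay inside the mesh bounding box
    assert (pts.min(0) >= tiny_lv_mesh.nodes.min(0) - 1e-9).all()
    assert (pts.max(0) <= tiny_lv_mesh.nodes.max(0) + 1e-9).all()
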