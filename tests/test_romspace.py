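"""Cosine-corrected shape space, alpha-shape volumes, map comparison."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from osteorom import (CorrectedCloud, PoseGrid, alpha_volume, compare_maps,
                      cosine_correct, volume_ratio)
from osteorom.romspace import wraparound_cloud
from osteorom.sampling import ROMMap, generate_grid


def make_map(grid: PoseGrid, viable_mask) -> ROMMap:
    poses = generate_grid(grid)
    mask = np.asarray(viable_mask, dtype=bool)
    return ROMMap(grid=grid, regime="3dof", poses=poses, viable_mask=mask,
                  n_offsets_clear=mask.astype(int))


def mask_for(grid: PoseGrid, wanted) -> np.ndarray:
    poses = generate_grid(grid)
    wanted = {tuple(w) for w in wanted}
    return np.array([tuple(p) in wanted for p in poses])


class TestCosineCorrect:
    def test_fe_zero_is_identity(self):
        grid = PoseGrid(step=10.0)
        poses = generate_grid(grid)
        mask = poses[:, 1] == 0.0
        cloud = cosine_correct(make_map(grid, mask))
        np.testing.assert_allclose(cloud.points, poses[mask], atol=1e-12)

    def test_gimbal_poses_collapse(self):
        grid = PoseGrid(step=30.0)
        mask = mask_for(grid, [(30.0, 90.0, 60.0)])
        cloud = cosine_correct(make_map(grid, mask))
        np.testing.assert_allclose(cloud.points[0], [0.0, 90.0, 60.0],
                                   atol=1e-9)

    def test_single_uncorrected_example(self):
        grid = PoseGrid(step=10.0)
        mask = mask_for(grid, [(30.0, 0.0, 50.0)])
        cloud = cosine_correct(make_map(grid, mask))
        np.testing.assert_allclose(cloud.points[0], [30.0, 0.0, 50.0])

    def test_correction_contracts_hull_volume(self):
        rng = np.random.default_rng(5)
        grid = PoseGrid(step=15.0)
        poses = generate_grid(grid)
        for _ in range(50):
            mask = np.zeros(len(poses), dtype=bool)
            mask[rng.choice(len(poses), size=60, replace=False)] = True
            cloud = cosine_correct(make_map(grid, mask))
            v_corr = ConvexHull(cloud.points).volume
            v_raw = ConvexHull(poses[mask]).volume
            assert v_corr <= v_raw * (1 + 1e-9)

    def test_empty_map_rejected(self):
        grid = PoseGrid(step=90.0)
        with pytest.raises(ValueError, match="no viable"):
            cosine_correct(make_map(grid, np.zeros(grid.size, dtype=bool)))

    def test_alternative_pairing(self):
        grid = PoseGrid(step=30.0)
        mask = mask_for(grid, [(30.0, 60.0, 90.0)])
        cloud = cosine_correct(make_map(grid, mask), correction="lar_by_fe")
        np.testing.assert_allclose(cloud.points[0],
                                   [30.0, 60.0, 90.0 * np.cos(np.radians(60))])


class TestAlphaVolume:
    def test_cube_corners_hull_limit(self):
        corners = np.array(np.meshgrid([0, 10.0], [0, 10.0], [0, 10.0])
                           ).reshape(3, -1).T
        res = alpha_volume(CorrectedCloud(corners, "none"), alpha=100.0)
        assert res.volume == pytest.approx(1000.0, rel=1e-9)
        assert res.n_components == 1

    def test_dense_grid_box_volume(self):
        xs = np.arange(0, 55, 5.0)
        pts = np.array(np.meshgrid(xs, xs, xs)).reshape(3, -1).T
        res = alpha_volume(CorrectedCloud(pts, "none"), alpha=10.0)
        assert abs(res.volume - 125_000.0) / 125_000.0 < 0.05

    def test_large_alpha_recovers_convex_hull(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(200, 3)) * [30, 20, 10]
        hull = ConvexHull(pts).volume
        res = alpha_volume(CorrectedCloud(pts, "none"), alpha=1e9)
        assert abs(res.volume - hull) / hull < 1e-6

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 50, size=(300, 3))
        cloud = CorrectedCloud(pts, "none")
        vols = [alpha_volume(cloud, a).volume for a in (5.0, 10.0, 20.0, 1e6)]
        assert all(v1 <= v2 + 1e-9 for v1, v2 in zip(vols, vols[1:]))

    def test_two_separated_clusters(self):
        xs = np.arange(0, 25, 5.0)
        block = np.array(np.meshgrid(xs, xs, xs)).reshape(3, -1).T
        pts = np.vstack([block, block + [200.0, 0, 0]])
        res = alpha_volume(CorrectedCloud(pts, "none"), alpha=10.0)
        assert res.n_components == 2

    def test_coplanar_rejected(self):
        pts = np.column_stack([np.random.default_rng(0).normal(size=(30, 2)),
                               np.zeros(30)])
        with pytest.raises(ValueError):
            alpha_volume(CorrectedCloud(pts, "none"), alpha=5.0)

    def test_nonpositive_alpha_rejected(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            alpha_volume(CorrectedCloud(pts, "none"), alpha=0.0)

    def test_wraparound_duplicates_boundary(self):
        pts = np.array([[0.0, -180.0, 0.0], [0.0, 180.0, 5.0],
                        [5.0, 170.0, 0.0], [2.0, -175.0, 3.0]])
        wrapped = wraparound_cloud(CorrectedCloud(pts, "none"), axes=(1,))
        assert len(wrapped.points) == 3 * len(pts)


class TestCompareMaps:
    def test_identical_maps(self):
        grid = PoseGrid(step=45.0)
        mask = np.zeros(grid.size, dtype=bool)
        mask[:20] = True
        a = make_map(grid, mask)
        c = compare_maps(a, make_map(grid, mask.copy()))
        assert c.jaccard == 1.0
        assert c.n_a_only == c.n_b_only == 0

    def test_empty_versus_nonempty(self):
        grid = PoseGrid(step=45.0)
        mask = np.zeros(grid.size, dtype=bool)
        mask[:10] = True
        c = compare_maps(make_map(grid, mask),
                         make_map(grid, np.zeros(grid.size, dtype=bool)))
        assert c.jaccard == 0.0
        assert c.n_a_only == 10

    def test_constructed_overlap_of_40(self):
        grid = PoseGrid(step=30.0)
        ma = np.zeros(grid.size, dtype=bool)
        mb = np.zeros(grid.size, dtype=bool)
        ma[:100] = True
        mb[60:160] = True  # overlap = poses 60..99
        c = compare_maps(make_map(grid, ma), make_map(grid, mb))
        assert c.n_both == 40
        assert c.n_a_only == 60
        assert c.n_b_only == 60

    def test_symmetry(self):
        grid = PoseGrid(step=45.0)
        rng = np.random.default_rng(4)
        ma = rng.random(grid.size) < 0.2
        mb = rng.random(grid.size) < 0.2
        ab = compare_maps(make_map(grid, ma), make_map(grid, mb))
        ba = compare_maps(make_map(grid, mb), make_map(grid, ma))
        assert ab.jaccard == ba.jaccard
        assert ab.n_a_only == ba.n_b_only

    def test_mismatched_grids_rejected(self):
        a = make_map(PoseGrid(step=45.0),
                     np.ones(PoseGrid(step=45.0).size, dtype=bool))
        b = make_map(PoseGrid(step=90.0),
                     np.ones(PoseGrid(step=90.0).size, dtype=bool))
        with pytest.raises(ValueError, match="different grids"):
            compare_maps(a, b)


class TestVolumeRatio:
    def test_restrictive_to_chimpanzee_scale(self):
        # printed four-DOF volumes: most congruent simulations against the
        # most mobile (chimpanzee-like) envelope
        assert volume_ratio(1_048_249, 5_632_700) == 18.61
        assert volume_ratio(1_645_521, 5_632_700) == 29.21

    def test_restrictive_to_human_scale(self):
        assert volume_ratio(1_048_249, 4_000_521) == 26.20
        assert volume_ratio(1_645_521, 4_000_521) == 41.13

    def test_equal_volumes(self):
        assert volume_ratio(123.4, 123.4) == 100.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            volume_ratio(1.0, 0.0)
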