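"""Pose grids, offset spheres, and viability classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteorom import (JointRig, PoseGrid, SyntheticJointSpec,
                      build_offset_sphere, classify_poses, generate_grid,
                      make_socket_joint)
from osteorom.sampling import OffsetSphere

from .conftest import icosphere


class TestPoseGrid:
    def test_default_grid_count(self):
        grid = PoseGrid()
        assert grid.size == 73 * 37 * 73 == 197_173
        # counting, not materializing: cheap even at full size
        assert len(generate_grid(grid)) == 197_173

    def test_coarse_grid_closed_form(self):
        grid = PoseGrid(step=90.0)
        assert grid.size == 5 * 3 * 5 == 75

    def test_ordering_abad_outer_lar_inner(self):
        grid = PoseGrid(fe_range=(0, 90), abad_range=(0, 90),
                        lar_range=(0, 90), step=90.0)
        poses = generate_grid(grid)
        np.testing.assert_array_equal(poses[:4], [
            [0, 0, 0], [0, 0, 90], [0, 90, 0], [0, 90, 90]])
        assert poses[-1].tolist() == [90, 90, 90]

    def test_indivisible_range_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            PoseGrid(fe_range=(0, 100), step=33.0)

    @given(
        na=st.integers(0, 6), nf=st.integers(0, 6), nl=st.integers(0, 6),
        step=st.sampled_from([2.5, 5.0, 10.0, 45.0]),
    )
    @settings(max_examples=40, deadline=None)
    def test_count_closed_form_property(self, na, nf, nl, step):
        grid = PoseGrid(fe_range=(0, nf * step), abad_range=(0, na * step),
                        lar_range=(0, nl * step), step=step)
        assert grid.size == (na + 1) * (nf + 1) * (nl + 1)
        assert len(generate_grid(grid)) == grid.size


class TestOffsetSphere:
    def test_standard_lattice(self):
        s = build_offset_sphere(2.448, 8, 4)
        assert s.n_vertices == 26
        assert s.n_faces == 32
        np.testing.assert_allclose(np.linalg.norm(s.vertices, axis=1), 2.448,
                                   atol=1e-9)

    def test_octahedron_case(self):
        s = build_offset_sphere(1.0, 4, 2)
        assert s.n_vertices == 6
        assert s.n_faces == 8

    @pytest.mark.parametrize("a", range(3, 13))
    @pytest.mark.parametrize("h", [2, 3, 4, 6])
    def test_counts_match_enumeration(self, a, h):
        s = OffsetSphere(1.0, a, h)
        assert s.n_vertices == a * (h - 1) + 2
        assert s.n_faces == a * h
        assert len({tuple(np.round(v, 9)) for v in s.vertices}) == s.n_vertices

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            build_offset_sphere(-1.0)
        with pytest.raises(ValueError):
            build_offset_sphere(1.0, 2, 4)


@pytest.fixture(scope="module")
def free_rig(world_acs):
    """Distal far from a small fixed element: nothing can collide."""
    prox = icosphere(radius=2.0, subdivisions=1, center=(500, 500, 500))
    dist = icosphere(radius=3.0, subdivisions=1, center=(0, 0, -6))
    return JointRig(proximal=prox, distal=dist, acs=world_acs)


@pytest.fixture(scope="module")
def tight_rig(world_acs):
    spec = SyntheticJointSpec(mesh_resolution=150, cup_coverage=150.0)
    prox, dist, _ = make_socket_joint(spec)
    return JointRig(proximal=prox, distal=dist, acs=world_acs)


class TestClassifyPoses:
    def test_free_joint_fully_viable(self, free_rig):
        grid = PoseGrid(step=45.0)
        rom = classify_poses(free_rig, grid, "3dof")
        assert rom.n_viable == grid.size

    def test_enclosed_joint_zero_viable(self, world_acs):
        # near-complete cup with zero clearance: the neck pierces the shell
        # in every pose
        spec = SyntheticJointSpec(head_radius=17.552, cup_radius=17.552,
                                  cup_coverage=179.0, mesh_resolution=150)
        prox, dist, _ = make_socket_joint(spec)
        rig = JointRig(proximal=prox, distal=dist, acs=world_acs)
        rom = classify_poses(rig, PoseGrid(step=90.0), "3dof")
        assert rom.n_viable == 0

    def test_congruent_interpenetrating_zero_viable(self, world_acs):
        # equal fitted radii: tessellated surfaces cross at every pose
        spec = SyntheticJointSpec(head_radius=17.552, cup_radius=17.552,
                                  cup_coverage=120.0, mesh_resolution=300)
        prox, dist, _ = make_socket_joint(spec)
        rig = JointRig(proximal=prox, distal=dist, acs=world_acs)
        rom = classify_poses(rig, PoseGrid(step=90.0), "3dof")
        assert rom.n_viable == 0

    def test_cone_boundary_within_one_step(self, cone_rig, cone_joint):
        *_, truth = cone_joint
        analytic = truth.clearance_cone_half_angle
        line = PoseGrid(fe_range=(0, 0), lar_range=(0, 0),
                        abad_range=(-90, 90), step=5.0)
        rom = classify_poses(cone_rig, line, "3dof")
        measured = rom.viable_poses[:, 0].max()
        assert abs(measured - analytic) <= 5.0
        # symmetric joint: same boundary on the negative side
        assert abs(-rom.viable_poses[:, 0].min() - analytic) <= 5.0

    def test_regime_offset_requirements(self, free_rig):
        with pytest.raises(ValueError, match="static_offset"):
            classify_poses(free_rig, PoseGrid(step=90.0), "4dof")
        with pytest.raises(ValueError, match="offset_sphere"):
            classify_poses(free_rig, PoseGrid(step=90.0), "6dof")

    def test_determinism(self, small_joint, world_acs):
        prox, dist, _ = small_joint
        rig = JointRig(proximal=prox, distal=dist, acs=world_acs)
        grid = PoseGrid(step=90.0)
        a = classify_poses(rig, grid, "3dof")
        b = classify_poses(rig, grid, "3dof")
        np.testing.assert_array_equal(a.viable_mask, b.viable_mask)
        np.testing.assert_array_equal(a.n_offsets_clear, b.n_offsets_clear)


class TestSixDof:
    def test_union_superset_of_any_static_offset(self, tight_rig):
        sphere = build_offset_sphere(2.448, 4, 2)
        grid = PoseGrid(step=90.0)
        rom6 = classify_poses(tight_rig, grid, "6dof", offset_sphere=sphere)
        for vi in [0, 3]:  # a pole and an equator vertex
            rom4 = classify_poses(tight_rig, grid, "4dof",
                                  static_offset=sphere.vertices[vi])
            assert rom4.viable_set() <= rom6.viable_set()

    def test_more_offsets_never_shrink_viability(self, tight_rig):
        sphere = build_offset_sphere(2.448, 4, 2)
        grid = PoseGrid(step=90.0)
        without = classify_poses(tight_rig, grid, "6dof", offset_sphere=sphere)
        with_center = classify_poses(tight_rig, grid, "6dof",
                                     offset_sphere=sphere,
                                     include_center=True)
        assert without.viable_set() <= with_center.viable_set()

    def test_per_pose_offsets_recorded(self, tight_rig):
        sphere = build_offset_sphere(2.448, 4, 2)
        grid = PoseGrid(fe_range=(0, 0), abad_range=(0, 0), lar_range=(0, 0),
                        step=5.0)
        rom = classify_poses(tight_rig, grid, "6dof", offset_sphere=sphere)
        if rom.n_viable:
            (idx,) = np.flatnonzero(rom.viable_mask)
            offsets = rom.per_pose_offsets[idx]
            assert len(offsets) == rom.n_offsets_clear[idx]
            assert all(0 <= oi < sphere.n_vertices for oi in offsets)


class TestRomMapIO:
    def test_csv_round_trip(self, small_joint, world_acs, tmp_path):
        prox, dist, _ = small_joint
        rig = JointRig(proximal=prox, distal=dist, acs=world_acs)
        rom = classify_poses(rig, PoseGrid(step=90.0), "3dof")
        path = rom.to_csv(tmp_path / "map.csv", provenance="test")
        from osteorom.sampling import ROMMap

        back = ROMMap.from_csv(path)
        assert back.grid == rom.grid
        np.testing.assert_array_equal(back.viable_mask, rom.viable_mask)
        np.testing.assert_allclose(back.poses, rom.poses)
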