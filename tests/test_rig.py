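"""ACS construction and pose application (rotation order pinned by oracle)."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from osteorom import ACS, FittedSphere, JointRig, Pose, apply_pose, build_acs
from osteorom.primitives import FittedCylinder
from osteorom.rig import pose_rotation_matrix, pose_vertices

from .conftest import icosphere


def _cyl(axis=(0, 0, 1.0)):
    axis = np.asarray(axis, float)
    return FittedCylinder(np.zeros(3), axis / np.linalg.norm(axis),
                          radius=5.0, length=50.0, rms_residual=0.0)


def _sph(center=(0.0, 0.0, 0.0)):
    return FittedSphere(np.asarray(center, float), 10.0, 0.0)


def euler_xyz_oracle(abad, fe, lar):
    """Independent homogeneous-matrix composition: Rz @ Ry @ Rx."""
    ca, sa = np.cos(np.radians(abad)), np.sin(np.radians(abad))
    cf, sf = np.cos(np.radians(fe)), np.sin(np.radians(fe))
    cl, sl = np.cos(np.radians(lar)), np.sin(np.radians(lar))
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cf, 0, sf], [0, 1, 0], [-sf, 0, cf]])
    rz = np.array([[cl, -sl, 0], [sl, cl, 0], [0, 0, 1]])
    return rz @ ry @ rx


class TestBuildACS:
    def test_forced_by_construction(self):
        acs = build_acs(_sph(), _sph(), _cyl((0, 0, -1)),
                        ground_normal=(0, 0, 1))
        np.testing.assert_allclose(acs.origin, 0.0)
        np.testing.assert_allclose(acs.z_axis, [0, 0, 1])

    def test_axes_orthonormal_right_handed(self):
        acs = build_acs(_sph((1, 2, 3)), _sph((1, 2, 3)), _cyl((0, 0, -1)),
                        ground_normal=(0, 0, 1))
        m = acs.matrix
        np.testing.assert_allclose(m.T @ m, np.eye(3), atol=1e-12)
        assert np.linalg.det(m) == pytest.approx(1.0)

    def test_equivariance_under_rotation(self):
        rot = Rotation.random(random_state=11).as_matrix()
        base = build_acs(_sph(), _sph(), _cyl((0, 0, -1)), (0, 0, 1))
        rotated = build_acs(
            _sph(), _sph(),
            FittedCylinder(np.zeros(3), rot @ [0, 0, -1.0], 5.0, 50.0, 0.0),
            ground_normal=rot @ [0, 0, 1.0],
            anterior_hint=rot @ [1.0, 0, 0],
        )
        np.testing.assert_allclose(rotated.matrix, rot @ base.matrix,
                                   atol=1e-9)

    def test_unsuperimposed_centres_rejected(self):
        with pytest.raises(ValueError, match="superimposed"):
            build_acs(_sph((0, 0, 0)), _sph((5, 0, 0)), _cyl((0, 0, -1)),
                      (0, 0, 1))

    def test_long_axis_not_neutral_rejected(self):
        with pytest.raises(ValueError, match="perpendicular to the ground"):
            build_acs(_sph(), _sph(), _cyl((1, 0, 0)), (0, 0, 1))

    def test_hint_parallel_to_normal_rejected(self):
        with pytest.raises(ValueError, match="unresolvable"):
            build_acs(_sph(), _sph(), _cyl((0, 0, -1)), (0, 0, 1),
                      anterior_hint=(0, 0, 1))


class TestApplyPose:
    @pytest.fixture
    def rig(self, world_acs):
        prox = icosphere(radius=1.0, subdivisions=0, center=(50, 50, 50))
        dist = icosphere(radius=3.0, subdivisions=1, center=(0, 0, -6))
        return JointRig(proximal=prox, distal=dist, acs=world_acs)

    def test_identity_pose(self, rig):
        out = apply_pose(rig, Pose())
        np.testing.assert_allclose(out.vertices, rig.distal.vertices,
                                   atol=1e-12)

    def test_single_axis_additivity(self, rig):
        once = apply_pose(apply_pose_rig(rig, Pose(fe=90.0)), Pose(fe=90.0))
        twice = apply_pose(rig, Pose(fe=180.0))
        np.testing.assert_allclose(once.vertices, twice.vertices, atol=1e-9)

    def test_rotation_order_pinned_against_oracle(self, rig):
        rng = np.random.default_rng(3)
        for _ in range(200):
            abad, fe, lar = rng.uniform(-180, 180, 3)
            np.testing.assert_allclose(
                pose_rotation_matrix(abad, fe, lar),
                euler_xyz_oracle(abad, fe, lar), atol=1e-12)
        # composition order matters: a different order disagrees
        m = pose_rotation_matrix(90.0, 45.0, 60.0)
        other = euler_xyz_oracle(90.0, 45.0, 60.0).T
        assert not np.allclose(m, other, atol=1e-6)

    def test_full_pose_against_matrix_oracle(self, rig):
        rng = np.random.default_rng(3)
        v = rig.distal.vertices
        o = rig.acs.origin
        for _ in range(50):
            abad, fe, lar = rng.uniform(-180, 180, 3)
            t = rng.normal(size=3)
            expected = (v - o) @ euler_xyz_oracle(abad, fe, lar).T + o + t
            got = pose_vertices(rig, Pose(abad, fe, lar, offset=t))
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_pose_is_rigid_motion(self, rig):
        rng = np.random.default_rng(12)
        out = apply_pose(rig, Pose(33.0, -71.0, 140.0, offset=[1, -2, 0.5]))
        idx = rng.integers(0, rig.distal.n_vertices, size=(100, 2))
        d0 = np.linalg.norm(
            rig.distal.vertices[idx[:, 0]] - rig.distal.vertices[idx[:, 1]],
            axis=1)
        d1 = np.linalg.norm(
            out.vertices[idx[:, 0]] - out.vertices[idx[:, 1]], axis=1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_offset_fixed_in_proximal_frame(self, rig):
        # the offset must not rotate with the pose: the same translation in
        # ACS axes is added whatever the rotation
        t = np.array([0.0, 2.5, 0.0])
        rotated = pose_vertices(rig, Pose(abad=90.0))
        shifted = pose_vertices(rig, Pose(abad=90.0, offset=t))
        np.testing.assert_allclose(shifted - rotated,
                                   np.broadcast_to(t, shifted.shape),
                                   atol=1e-12)

    def test_acs_axes_respected(self):
        # with a rotated ACS, a pure abad rotation acts about the ACS x axis
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        acs = ACS(origin=np.zeros(3), x_axis=rot[:, 0], y_axis=rot[:, 1],
                  z_axis=rot[:, 2])
        dist = icosphere(radius=1.0, subdivisions=0, center=(0, 0, -4))
        rig = JointRig(proximal=icosphere(center=(99, 99, 99)), distal=dist,
                       acs=acs)
        out = pose_vertices(rig, Pose(abad=90.0))
        # ACS x is world y: rotating +90 about world y maps -z to -x
        expected = dist.vertices @ Rotation.from_rotvec(
            [0, np.pi / 2, 0]).as_matrix().T
        np.testing.assert_allclose(out, expected, atol=1e-9)


def apply_pose_rig(rig, pose):
    """Re-rig with the posed distal mesh (for composition tests)."""
    return JointRig(proximal=rig.proximal, distal=apply_pose(rig, pose),
                    acs=rig.acs)


class TestRigSerialization:
    def test_yaml_round_trip(self, tmp_path, world_acs):
        prox = icosphere(center=(9, 9, 9))
        dist = icosphere(center=(0, 0, -5))
        rig = JointRig(proximal=prox, distal=dist, acs=world_acs)
        path = rig.to_yaml(tmp_path / "rig.yaml")
        back = JointRig.from_yaml(path, proximal=prox, distal=dist)
        np.testing.assert_allclose(back.acs.matrix, rig.acs.matrix)
        np.testing.assert_allclose(back.neutral_transform.matrix,
                                   rig.neutral_transform.matrix)
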