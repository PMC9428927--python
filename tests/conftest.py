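import numpy as np
import pytest
import trimesh

from osteorom import (ACS, JointRig, SyntheticJointSpec, TriMesh,
                      make_socket_joint)


@pytest.fixture(scope="session")
def world_acs() -> ACS:
    return ACS(origin=np.zeros(3), x_axis=np.array([1.0, 0, 0]),
               y_axis=np.array([0, 1.0, 0]), z_axis=np.array([0, 0, 1.0]))


@pytest.fixture(scope="session")
def cone_joint():
    """Axially symmetric joint with a closed-form clearance cone (res 1000)."""
    spec = SyntheticJointSpec(mesh_resolution=1000)
    prox, dist, truth = make_socket_joint(spec)
    return prox, dist, truth


@pytest.fixture(scope="session")
def cone_rig(cone_joint, world_acs) -> JointRig:
    prox, dist, _ = cone_joint
    return JointRig(proximal=prox, distal=dist, acs=world_acs)


@pytest.fixture(scope="session")
def small_joint():
    """Coarse joint for collision-heavy tests (a few hundred triangles)."""
    spec = SyntheticJointSpec(mesh_resolution=150)
    prox, dist, truth = make_socket_joint(spec)
    return prox, dist, truth


@pytest.fixture
def tetrahedron() -> TriMesh:
    v = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriMesh(v, f, "tetra")


def icosphere(radius=1.0, subdivisions=1, center=(0.0, 0.0, 0.0)) -> TriMesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(np.asarray(m.vertices) + np.asarray(center),
                   np.asarray(m.faces), "icosphere")
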