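"""Anatomical coordinate system (ACS), neutral pose, and pose application.

The ACS is a right-handed orthonormal frame at the joint centre. Axis
semantics follow the hip convention used throughout: X is abduction (+) /
adduction (-), Y is flexion (+) / extension (-), Z is long-axis rotation
(external +, internal -), with the femur extending toward the ground in
neutral so that Z is perpendicular to the ground.

Rotation composition uses the Maya-style "XYZ" rotate order: X is applied
first, i.e. the composed matrix is ``R = Rz(lar) @ Ry(fe) @ Rx(abad)``,
expressed in ACS axes that stay fixed in the proximal (pelvis) frame. The
pose grid downstream is defined on these fixed-axis angle triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform, TriMesh, transform_mesh
from .primitives import FittedCylinder, FittedSphere

__all__ = ["ACS", "Pose", "JointRig", "build_acs", "apply_pose", "pose_rotation_matrix"]

_ORTHO_TOL = 1e-9


@dataclass
class ACS:
    """Joint-centred anatomical frame (origin mm, orthonormal axes)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    rotation_order: str = "XYZ"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.x_axis = np.asarray(self.x_axis, dtype=np.float64).reshape(3)
        self.y_axis = np.asarray(self.y_axis, dtype=np.float64).reshape(3)
        self.z_axis = np.asarray(self.z_axis, dtype=np.float64).reshape(3)
        m = self.matrix
        if np.abs(m.T @ m - np.eye(3)).max() > 1e-8:
            raise ValueError("ACS axes are not orthonormal")
        if not np.allclose(np.cross(self.x_axis, self.y_axis), self.z_axis, atol=1e-8):
            raise ValueError("ACS is not right-handed (x cross y must equal z)")
        if self.rotation_order != "XYZ":
            raise ValueError("only the XYZ rotation order is supported")

    @property
    def matrix(self) -> np.ndarray:
        """Columns are the x, y, z axes (ACS -> world rotation)."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def to_dict(self) -> dict:
        return {"origin": self.origin.tolist(), "x_axis": self.x_axis.tolist(),
                "y_axis": self.y_axis.tolist(), "z_axis": self.z_axis.tolist(),
                "rotation_order": self.rotation_order}

    @classmethod
    def from_dict(cls, d: dict) -> "ACS":
        return cls(np.asarray(d["origin"]), np.asarray(d["x_axis"]),
                   np.asarray(d["y_axis"]), np.asarray(d["z_axis"]),
                   d.get("rotation_order", "XYZ"))


@dataclass
class Pose:
    """One joint configuration: rotations in degrees, offset in mm (ACS axes)."""

    abad: float = 0.0   # about X
    fe: float = 0.0     # about Y
    lar: float = 0.0    # about Z
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite([self.abad, self.fe, self.lar])):
            raise ValueError("pose angles must be finite")


def pose_rotation_matrix(abad: float, fe: float, lar: float) -> np.ndarray:
    """``Rz(lar) @ Ry(fe) @ Rx(abad)`` in degrees (X applied first)."""
    return Rotation.from_euler("xyz", [abad, fe, lar], degrees=True).as_matrix()


@dataclass
class JointRig:
    """Two articulated meshes plus the frame all poses are expressed in.

    ``neutral_transform`` maps the distal mesh from its stored coordinates
    into the neutral (0, 0, 0) posture; it is the identity when the distal
    mesh is supplied already neutral.
    """

    proximal: TriMesh
    distal: TriMesh
    acs: ACS
    neutral_transform: RigidTransform = field(default_factory=RigidTransform.identity)

    def distal_neutral(self) -> TriMesh:
        return transform_mesh(self.distal, self.neutral_transform)

    def to_yaml(self, path: str | Path,
                proximal_path: str | None = None,
                distal_path: str | None = None) -> Path:
        payload = {
            "acs": self.acs.to_dict(),
            "neutral_rotation": self.neutral_transform.rotation.tolist(),
            "neutral_translation": self.neutral_transform.translation.tolist(),
            "proximal_mesh": proximal_path,
            "distal_mesh": distal_path,
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path,
                  proximal: TriMesh | None = None,
                  distal: TriMesh | None = None) -> "JointRig":
        from .geometry import load_mesh

        d = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        if proximal is None:
            if not d.get("proximal_mesh"):
                raise ValueError("rig file names no proximal mesh and none was given")
            proximal = load_mesh(base / d["proximal_mesh"])
        if distal is None:
            if not d.get("distal_mesh"):
                raise ValueError("rig file names no distal mesh and none was given")
            distal = load_mesh(base / d["distal_mesh"])
        return cls(
            proximal=proximal,
            distal=distal,
            acs=ACS.from_dict(d["acs"]),
            neutral_transform=RigidTransform(
                np.asarray(d["neutral_rotation"]),
                np.asarray(d["neutral_translation"]),
            ),
        )


def _unit(v, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64).reshape(3)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"{what} has zero length")
    return v / n


def build_acs(acetabulum: FittedSphere, head: FittedSphere,
              long_axis: FittedCylinder, ground_normal,
              anterior_hint=(1.0, 0.0, 0.0),
              center_tol: float = 1.0,
              alignment_tol_deg: float = 15.0) -> ACS:
    """Construct the hip ACS from fitted primitives in the neutral posture.

    The origin is the superimposed sphere centre. ``z_axis`` is the ground
    normal (the femoral long axis must already point along -z within
    *alignment_tol_deg* — i.e. the rig is in neutral, femur toward the
    ground). The ABAD (x) axis is the anterior reference direction
    projected orthogonal to z; flexion (y) completes the right-handed frame.
    """
    if np.linalg.norm(acetabulum.center - head.center) > center_tol:
        raise ValueError(
            "acetabulum and head sphere centres are not superimposed; "
            "rearticulate before building the ACS"
        )
    z = _unit(ground_normal, "ground normal")
    axis = _unit(long_axis.axis_direction, "long axis")
    cosang = abs(float(axis @ z))
    if cosang < np.cos(np.radians(alignment_tol_deg)):
        raise ValueError(
            "long axis is not perpendicular to the ground: set up the neutral "
            "posture (femur toward the ground) before building the ACS"
        )
    hint = np.asarray(anterior_hint, dtype=np.float64).reshape(3)
    x = hint - (hint @ z) * z
    if np.linalg.norm(x) < 1e-9:
        raise ValueError("anterior hint is parallel to the ground normal; "
                         "the ABAD axis is unresolvable")
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    origin = 0.5 * (acetabulum.center + head.center)
    return ACS(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def apply_pose(rig: JointRig, pose: Pose) -> TriMesh:
    """Pose the distal mesh: ``v' = R (v - o) + o + t``.

    The rotation R (composed in the fixed XYZ order) acts about the joint
    centre ``o``; the translational offset ``t`` (ACS axes) stays fixed in
    the proximal frame, as a Maya-style transform applies it. Rotating the
    pre-translated mesh about the displaced centre ``o + t`` — the 6-DOF
    "ACS moved to the offset-sphere vertex" picture — gives the identical
    map, so one formula serves every sampling regime.
    """
    verts = pose_vertices(rig, pose)
    neutral = rig.distal_neutral()
    return TriMesh(verts, neutral.faces.copy(), neutral.name)


def pose_vertices(rig: JointRig, pose: Pose) -> np.ndarray:
    """Vertex-array form of :func:`apply_pose` (the sampling hot path)."""
    a = rig.acs.matrix
    r_world = a @ pose_rotation_matrix(pose.abad, pose.fe, pose.lar) @ a.T
    t_world = a @ pose.offset
    origin = rig.acs.origin
    v = rig.neutral_transform.apply(rig.distal.vertices)
    return (v - origin) @ r_world.T + origin + t_world
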