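"""Primitive-shape fitting, rearticulation, and joint spacing.

Spheres are fitted to the acetabulum and femoral head, cylinders to long-
bone shafts/condyles; the fitted centres define the joint centre, and the
difference between socket and head radii defines the joint spacing used as
a proxy for maximum articular-cartilage thickness.

Sphere fitting is a Coope-style algebraic linear solve followed by
orthogonal-distance (geometric) refinement; cylinder fitting initializes
the axis by PCA and refines axis, radius and position jointly. Both report
the RMS orthogonal residual so a poor articular-surface selection is
visible downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .geometry import RigidTransform

__all__ = [
    "FittedSphere",
    "FittedCylinder",
    "JointSpacing",
    "fit_sphere",
    "fit_cylinder",
    "rearticulate",
    "joint_spacing_from_radii",
]


class FittingError(ValueError):
    """Raised when the input points cannot constrain the requested primitive."""


@dataclass
class FittedSphere:
    center: np.ndarray      # (3,) mm
    radius: float           # mm
    rms_residual: float     # mm

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms residual must be non-negative")

    def to_dict(self) -> dict:
        return {"type": "sphere", "center": self.center.tolist(),
                "radius": float(self.radius),
                "rms_residual": float(self.rms_residual)}

    @classmethod
    def from_dict(cls, d: dict) -> "FittedSphere":
        return cls(np.asarray(d["center"]), d["radius"], d["rms_residual"])


@dataclass
class FittedCylinder:
    axis_point: np.ndarray      # (3,) mm, a point on the axis
    axis_direction: np.ndarray  # unit vector, canonical sign (+Z component)
    radius: float               # mm
    length: float               # mm, extent of point projections on the axis
    rms_residual: float         # mm

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=np.float64).reshape(3)
        self.axis_direction = np.asarray(self.axis_direction, dtype=np.float64).reshape(3)
        if abs(np.linalg.norm(self.axis_direction) - 1.0) > 1e-9:
            raise ValueError("axis_direction must be a unit vector")
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("cylinder radius and length must be positive")

    def to_dict(self) -> dict:
        return {"type": "cylinder", "axis_point": self.axis_point.tolist(),
                "axis_direction": self.axis_direction.tolist(),
                "radius": float(self.radius), "length": float(self.length),
                "rms_residual": float(self.rms_residual)}

    @classmethod
    def from_dict(cls, d: dict) -> "FittedCylinder":
        return cls(np.asarray(d["axis_point"]), np.asarray(d["axis_direction"]),
                   d["radius"], d["length"], d["rms_residual"])


@dataclass
class JointSpacing:
    """The distance budget between articular surfaces (mm)."""

    value: float
    source: str = "radii_difference"   # or "configured"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("joint spacing must be non-negative")
        if self.source not in ("radii_difference", "configured"):
            raise ValueError(f"unknown spacing source {self.source!r}")


def _check_rank3(points: np.ndarray, what: str) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[-1] < 1e-9 * max(s[0], 1.0):
        raise FittingError(f"points are degenerate (coplanar/collinear) for {what} fit")


def fit_sphere(points: np.ndarray) -> FittedSphere:
    """Least-squares sphere through a point cloud.

    Algebraic (Coope) linear solve, then orthogonal-distance refinement of
    centre and radius. Requires >= 4 non-coplanar points.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(points) < 4:
        raise FittingError("sphere fit needs at least 4 points")
    _check_rank3(points, "sphere")
    # |p|^2 = 2 p.c + (r^2 - |c|^2): linear in (c, k)
    a = np.column_stack([2.0 * points, np.ones(len(points))])
    b = np.einsum("ij,ij->i", points, points)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center0 = sol[:3]
    r2 = sol[3] + center0 @ center0
    if r2 <= 0:
        raise FittingError("algebraic sphere fit produced non-positive radius")
    radius0 = float(np.sqrt(r2))

    def resid(x):
        return np.linalg.norm(points - x[:3], axis=1) - x[3]

    res = least_squares(resid, np.r_[center0, radius0], method="lm")
    center, radius = res.x[:3], float(res.x[3])
    if radius <= 0:
        raise FittingError("sphere refinement collapsed to non-positive radius")
    rms = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    return FittedSphere(center, radius, rms)


def _canonical_direction(d: np.ndarray) -> np.ndarray:
    """Resolve the +/- axis ambiguity: positive Z, then Y, then X component."""
    for i in (2, 1, 0):
        if abs(d[i]) > 1e-12:
            return d if d[i] > 0 else -d
    return d


def fit_cylinder(points: np.ndarray) -> FittedCylinder:
    """Least-squares infinite cylinder, PCA-initialized, then refined.

    The reported length is the extent of the point projections on the fitted
    axis; axis_point is the projection of the centroid onto the axis.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(points) < 6:
        raise FittingError("cylinder fit needs at least 6 points")
    centroid = points.mean(axis=0)
    centered = points - centroid
    u_svd, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise FittingError("points are collinear; cylinder is unconstrained")
    axis0 = vt[0]  # largest-variance direction

    def axis_from_angles(theta, phi):
        return np.array([
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(theta),
        ])

    theta0 = float(np.arccos(np.clip(axis0[2], -1, 1)))
    phi0 = float(np.arctan2(axis0[1], axis0[0]))

    def radial_dist(x):
        axis = axis_from_angles(x[0], x[1])
        p0 = centroid + np.array([x[2], x[3], x[4]])
        rel = points - p0
        along = rel @ axis
        return np.linalg.norm(rel - np.outer(along, axis), axis=1)

    r0 = float(np.median(radial_dist([theta0, phi0, 0, 0, 0])))
    if r0 <= 0:
        raise FittingError("degenerate cylinder initialization")

    def resid(x):
        return radial_dist(x) - x[5]

    res = least_squares(resid, np.r_[theta0, phi0, 0.0, 0.0, 0.0, r0], method="lm")
    axis = _canonical_direction(axis_from_angles(res.x[0], res.x[1]))
    p0 = centroid + res.x[2:5]
    radius = float(res.x[5])
    if radius <= 0:
        raise FittingError("cylinder refinement collapsed to non-positive radius")
    along = (points - p0) @ axis
    length = float(along.max() - along.min())
    if length <= 0:
        raise FittingError("cylinder has zero axial extent")
    axis_point = p0 + axis * float(along.mean())
    rms = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    return FittedCylinder(axis_point, axis, radius, length, rms)


def rearticulate(moving_sphere: FittedSphere,
                 fixed_sphere: FittedSphere) -> RigidTransform:
    """Pure translation superimposing the moving centre onto the fixed one.

    Orientation is left untouched — it is established by the anatomical
    coordinate system in the next setup step.
    """
    return RigidTransform.from_translation(fixed_sphere.center - moving_sphere.center)


def joint_spacing_from_radii(acetabulum: FittedSphere,
                             head: FittedSphere) -> JointSpacing:
    """Joint spacing = socket radius minus head radius.

    The difference of the two fitted radii is the standard proxy for joint
    spacing (maximum cartilage thickness) when no cartilage is preserved.
    """
    if head.radius > acetabulum.radius:
        raise ValueError(
            "femoral head radius exceeds acetabulum radius: non-physical articulation"
        )
    return JointSpacing(acetabulum.radius - head.radius, source="radii_difference")


def save_fit_report(shapes: dict[str, FittedSphere | FittedCylinder],
                    path: str | Path) -> Path:
    """Serialize named fitted shapes to a JSON report."""
    path = Path(path)
    payload = {name: s.to_dict() for name, s in shapes.items()}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def load_fit_report(path: str | Path) -> dict[str, FittedSphere | FittedCylinder]:
    data = json.loads(Path(path).read_text())
    out: dict[str, FittedSphere | FittedCylinder] = {}
    for name, d in data.items():
        if d.get("type") == "sphere":
            out[name] = FittedSphere.from_dict(d)
        elif d.get("type") == "cylinder":
            out[name] = FittedCylinder.from_dict(d)
        else:
            raise ValueError(f"unknown shape type in report entry {name!r}")
    return out
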