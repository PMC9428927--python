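"""Parametric ball-and-socket joint meshes and gait-like traces.

Every other module is testable without external data: this module builds a
hip-like joint with known ground truth — a spherical cup (acetabulum
analogue) truncated at a chosen coverage angle and thickened into a closed
shell with a backing plate, and a femur analogue made of a spherical head,
a cylindrical neck and a wider shaft extending along -Z in the neutral
posture. Default dimensions mimic a small hominin hip: head radius
17.552 mm and cup radius 20.0 mm, i.e. a 2.448 mm radii difference, with a
289 mm femoral length available for the thickness-scaling arithmetic.

For the ideal (noise-free) geometry the rotational clearance is a closed
form: with the cup rim at polar angle ``coverage`` from the +Z pole and the
neck a cylinder of radius ``r_n`` through the joint centre, the femur can
tilt away from -Z by at most ``180 - coverage - asin(r_n / r_cup)``
degrees before the neck hits the inner rim. This cone half-angle is the
analytic oracle for the collision-based ROM boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import TriMesh, VertexMask, concatenate
from .mocap import JointAngleTrace

__all__ = ["SyntheticJointSpec", "SyntheticJointTruth", "make_socket_joint",
           "make_gait_trace"]


@dataclass
class SyntheticJointSpec:
    """Parameters of the synthetic hip-like joint (lengths mm, angles deg)."""

    head_radius: float = 17.552
    cup_radius: float = 20.0
    cup_coverage: float = 120.0      # polar angle of the cup rim from the pole
    neck_length: float = 40.0
    neck_radius: float = 8.0
    shaft_length: float = 120.0
    shaft_radius: float = 12.0
    shell_thickness: float = 2.0
    cup_axis: tuple = (0.0, 0.0, 1.0)   # direction of the cup pole
    femur_length: float = 289.0      # scale reference for thickness scaling
    mesh_resolution: int = 2000      # target vertex count per articular surface
    noise_sd: float = 0.0            # mm, Gaussian displacement along normals
    seed: int = 0
    with_plate: bool = True

    def __post_init__(self) -> None:
        if self.cup_radius < self.head_radius:
            raise ValueError("cup radius must be >= head radius")
        if not 0.0 < self.cup_coverage < 180.0:
            raise ValueError("cup coverage must lie strictly between 0 and 180 deg")
        for name in ("head_radius", "cup_radius", "neck_length", "neck_radius",
                     "shaft_length", "shaft_radius", "shell_thickness",
                     "femur_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mesh_resolution < 50:
            raise ValueError("mesh_resolution must be at least 50")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def spacing(self) -> float:
        return self.cup_radius - self.head_radius

    @property
    def clearance_cone_half_angle(self) -> float | None:
        """Analytic max tilt (deg) of the femur from -Z before neck-rim contact.

        Closed form only for the axially symmetric joint (cup pole +Z);
        ``None`` for a tilted cup.
        """
        axis = np.asarray(self.cup_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        if not np.allclose(axis, [0.0, 0.0, 1.0]):
            return None
        return 180.0 - self.cup_coverage - np.degrees(
            np.arcsin(min(1.0, self.neck_radius / self.cup_radius))
        )


@dataclass
class SyntheticJointTruth:
    """Ground truth emitted alongside the generated meshes."""

    head_center: np.ndarray
    head_radius: float
    cup_center: np.ndarray
    cup_radius: float
    spacing: float
    clearance_cone_half_angle: float
    head_mask: VertexMask
    cup_mask: VertexMask
    spec: SyntheticJointSpec = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "head_center": np.asarray(self.head_center).tolist(),
            "head_radius": self.head_radius,
            "cup_center": np.asarray(self.cup_center).tolist(),
            "cup_radius": self.cup_radius,
            "spacing": self.spacing,
            "clearance_cone_half_angle": self.clearance_cone_half_angle,
        }


def _rotation_to(axis: np.ndarray) -> tuple[np.ndarray, float]:
    """Rotation matrix mapping +Z onto *axis* (already unit length)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(z @ axis)
    if np.linalg.norm(v) < 1e-12:
        return (np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])), c
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    return rot, c


def _icosphere_subdivisions(target_vertices: int) -> int:
    # icosphere vertex counts are 10 * 4^n + 2; pick the closest
    best, best_err = 0, float("inf")
    for n in range(7):
        err = abs(np.log((10 * 4**n + 2) / target_vertices))
        if err < best_err:
            best, best_err = n, err
    return best


def _spherical_shell(r_in: float, r_out: float, coverage_deg: float,
                     n_theta: int, n_phi: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed shell between two spherical caps, rim annulus at the coverage.

    Returns (vertices, faces, inner_surface_indices). The pole is +Z.
    """
    cov = np.radians(coverage_deg)
    verts: list[np.ndarray] = []
    inner_rings: list[list[int]] = []
    outer_rings: list[list[int]] = []

    def add_cap(radius: float, rings: list[list[int]]) -> int:
        pole = len(verts)
        verts.append(np.array([0.0, 0.0, radius]))
        for k in range(1, n_theta + 1):
            theta = cov * k / n_theta
            ring = []
            for j in range(n_phi):
                phi = 2 * np.pi * j / n_phi
                ring.append(len(verts))
                verts.append(radius * np.array([
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    np.cos(theta),
                ]))
            rings.append(ring)
        return pole

    inner_pole = add_cap(r_in, inner_rings)
    n_inner = len(verts)
    outer_pole = add_cap(r_out, outer_rings)

    faces: list[tuple[int, int, int]] = []

    def cap_faces(pole: int, rings: list[list[int]], flip: bool) -> None:
        for j in range(n_phi):
            a, b = rings[0][j], rings[0][(j + 1) % n_phi]
            faces.append((pole, b, a) if flip else (pole, a, b))
        for k in range(n_theta - 1):
            top, bot = rings[k], rings[k + 1]
            for j in range(n_phi):
                jj = (j + 1) % n_phi
                if flip:
                    faces.append((top[j], bot[jj], bot[j]))
                    faces.append((top[j], top[jj], bot[jj]))
                else:
                    faces.append((top[j], bot[j], bot[jj]))
                    faces.append((top[j], bot[jj], top[jj]))

    # inner surface normals point toward the centre (into the socket cavity)
    cap_faces(inner_pole, inner_rings, flip=True)
    cap_faces(outer_pole, outer_rings, flip=False)
    rim_in, rim_out = inner_rings[-1], outer_rings[-1]
    for j in range(n_phi):
        jj = (j + 1) % n_phi
        faces.append((rim_in[j], rim_out[j], rim_out[jj]))
        faces.append((rim_in[j], rim_out[jj], rim_in[jj]))

    inner_idx = np.arange(n_inner)
    return np.array(verts), np.array(faces, dtype=np.int64), inner_idx


def make_socket_joint(spec: SyntheticJointSpec,
                      distal_offset=(0.0, 0.0, 0.0),
                      ) -> tuple[TriMesh, TriMesh, SyntheticJointTruth]:
    """Build the (proximal, distal) mesh pair plus its ground-truth record.

    The joint is emitted articulated and concentric at the origin; a
    non-zero *distal_offset* displaces the distal element (e.g. to exercise
    rearticulation). Surface noise, when requested, displaces vertices
    along their normals with a seeded generator; the truth record keeps the
    noise-free parameters.
    """
    rng = np.random.default_rng(spec.seed)

    # -- distal: head + neck + shaft along -Z ----------------------------
    head_tm = trimesh.creation.icosphere(
        subdivisions=_icosphere_subdivisions(spec.mesh_resolution),
        radius=spec.head_radius,
    )
    neck_end = spec.head_radius + spec.neck_length
    sections = max(24, int(np.sqrt(spec.mesh_resolution)))
    neck_tm = trimesh.creation.cylinder(
        radius=spec.neck_radius, sections=sections,
        segment=[[0, 0, 0], [0, 0, -neck_end]],
    )
    # the shaft starts 1 mm up inside the neck span so that no two cap-fan
    # centre vertices coincide (coincident vertices would weld on export)
    shaft_tm = trimesh.creation.cylinder(
        radius=spec.shaft_radius, sections=sections,
        segment=[[0, 0, -(neck_end - 1.0)],
                 [0, 0, -(neck_end + spec.shaft_length)]],
    )
    # keep triangle sizes uniform across the whole element (as in scanned
    # bone meshes): split the cylinders' long side triangles down to the
    # head's edge length so no sliver dominates collision broad-phase boxes
    head_edges = np.asarray(head_tm.vertices)[np.asarray(head_tm.edges_unique)]
    max_edge = 3.0 * float(np.median(
        np.linalg.norm(head_edges[:, 0] - head_edges[:, 1], axis=1)))

    def _uniform(tm: trimesh.Trimesh, label: str) -> TriMesh:
        v, f = trimesh.remesh.subdivide_to_size(
            np.asarray(tm.vertices), np.asarray(tm.faces), max_edge)
        m = trimesh.Trimesh(v, f, process=True)
        return TriMesh(np.asarray(m.vertices), np.asarray(m.faces), label)

    head = TriMesh(np.asarray(head_tm.vertices), np.asarray(head_tm.faces), "head")
    neck = _uniform(neck_tm, "neck")
    shaft = _uniform(shaft_tm, "shaft")
    distal = concatenate([head, neck, shaft], name="synthetic_femur")
    head_mask = VertexMask("synthetic_femur", np.arange(head.n_vertices))

    # -- proximal: cup shell (+ backing plate) ---------------------------
    n_phi = max(12, int(round(np.sqrt(spec.mesh_resolution * 2))))
    n_theta = max(4, int(round(spec.mesh_resolution / n_phi)))
    cup_v, cup_f, inner_idx = _spherical_shell(
        spec.cup_radius, spec.cup_radius + spec.shell_thickness,
        spec.cup_coverage, n_theta, n_phi,
    )
    axis = np.asarray(spec.cup_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if not np.allclose(axis, [0.0, 0.0, 1.0]):
        # rotate the shell so its pole points along cup_axis
        rot, _ = _rotation_to(axis)
        cup_v = cup_v @ rot.T
    cup_tm = trimesh.Trimesh(cup_v, cup_f, process=False)
    trimesh.repair.fix_normals(cup_tm)
    cup = TriMesh(np.asarray(cup_tm.vertices), np.asarray(cup_tm.faces),
                  "synthetic_pelvis")
    parts = [cup]
    if spec.with_plate:
        r_out = spec.cup_radius + spec.shell_thickness
        plate_tm = trimesh.creation.box(
            extents=[3 * spec.cup_radius, 3 * spec.cup_radius, 2.0])
        plate_tm.apply_translation([0, 0, r_out + 2.0])
        if not np.allclose(axis, [0.0, 0.0, 1.0]):
            rot, _ = _rotation_to(axis)
            plate_tm.apply_transform(
                np.vstack([np.column_stack([rot, np.zeros(3)]), [0, 0, 0, 1]]))
        parts.append(TriMesh(np.asarray(plate_tm.vertices),
                             np.asarray(plate_tm.faces), "plate"))
    proximal = concatenate(parts, name="synthetic_pelvis")
    cup_mask = VertexMask("synthetic_pelvis", inner_idx)

    if spec.noise_sd > 0:
        for mesh in (proximal, distal):
            tm = mesh.as_trimesh()
            normals = np.asarray(tm.vertex_normals)
            mesh.vertices += normals * rng.normal(
                0.0, spec.noise_sd, size=(mesh.n_vertices, 1))

    offset = np.asarray(distal_offset, dtype=np.float64).reshape(3)
    if np.any(offset != 0):
        distal = TriMesh(distal.vertices + offset, distal.faces, distal.name)

    truth = SyntheticJointTruth(
        head_center=offset.copy(),
        head_radius=spec.head_radius,
        cup_center=np.zeros(3),
        cup_radius=spec.cup_radius,
        spacing=spec.spacing,
        clearance_cone_half_angle=spec.clearance_cone_half_angle,
        head_mask=head_mask,
        cup_mask=cup_mask,
        spec=spec,
    )
    return proximal, distal, truth


def make_gait_trace(amplitudes=(40.0, 10.0, 8.0), n_frames: int = 200,
                    seed: int = 0, duration: float = 2.0,
                    cadence_hz: float = 1.0, jitter_sd: float = 0.25,
                    condition: str = "synthetic") -> JointAngleTrace:
    """Smooth sinusoidal hip-angle trace with bounded Gaussian jitter.

    *amplitudes* are the per-axis (fe, abad, lar) half-ranges in degrees.
    Jitter is clipped at three standard deviations so the trace stays
    within ``amplitude + 3 * jitter_sd`` on every axis; identical seeds
    give identical traces.
    """
    if n_frames < 2:
        raise ValueError("a trace needs at least 2 frames")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_frames)
    w = 2 * np.pi * cadence_hz
    a_fe, a_abad, a_lar = amplitudes

    def jitter():
        if jitter_sd <= 0:
            return 0.0
        return np.clip(rng.normal(0.0, jitter_sd, n_frames),
                       -3 * jitter_sd, 3 * jitter_sd)

    fe = a_fe * np.sin(w * t) + jitter()
    abad = a_abad * np.sin(w * t + np.pi / 3) + jitter()
    lar = a_lar * np.sin(w * t + 2 * np.pi / 3) + jitter()
    return JointAngleTrace(times=t, fe=fe, abad=abad, lar=lar,
                           condition=condition)
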