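"""Pose grids, offset spheres, and viable-pose classification.

A pose grid is the Cartesian product of inclusive Euler-angle ranges at a
fixed step (default 5 degrees: FE and LAR span -180..180, ABAD -90..90,
giving 73 * 37 * 73 = 197,173 poses). Each grid pose is tested for bone-
mesh interpenetration; non-viable poses are discarded.

Three regimes are supported:

* ``3dof``  — rotations only, tested at zero translational offset;
* ``4dof``  — rotations plus one static translational offset (joint-spacing
  sweeps translate along the ACS Y axis);
* ``6dof``  — rotations plus dynamic translation: the rotation centre visits
  every vertex of a coarse UV "offset sphere" whose radius equals the
  fitted-radii difference, and a pose is viable iff it clears collision at
  at least one vertex (union semantics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .collision import CollisionChecker
from .geometry import TriMesh  # noqa: F401 (re-exported container)
from .rig import JointRig, Pose, pose_vertices

__all__ = [
    "PoseGrid",
    "OffsetSphere",
    "ROMMap",
    "generate_grid",
    "build_offset_sphere",
    "classify_poses",
]

REGIMES = ("3dof", "4dof", "6dof")


@dataclass
class PoseGrid:
    """Inclusive Euler-angle ranges (degrees) sampled at a fixed step."""

    fe_range: tuple[float, float] = (-180.0, 180.0)
    abad_range: tuple[float, float] = (-90.0, 90.0)
    lar_range: tuple[float, float] = (-180.0, 180.0)
    step: float = 5.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        self.step = float(self.step)
        for name in ("fe_range", "abad_range", "lar_range"):
            lo, hi = getattr(self, name)
            setattr(self, name, (float(lo), float(hi)))
            if lo > hi:
                raise ValueError(f"{name}: min exceeds max")
            n = (hi - lo) / self.step
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name} span is not divisible by step {self.step}")

    def axis_values(self, name: str) -> np.ndarray:
        lo, hi = getattr(self, f"{name}_range")
        n = int(round((hi - lo) / self.step))
        return lo + self.step * np.arange(n + 1)

    @property
    def shape(self) -> tuple[int, int, int]:
        """(n_abad, n_fe, n_lar)."""
        return tuple(
            len(self.axis_values(a)) for a in ("abad", "fe", "lar")
        )

    @property
    def size(self) -> int:
        na, nf, nl = self.shape
        return na * nf * nl

    def to_dict(self) -> dict:
        return {"fe_range": list(self.fe_range), "abad_range": list(self.abad_range),
                "lar_range": list(self.lar_range), "step": self.step}

    @classmethod
    def from_dict(cls, d: dict) -> "PoseGrid":
        return cls(tuple(d["fe_range"]), tuple(d["abad_range"]),
                   tuple(d["lar_range"]), d["step"])


def generate_grid(grid: PoseGrid) -> np.ndarray:
    """Ordered (N, 3) array of (abad, fe, lar) triples.

    Iteration order is fixed — abad outermost, fe middle, lar innermost —
    so downstream per-pose records are reproducible.
    """
    abad = grid.axis_values("abad")
    fe = grid.axis_values("fe")
    lar = grid.axis_values("lar")
    a, f, l = np.meshgrid(abad, fe, lar, indexing="ij")
    return np.column_stack([a.ravel(), f.ravel(), l.ravel()])


@dataclass
class OffsetSphere:
    """Coarse UV-sphere lattice of translational offsets.

    At the default 8 axis divisions (longitude) and 4 height divisions
    (latitude bands) the lattice has 8 * 3 + 2 = 26 vertices and 32 faces
    (two triangle-fan caps plus quad bands, quads counted singly).
    """

    radius: float
    axis_divisions: int = 8
    height_divisions: int = 4
    vertices: np.ndarray = field(init=False)
    faces: list = field(init=False)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("offset sphere radius must be positive")
        if self.axis_divisions < 3 or self.height_divisions < 2:
            raise ValueError("need axis divisions >= 3 and height divisions >= 2")
        a, h, r = self.axis_divisions, self.height_divisions, self.radius
        verts = [np.array([0.0, 0.0, r])]
        rings = []
        for k in range(1, h):
            theta = np.pi * k / h
            ring = []
            for j in range(a):
                phi = 2 * np.pi * j / a
                ring.append(len(verts))
                verts.append(r * np.array([
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    np.cos(theta),
                ]))
            rings.append(ring)
        south = len(verts)
        verts.append(np.array([0.0, 0.0, -r]))
        faces: list = []
        for j in range(a):  # north cap
            faces.append((0, rings[0][j], rings[0][(j + 1) % a]))
        for k in range(h - 2):  # quad bands
            top, bot = rings[k], rings[k + 1]
            for j in range(a):
                faces.append((top[j], bot[j], bot[(j + 1) % a], top[(j + 1) % a]))
        for j in range(a):  # south cap
            faces.append((south, rings[-1][(j + 1) % a], rings[-1][j]))
        self.vertices = np.array(verts)
        self.faces = faces

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


def build_offset_sphere(radius: float, axis_divisions: int = 8,
                        height_divisions: int = 4) -> OffsetSphere:
    """UV-sphere offset lattice (see :class:`OffsetSphere`)."""
    return OffsetSphere(radius, axis_divisions, height_divisions)


@dataclass
class ROMMap:
    """Viability of every grid pose under one sampling regime."""

    grid: PoseGrid
    regime: str
    poses: np.ndarray            # (N, 3) abad, fe, lar — generate_grid order
    viable_mask: np.ndarray      # (N,) bool
    n_offsets_clear: np.ndarray  # (N,) int
    static_offset: np.ndarray | None = None
    offset_sphere: OffsetSphere | None = None
    per_pose_offsets: dict[int, tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if len(self.poses) != self.grid.size:
            raise ValueError("pose list does not match grid size")

    @property
    def n_viable(self) -> int:
        return int(self.viable_mask.sum())

    @property
    def viable_poses(self) -> np.ndarray:
        return self.poses[self.viable_mask]

    def viable_set(self) -> set[tuple[float, float, float]]:
        return {tuple(np.round(p, 9)) for p in self.viable_poses}

    # -- persistence ------------------------------------------------------

    def to_csv(self, path: str | Path, provenance: str = "") -> Path:
        path = Path(path)
        df = pd.DataFrame({
            "abad_deg": self.poses[:, 0],
            "fe_deg": self.poses[:, 1],
            "lar_deg": self.poses[:, 2],
            "viable": self.viable_mask.astype(int),
            "n_offsets_clear": self.n_offsets_clear,
        })
        header = f"# osteorom ROM map | regime={self.regime}"
        if provenance:
            header += f" | {provenance}"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            df.to_csv(fh, index=False)
        meta = {
            "regime": self.regime,
            "grid": self.grid.to_dict(),
            "static_offset": None if self.static_offset is None
            else np.asarray(self.static_offset).tolist(),
            "offset_sphere": None if self.offset_sphere is None else {
                "radius": self.offset_sphere.radius,
                "axis_divisions": self.offset_sphere.axis_divisions,
                "height_divisions": self.offset_sphere.height_divisions,
            },
            "n_viable": self.n_viable,
        }
        Path(str(path) + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ROMMap":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".meta.json").read_text())
        df = pd.read_csv(path, comment="#")
        grid = PoseGrid.from_dict(meta["grid"])
        sphere = None
        if meta.get("offset_sphere"):
            s = meta["offset_sphere"]
            sphere = OffsetSphere(s["radius"], s["axis_divisions"], s["height_divisions"])
        return cls(
            grid=grid,
            regime=meta["regime"],
            poses=df[["abad_deg", "fe_deg", "lar_deg"]].to_numpy(float),
            viable_mask=df["viable"].to_numpy(bool),
            n_offsets_clear=df["n_offsets_clear"].to_numpy(int),
            static_offset=None if meta.get("static_offset") is None
            else np.asarray(meta["static_offset"], dtype=float),
            offset_sphere=sphere,
        )


def auto_offset_direction(rig: JointRig, magnitude: float = 1.0) -> np.ndarray:
    """Pick the ACS Y sign that moves the distal element away from the socket.

    The sign chosen is the one that increases the minimum vertex-to-vertex
    distance between the meshes when the distal element is displaced along
    it from neutral.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(rig.proximal.vertices)
    gaps = []
    for sign in (1.0, -1.0):
        pose = Pose(offset=np.array([0.0, sign * magnitude, 0.0]))
        verts = pose_vertices(rig, pose)
        gaps.append(tree.query(verts)[0].min())
    return np.array([0.0, 1.0 if gaps[0] >= gaps[1] else -1.0, 0.0])


def classify_poses(rig: JointRig, grid: PoseGrid, regime: str = "3dof",
                   static_offset=None, offset_sphere: OffsetSphere | None = None,
                   include_center: bool = False, contact_tol: float = 0.0,
                   progress: bool = False) -> ROMMap:
    """Test every grid pose for interpenetration and build the ROM map.

    Classification is fully deterministic. In the 6-DOF regime a pose is
    viable iff it is collision-free at at least one offset-sphere vertex;
    ``per_pose_offsets`` records which vertices cleared. The sphere centre
    (zero offset) is not among the sampled offsets unless *include_center*.
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    if regime == "4dof" and static_offset is None:
        raise ValueError("4dof regime requires a static_offset")
    if regime == "6dof" and offset_sphere is None:
        raise ValueError("6dof regime requires an offset_sphere")

    if regime == "3dof":
        offsets = np.zeros((1, 3))
    elif regime == "4dof":
        offsets = np.asarray(static_offset, dtype=np.float64).reshape(1, 3)
    else:
        offsets = offset_sphere.vertices.copy()
        if include_center:
            offsets = np.vstack([np.zeros(3), offsets])

    poses = generate_grid(grid)
    checker = CollisionChecker(rig.proximal, tol=contact_tol)
    neutral = rig.distal_neutral()
    v0 = neutral.vertices - rig.acs.origin
    faces = neutral.faces
    distal_watertight = neutral.is_watertight()

    # radial-band cull: rotation about the pivot keeps every point of a
    # distal triangle in a fixed band of distances from the pivot (widened
    # by the largest translational offset), so triangles whose band cannot
    # overlap any fixed-mesh triangle's band never collide in any pose
    t_max = (np.linalg.norm(offsets, axis=1).max() if len(offsets) else 0.0)
    pad = t_max + contact_tol + 1e-9
    fx_tris = rig.proximal.triangles - rig.acs.origin
    fx_lo3, fx_hi3 = fx_tris.min(axis=1), fx_tris.max(axis=1)
    # conservative per-triangle radial interval via the AABB
    nearest = np.clip(0.0, fx_lo3, fx_hi3)
    fx_lb = np.linalg.norm(nearest, axis=1)
    fx_ub = np.linalg.norm(fx_tris, axis=2).max(axis=1)
    # merge fixed bands into a short union of disjoint intervals
    order = np.argsort(fx_lb)
    bands: list[list[float]] = []
    for lb, ub in zip(fx_lb[order], fx_ub[order]):
        if bands and lb <= bands[-1][1]:
            bands[-1][1] = max(bands[-1][1], ub)
        else:
            bands.append([float(lb), float(ub)])
    vert_dist = np.linalg.norm(v0, axis=1)
    tri_v = v0[faces]
    edge_len = np.linalg.norm(tri_v[:, [1, 2, 0]] - tri_v, axis=2).max(axis=1)
    mv_lb = np.maximum(vert_dist[faces].min(axis=1) - edge_len, 0.0) - pad
    mv_ub = vert_dist[faces].max(axis=1) + pad
    keep = np.zeros(len(faces), dtype=bool)
    for lb, ub in bands:
        keep |= (mv_lb <= ub) & (mv_ub >= lb)
    active_faces = faces[keep]
    if len(active_faces) == 0:
        active_faces = faces[:1]  # degenerate but keeps the API uniform
    a = rig.acs.matrix
    origin = rig.acs.origin
    t_world = offsets @ a.T  # offsets expressed in world coordinates

    from scipy.spatial.transform import Rotation

    # all pose rotations in one vectorized call: R = Rz(lar) Ry(fe) Rx(abad)
    r_all = Rotation.from_euler("xyz", poses, degrees=True).as_matrix()
    r_world_all = np.einsum("ij,njk,lk->nil", a, r_all, a)

    viable = np.zeros(len(poses), dtype=bool)
    n_clear = np.zeros(len(poses), dtype=np.int64)
    per_pose: dict[int, tuple[int, ...]] = {}

    iterator = range(len(poses))
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm  # type: ignore

        iterator = tqdm(iterator, total=len(poses))

    multi = regime == "6dof"
    for i in iterator:
        # v' = R (v - o) + o + t: rotate about the joint centre, then add
        # the proximal-frame offset (identical to rotating the translated
        # mesh about the displaced centre o + t)
        rotated = v0 @ r_world_all[i].T + origin
        clear = []
        for oi in range(len(offsets)):
            verts = rotated + t_world[oi]
            if not checker.intersects(verts, active_faces,
                                      moving_watertight=distal_watertight,
                                      containment_faces=faces):
                clear.append(oi)
        if clear:
            viable[i] = True
            n_clear[i] = len(clear)
            if multi:
                per_pose[i] = tuple(clear)

    return ROMMap(
        grid=grid,
        regime=regime,
        poses=poses,
        viable_mask=viable,
        n_offsets_clear=n_clear,
        static_offset=offsets[0].copy() if regime == "4dof" else None,
        offset_sphere=offset_sphere if regime == "6dof" else None,
        per_pose_offsets=per_pose if regime == "6dof" else None,
    )
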