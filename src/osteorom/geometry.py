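"""Triangle-mesh containers, rigid transforms, and mesh file I/O.

All lengths are millimetres and all angles degrees throughout the package;
no unit autodetection is attempted. Meshes are plain indexed triangle soups
(the substrate of every collision test downstream); file parsing and
serialization are delegated to :mod:`trimesh`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TriMesh",
    "VertexMask",
    "RigidTransform",
    "MeshValidationReport",
    "load_mesh",
    "save_mesh",
    "validate_mesh",
    "transform_mesh",
]

#: Vertex de-duplication tolerance on load (mm). STL repeats vertices per facet.
MERGE_TOL = 1e-8

_SUPPORTED_FORMATS = ("obj", "ply", "stl")


@dataclass
class TriMesh:
    """An indexed triangle surface mesh of a skeletal element.

    Parameters
    ----------
    vertices : (V, 3) float array, millimetres.
    faces : (F, 3) int array of vertex indices.
    name : free-form label used to tie vertex masks to meshes.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (V, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (F, 3) array of triangles")
        if len(self.faces) < 1:
            raise ValueError("mesh must contain at least one face")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh contains non-finite vertex coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    # -- derived geometry -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) axis-aligned min/max corner coordinates."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def face_areas(self) -> np.ndarray:
        tri = self.triangles
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def euler_characteristic(self) -> int:
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + self.n_faces

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), self.name)


@dataclass
class VertexMask:
    """A selection of vertex indices marking an articular surface."""

    mesh_name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.unique(np.asarray(self.indices, dtype=np.int64))
        if len(self.indices) == 0:
            raise ValueError("vertex mask may not be empty")
        if self.indices.min() < 0:
            raise ValueError("vertex mask indices must be non-negative")

    def select(self, mesh: TriMesh) -> np.ndarray:
        """Return the (k, 3) coordinates of the masked vertices of *mesh*."""
        if self.indices.max() >= mesh.n_vertices:
            raise ValueError(
                f"mask indices exceed vertex count of mesh {mesh.name!r}"
            )
        return mesh.vertices[self.indices]

    @classmethod
    def load(cls, path: str | Path, mesh_name: str = "") -> "VertexMask":
        """Read a plain-text mask: one 0-based integer index per line."""
        raw = Path(path).read_text().split()
        return cls(mesh_name=mesh_name, indices=np.array([int(t) for t in raw]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(str(i) for i in self.indices) + "\n")


@dataclass
class RigidTransform:
    """A proper rigid motion ``v' = R v + t`` (rotation + translation, mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    #: orthonormality tolerance for the rotation part
    TOL: float = 1e-8

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > self.TOL or abs(np.linalg.det(self.rotation) - 1.0) > self.TOL:
            raise ValueError("transform is not a proper rigid motion")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=np.float64))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying *other* first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 form."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class MeshValidationReport:
    name: str
    n_vertices: int
    n_faces: int
    watertight: bool
    n_degenerate_faces: int
    n_self_intersections: int | None
    euler_characteristic: int


def _normalize_format(path: str | Path, fmt: str | None) -> str:
    fmt = (fmt or Path(path).suffix.lstrip(".")).lower()
    if fmt not in _SUPPORTED_FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_SUPPORTED_FORMATS}")
    return fmt


def load_mesh(path: str | Path, format: str | None = None, name: str | None = None) -> TriMesh:
    """Load a triangle mesh from OBJ / PLY / STL.

    Units are taken as millimetres as-is. Duplicate vertices are merged
    (tolerance :data:`MERGE_TOL`); zero-area faces are dropped. Polygonal
    faces in OBJ files are fan-triangulated by the reader and a warning is
    emitted.
    """
    path = Path(path)
    fmt = _normalize_format(path, format)
    if not path.is_file():
        raise IOError(f"mesh file not found: {path}")
    if fmt == "obj":
        try:
            text = path.read_text(errors="replace")
            if any(
                line.startswith("f ") and len(line.split()) > 4
                for line in text.splitlines()
            ):
                warnings.warn(
                    f"{path.name}: non-triangular OBJ faces were fan-triangulated",
                    stacklevel=2,
                )
        except OSError:
            pass
    try:
        loaded = trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # pragma: no cover - parser specifics
        raise IOError(f"could not parse {path} as {fmt}: {exc}") from exc
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise ValueError(f"{path}: empty scene")
        loaded = trimesh.util.concatenate(geoms)
    loaded.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=8)
    verts = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if len(faces) == 0:
        raise ValueError(f"{path}: mesh has no faces")
    mesh = TriMesh(verts, faces, name=name if name is not None else path.stem)
    areas = mesh.face_areas()
    keep = areas > 1e-12
    if not np.all(keep):
        mesh = TriMesh(mesh.vertices, mesh.faces[keep], mesh.name)
    return mesh


def save_mesh(mesh: TriMesh, path: str | Path, format: str | None = None) -> Path:
    """Write *mesh* to OBJ / ASCII PLY / STL, inferring the format from the suffix."""
    path = Path(path)
    fmt = _normalize_format(path, format)
    tm = mesh.as_trimesh()
    if fmt == "ply":
        data = tm.export(file_type="ply", encoding="ascii")
    else:
        data = tm.export(file_type=fmt)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
    return path


def validate_mesh(mesh: TriMesh, check_self_intersections: bool = True,
                  max_faces_for_intersection: int = 20000) -> MeshValidationReport:
    """Report watertightness, degenerate faces and self-intersections.

    The input mesh is not modified. Self-intersection counting is an
    all-candidate-pairs triangle test (adjacency excluded) and is skipped,
    reported as ``None``, above *max_faces_for_intersection* faces.
    """
    from .collision import count_self_intersections

    areas = mesh.face_areas()
    n_degenerate = int(np.sum(areas <= 1e-12))
    n_self = None
    if check_self_intersections and mesh.n_faces <= max_faces_for_intersection:
        n_self = count_self_intersections(mesh)
    return MeshValidationReport(
        name=mesh.name,
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        watertight=mesh.is_watertight(),
        n_degenerate_faces=n_degenerate,
        n_self_intersections=n_self,
        euler_characteristic=mesh.euler_characteristic(),
    )


def transform_mesh(mesh: TriMesh, transform: RigidTransform) -> TriMesh:
    """Apply a rigid motion to every vertex; connectivity is unchanged."""
    if not isinstance(transform, RigidTransform):
        raise TypeError("transform must be a RigidTransform")
    return TriMesh(transform.apply(mesh.vertices), mesh.faces.copy(), mesh.name)


def concatenate(meshes: list[TriMesh], name: str = "") -> TriMesh:
    """Stack meshes into one without merging vertices (indices stay stable)."""
    offsets = np.cumsum([0] + [m.n_vertices for m in meshes[:-1]])
    verts = np.vstack([m.vertices for m in meshes])
    faces = np.vstack([m.faces + off for m, off in zip(meshes, offsets)])
    return TriMesh(verts, faces, name)
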