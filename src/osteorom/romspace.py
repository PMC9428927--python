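"""Cosine-corrected Euler shape space, alpha-shape volumes, map comparison.

Euler-angle coordinates distort near gimbal alignment: with the composition
``Rz(lar) @ Ry(fe) @ Rx(abad)``, the first-applied (abad) and last-applied
(lar) axes collapse onto one another as the middle angle (fe) approaches
+/-90 degrees. The default correction therefore scales the abad coordinate
by cos(fe), leaving fe and lar untouched; other axis pairings are
selectable for sensitivity checks.

The volume of a ROM map (degree^3) is the volume of a 3D alpha shape over
the corrected viable-pose cloud: the union of Delaunay tetrahedra whose
circumradius does not exceed alpha. Alpha -> infinity recovers the convex
hull; small alpha preserves concavities and disconnected "islands".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .sampling import ROMMap

__all__ = [
    "CorrectedCloud",
    "AlphaShapeResult",
    "MapComparison",
    "cosine_correct",
    "alpha_volume",
    "compare_maps",
    "volume_ratio",
]

#: available corrections: scaled axis index, cosine-argument axis index
#: (columns are 0=abad, 1=fe, 2=lar)
_CORRECTIONS = {
    "abad_by_fe": (0, 1),
    "lar_by_fe": (2, 1),
    "fe_by_abad": (1, 0),
}


@dataclass
class CorrectedCloud:
    """Viable poses mapped into corrected degree coordinates."""

    points: np.ndarray      # (N, 3), columns follow (abad', fe', lar')
    correction: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)


@dataclass
class AlphaShapeResult:
    alpha: float            # corrected degrees
    volume: float           # degree^3
    n_components: int
    n_tetrahedra: int = 0
    hull_volume: float = 0.0


def default_alpha(step: float) -> float:
    """Default alpha = 1.5 x the grid step in corrected units.

    Small enough to preserve concavities and islands, large enough to
    connect diagonally adjacent grid cells.
    """
    return 1.5 * step


def cosine_correct(rom_map: ROMMap, correction: str = "abad_by_fe") -> CorrectedCloud:
    """Map the viable poses of *rom_map* into the cosine-corrected space."""
    if correction not in _CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}; "
                         f"choose from {sorted(_CORRECTIONS)}")
    pts = rom_map.viable_poses.astype(np.float64).copy()
    if len(pts) == 0:
        raise ValueError("ROM map has no viable poses to correct")
    scaled, arg = _CORRECTIONS[correction]
    pts[:, scaled] = pts[:, scaled] * np.cos(np.radians(pts[:, arg]))
    return CorrectedCloud(points=pts, correction=correction)


def _circumradii(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Circumsphere radius of each tetrahedron (vectorized linear solve)."""
    p0 = points[tets[:, 0]]
    rows = points[tets[:, 1:]] - p0[:, None, :]          # (M, 3, 3)
    rhs = 0.5 * np.einsum("ijk,ijk->ij", rows, rows)     # (M, 3)
    det = np.linalg.det(rows)
    good = np.abs(det) > 1e-12
    radii = np.full(len(tets), np.inf)
    if good.any():
        centers = np.linalg.solve(rows[good], rhs[good][..., None])[..., 0]
        radii[good] = np.linalg.norm(centers, axis=1)
    return radii


def _tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p0 = points[tets[:, 0]]
    rows = points[tets[:, 1:]] - p0[:, None, :]
    return np.abs(np.linalg.det(rows)) / 6.0


def _count_components(tets: np.ndarray) -> int:
    """Spatially disconnected clusters ("islands") of kept tetrahedra.

    Tetrahedra sharing any vertex are one component; vertex sharing is
    robust to the sliver tetrahedra that degenerate (gridded) inputs
    produce, where strict face adjacency can split a connected solid.
    """
    parent = np.arange(len(tets))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    seen: dict[int, int] = {}
    for ti, tet in enumerate(tets):
        for v in tet:
            v = int(v)
            if v in seen:
                a, b = find(seen[v]), find(ti)
                if a != b:
                    parent[b] = a
            else:
                seen[v] = ti
    return len({find(i) for i in range(len(tets))})


def alpha_volume(cloud: CorrectedCloud, alpha: float) -> AlphaShapeResult:
    """Alpha-complex volume of a corrected pose cloud.

    Keeps Delaunay tetrahedra with circumradius <= alpha; the volume is the
    sum of kept tetrahedron volumes and is bounded above by the convex-hull
    volume (checked).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    pts = cloud.points
    if len(pts) < 4:
        raise ValueError("alpha shape needs at least 4 points")
    try:
        tri = Delaunay(pts)
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate (coplanar?) point cloud: {exc}") from exc
    tets = tri.simplices
    keep = _circumradii(pts, tets) <= alpha
    kept = tets[keep]
    volume = float(_tet_volumes(pts, kept).sum()) if len(kept) else 0.0
    hull_volume = float(hull.volume)
    if volume > hull_volume * (1 + 1e-9) + 1e-9:
        raise AssertionError("alpha volume exceeded convex hull volume")
    n_components = _count_components(kept) if len(kept) else 0
    return AlphaShapeResult(alpha=float(alpha), volume=volume,
                            n_components=n_components,
                            n_tetrahedra=int(len(kept)),
                            hull_volume=hull_volume)


def wraparound_cloud(cloud: CorrectedCloud, axes=(1, 2),
                     period: float = 360.0) -> CorrectedCloud:
    """Duplicate points shifted +/- one period along toroidal axes.

    FE and LAR live on a circle (-180 == 180); duplicating boundary points
    lets the alpha complex close across the seam. Volumes computed from the
    result overcount the duplicated shells and are for topology inspection,
    not for comparison with flat-box volumes.
    """
    pts = [cloud.points]
    for ax in axes:
        shifted = []
        for block in pts:
            for sign in (-1.0, 1.0):
                s = block.copy()
                s[:, ax] += sign * period
                shifted.append(s)
        pts.extend(shifted)
    return CorrectedCloud(np.vstack(pts), cloud.correction + "+wrap")


@dataclass
class MapComparison:
    n_a_only: int
    n_b_only: int
    n_both: int
    jaccard: float
    extents_a: dict[str, tuple[float, float]]
    extents_b: dict[str, tuple[float, float]]


def _marginal_extents(poses: np.ndarray) -> dict[str, tuple[float, float]]:
    names = ("abad", "fe", "lar")
    if len(poses) == 0:
        return {n: (float("nan"), float("nan")) for n in names}
    return {n: (float(poses[:, i].min()), float(poses[:, i].max()))
            for i, n in enumerate(names)}


def compare_maps(a: ROMMap, b: ROMMap) -> MapComparison:
    """Set arithmetic between two ROM maps defined on identical grids."""
    if a.grid != b.grid:
        raise ValueError("ROM maps are defined on different grids")
    sa, sb = a.viable_set(), b.viable_set()
    inter = sa & sb
    union = sa | sb
    return MapComparison(
        n_a_only=len(sa - sb),
        n_b_only=len(sb - sa),
        n_both=len(inter),
        jaccard=(len(inter) / len(union)) if union else 1.0,
        extents_a=_marginal_extents(a.viable_poses),
        extents_b=_marginal_extents(b.viable_poses),
    )


def volume_ratio(a: AlphaShapeResult | float, b: AlphaShapeResult | float) -> float:
    """Percentage ``100 * a / b`` of two ROM volumes, to 2 decimals."""
    va = a.volume if isinstance(a, AlphaShapeResult) else float(a)
    vb = b.volume if isinstance(b, AlphaShapeResult) else float(b)
    if vb <= 0:
        raise ValueError("reference volume must be positive")
    return round(100.0 * va / vb, 2)
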