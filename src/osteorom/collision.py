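"""Triangle-mesh interpenetration testing.

Viability of a joint pose is decided by whether the two bone meshes
interpenetrate. The test here is *strict*: two meshes collide iff

* some triangle edge of one mesh pierces the open interior of a triangle
  of the other (transversal surface crossing), or
* a pair of coplanar triangles overlaps with positive area, or
* one closed mesh lies entirely inside the other (ray-parity test).

Touching-but-not-crossing contact (shared vertices, edge-on-edge or
edge-in-plane grazing) counts as NON-colliding: interpenetration, not
contact, is the criterion. A configurable contact tolerance (mm, default 0)
demands that a piercing clear the triangle boundary by that margin before
it counts.

A conservative broad phase (per-triangle AABBs hashed into a uniform
spatial grid built over the fixed mesh) prunes candidate pairs; the
narrow-phase predicate applied to the survivors is the same one the
brute-force all-pairs oracle uses, so the accelerated result is identical
to brute force by construction.
"""

from __future__ import annotations

import numpy as np

from .geometry import TriMesh

__all__ = ["CollisionChecker", "check_collision", "count_self_intersections"]

_DET_EPS = 1e-12
#: fixed, deliberately irrational-looking ray directions for parity tests
_RAY_DIRECTIONS = np.array(
    [
        [0.57735027, 0.52106591, 0.62860932],
        [-0.33218192, 0.81124219, 0.48056815],
        [0.14921761, -0.43150985, 0.88968655],
        [0.90096887, 0.22252093, -0.37252042],
        [-0.70710678, 0.5, 0.5],
        [0.26726124, 0.53452248, -0.80178373],
        [-0.12309149, -0.49236596, 0.86164044],
        [0.45584231, -0.56980288, 0.68376346],
    ]
)


def _tri_aabbs(tris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return tris.min(axis=1), tris.max(axis=1)


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without np.cross's axis-juggling overhead."""
    out = np.empty_like(a)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def _segments_pierce(orig: np.ndarray, vec: np.ndarray, tri: np.ndarray,
                     tol: float) -> np.ndarray:
    """Strict Moller-Trumbore segment-vs-triangle interior test, batched.

    ``orig + s * vec`` for s in (0, 1) must cross the open interior of the
    matching triangle, clearing the boundary by *tol* millimetres.
    """
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    h = _cross(vec, e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > _DET_EPS
    inv = np.where(ok, det, 1.0)
    s0 = orig - tri[:, 0]
    u = np.einsum("ij,ij->i", s0, h) / inv
    q = _cross(s0, e1)
    v = np.einsum("ij,ij->i", vec, q) / inv
    t = np.einsum("ij,ij->i", e2, q) / inv
    if tol > 0.0:
        # convert the mm tolerance to parameter-space margins
        seg_len = np.linalg.norm(vec, axis=1)
        seg_len = np.where(seg_len > 0, seg_len, 1.0)
        area2 = np.linalg.norm(_cross(e1, e2), axis=1)
        # height of the triangle above each side ~ area2 / side length
        char = np.where(area2 > 0, area2, 1.0)
        mu = tol * np.linalg.norm(e2, axis=1) / char   # margin on u
        mv = tol * np.linalg.norm(e1, axis=1) / char   # margin on v
        mw = tol * np.linalg.norm(e2 - e1, axis=1) / char
        mt = tol / seg_len
    else:
        mu = mv = mw = mt = 0.0
    return (
        ok
        & (u > mu)
        & (v > mv)
        & (u + v < 1.0 - mw)
        & (t > mt)
        & (t < 1.0 - mt)
    )


def _coplanar_overlap(ta: np.ndarray, tb: np.ndarray) -> bool:
    """Positive-area overlap of two (near-)coplanar triangles via shapely."""
    from shapely.geometry import Polygon

    n = np.cross(ta[1] - ta[0], ta[2] - ta[0])
    nn = np.linalg.norm(n)
    if nn < _DET_EPS:
        return False
    n = n / nn
    # project both triangles to the dominant plane
    drop = int(np.argmax(np.abs(n)))
    keep = [i for i in range(3) if i != drop]
    pa = Polygon(ta[:, keep])
    pb = Polygon(tb[:, keep])
    if not (pa.is_valid and pb.is_valid):
        return False
    return pa.intersection(pb).area > 1e-12


def tri_pairs_intersect(tris_a: np.ndarray, tris_b: np.ndarray,
                        tol: float = 0.0, any_hit: bool = False) -> np.ndarray:
    """Pairwise strict-interpenetration test for aligned triangle arrays.

    Parameters
    ----------
    tris_a, tris_b : (N, 3, 3) arrays; pair *i* is ``tris_a[i]`` vs ``tris_b[i]``.
    any_hit : return as soon as some pair is known to intersect (existence
        queries); per-pair flags for pairs after the first hit may be
        incomplete in that mode.

    Returns a boolean (N,) array.
    """
    tris_a = np.asarray(tris_a, dtype=np.float64)
    tris_b = np.asarray(tris_b, dtype=np.float64)
    n = len(tris_a)
    if n == 0:
        return np.zeros(0, dtype=bool)
    hit = np.zeros(n, dtype=bool)
    # all three edges of one triangle against the other, fused in one batch
    for tris_e, tris_t in ((tris_a, tris_b), (tris_b, tris_a)):
        orig = tris_e.reshape(-1, 3)                       # (3N, 3) edge starts
        vec = tris_e[:, [1, 2, 0]].reshape(-1, 3) - orig   # edge vectors
        tri = np.repeat(tris_t, 3, axis=0)
        hit |= _segments_pierce(orig, vec, tri, tol).reshape(n, 3).any(axis=1)
        if any_hit and hit.any():
            return hit
    # coplanar pairs evade the transversal test; treat area overlap as collision
    nb = _cross(tris_b[:, 1] - tris_b[:, 0], tris_b[:, 2] - tris_b[:, 0])
    nbn = np.linalg.norm(nb, axis=1, keepdims=True)
    scale = max(np.abs(tris_a).max(), np.abs(tris_b).max(), 1.0)
    cop_eps = 1e-9 * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        nbu = np.where(nbn > _DET_EPS, nb / nbn, 0.0)
    d = np.abs(
        np.einsum(
            "ikj,ij->ik", tris_a - tris_b[:, :1], nbu
        )
    ).max(axis=1)
    coplanar = (~hit) & (d <= cop_eps) & (nbn[:, 0] > _DET_EPS)
    for i in np.flatnonzero(coplanar):
        if _coplanar_overlap(tris_a[i], tris_b[i]):
            hit[i] = True
    return hit


def points_in_mesh(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Ray-parity containment of points in a closed triangle mesh."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    out = np.zeros(len(points), dtype=bool)
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    for pi, p in enumerate(points):
        for d in _RAY_DIRECTIONS:
            h = np.cross(d, e2)
            det = np.einsum("ij,ij->i", e1, h)
            ok = np.abs(det) > _DET_EPS
            inv = np.where(ok, det, 1.0)
            s0 = p - tris[:, 0]
            u = np.einsum("ij,ij->i", s0, h) / inv
            q = np.cross(s0, e1)
            v = np.einsum("ij,ij->i", d[None, :], q) / inv
            t = np.einsum("ij,ij->i", e2, q) / inv
            hits = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
            # a hit grazing a triangle boundary could be double counted:
            # retry with the next canned direction
            margin = np.minimum(np.minimum(u, v), 1.0 - u - v)
            if np.any(hits & (margin < 1e-9)):
                continue
            out[pi] = bool(np.count_nonzero(hits) % 2)
            break
    return out


_KEY_BIAS = np.int64(1) << 20
_KEY_SHIFT = 21


def _cell_keys(ix: np.ndarray, iy: np.ndarray, iz: np.ndarray) -> np.ndarray:
    return (
        ((ix + _KEY_BIAS) << (2 * _KEY_SHIFT))
        | ((iy + _KEY_BIAS) << _KEY_SHIFT)
        | (iz + _KEY_BIAS)
    )


class CollisionChecker:
    """Interpenetration tests of moving geometry against one fixed mesh.

    The broad phase hashes the fixed mesh's triangle AABBs into a uniform
    grid (cell edge ~ the typical triangle size) once; each query hashes
    the moving triangles into the same grid, so repeated queries — one per
    sampled pose — only pay for the moving mesh's transform. Oversized
    triangles on either side fall back to direct AABB overlap so a few
    coarse faces cannot degrade the grid.
    """

    def __init__(self, fixed: TriMesh, tol: float = 0.0):
        self.fixed = fixed
        self.tol = float(tol)
        self.tris = fixed.triangles
        self.lo, self.hi = _tri_aabbs(self.tris)
        widths = (self.hi - self.lo).max(axis=1)
        # cell edge: generous multiple of the typical AABB so nearly all
        # fixed triangles span at most 2 cells per axis
        self.cell = float(max(2.0 * np.percentile(widths, 90), tol, 1e-6))
        small = widths <= self.cell
        self.large_idx = np.flatnonzero(~small)
        small_idx = np.flatnonzero(small)
        keys_parts, ids_parts = [], []
        i0 = np.floor((self.lo[small_idx] - tol) / self.cell).astype(np.int64)
        i1 = np.floor((self.hi[small_idx] + tol) / self.cell).astype(np.int64)
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    d = np.array([dx, dy, dz])
                    cells = i0 + d
                    ok = np.all(cells <= i1, axis=1)
                    keys_parts.append(_cell_keys(cells[ok, 0], cells[ok, 1],
                                                 cells[ok, 2]))
                    ids_parts.append(small_idx[ok])
        keys = np.concatenate(keys_parts)
        ids = np.concatenate(ids_parts)
        order = np.argsort(keys, kind="stable")
        self.grid_keys = keys[order]
        self.grid_ids = ids[order]
        self.global_lo = self.lo.min(axis=0) - tol
        self.global_hi = self.hi.max(axis=0) + tol
        # bounding-sphere bounds for the narrow-phase prefilter
        self.fixed_centers = self.tris.mean(axis=1)
        self.fixed_radii = np.linalg.norm(
            self.tris - self.fixed_centers[:, None, :], axis=2
        ).max(axis=1)
        self.fixed_watertight = fixed.is_watertight()

    # -- internals --------------------------------------------------------

    def _candidate_pairs(self, tris_m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo_m, hi_m = _tri_aabbs(tris_m)
        near = np.all(hi_m >= self.global_lo, axis=1) & np.all(
            lo_m <= self.global_hi, axis=1
        )
        idx_m = np.flatnonzero(near)
        if len(idx_m) == 0:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        lo_n, hi_n = lo_m[idx_m], hi_m[idx_m]
        i0 = np.floor(lo_n / self.cell).astype(np.int64)
        i1 = np.floor(hi_n / self.cell).astype(np.int64)
        span = (i1 - i0).max(axis=1)
        mi_parts, fi_parts = [], []

        def _hash_lookup(rows: np.ndarray) -> None:
            if len(rows) == 0 or not len(self.grid_keys):
                return
            a0, a1 = i0[rows], i1[rows]
            nx, ny, nz = ((a1 - a0).max(axis=0) + 1).tolist()
            for dx in range(nx):
                for dy in range(ny):
                    for dz in range(nz):
                        d = np.array([dx, dy, dz])
                        cells = a0 + d
                        ok = np.flatnonzero(np.all(cells <= a1, axis=1))
                        if len(ok) == 0:
                            continue
                        keys = _cell_keys(cells[ok, 0], cells[ok, 1], cells[ok, 2])
                        left = np.searchsorted(self.grid_keys, keys, side="left")
                        right = np.searchsorted(self.grid_keys, keys, side="right")
                        counts = right - left
                        have = counts > 0
                        if not have.any():
                            continue
                        left, counts = left[have], counts[have]
                        sub = rows[ok[have]]
                        # expand [left, left+count) ranges into flat indices
                        total = int(counts.sum())
                        starts = np.repeat(left, counts)
                        within = np.arange(total) - np.repeat(
                            np.cumsum(counts) - counts, counts
                        )
                        fi_parts.append(self.grid_ids[starts + within])
                        mi_parts.append(idx_m[np.repeat(sub, counts)])

        _hash_lookup(np.flatnonzero(span <= 1))
        _hash_lookup(np.flatnonzero((span > 1) & (span <= 5)))

        # truly huge moving triangles, and oversized fixed ones: direct AABB
        def _aabb_block(rows: np.ndarray, cols: np.ndarray) -> None:
            if len(rows) == 0 or len(cols) == 0:
                return
            overlap = np.all(
                hi_n[rows][:, None, :] + self.tol >= self.lo[cols][None, :, :],
                axis=2,
            ) & np.all(
                lo_n[rows][:, None, :] - self.tol <= self.hi[cols][None, :, :],
                axis=2,
            )
            mj, fj = np.nonzero(overlap)
            if len(mj):
                mi_parts.append(idx_m[rows[mj]])
                fi_parts.append(cols[fj])

        _aabb_block(np.flatnonzero(span > 5), np.arange(len(self.tris)))
        _aabb_block(np.arange(len(idx_m)), self.large_idx)

        if not mi_parts:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        mi = np.concatenate(mi_parts)
        fi = np.concatenate(fi_parts)
        # drop duplicates (same pair reached through several cells)
        pair_ids = mi * np.int64(len(self.tris)) + fi
        order = np.argsort(pair_ids, kind="stable")
        pair_ids = pair_ids[order]
        first = np.ones(len(pair_ids), dtype=bool)
        first[1:] = pair_ids[1:] != pair_ids[:-1]
        keep_idx = order[first]
        mi = mi[keep_idx]
        fi = fi[keep_idx]
        # exact AABB overlap filter
        ok = np.all(hi_m[mi] + self.tol >= self.lo[fi], axis=1) & np.all(
            lo_m[mi] - self.tol <= self.hi[fi], axis=1
        )
        return mi[ok], fi[ok]

    def surfaces_intersect(self, verts: np.ndarray, faces: np.ndarray,
                           brute: bool = False) -> bool:
        """True iff any moving triangle strictly interpenetrates a fixed one."""
        tris_m = verts[faces]
        if brute:
            nm, nf = len(tris_m), len(self.tris)
            mi = np.repeat(np.arange(nm), nf)
            fi = np.tile(np.arange(nf), nm)
        else:
            mi, fi = self._candidate_pairs(tris_m)
        if len(mi) == 0:
            return False
        # bounding-sphere prefilter (conservative): centres farther apart
        # than the summed circumradius bounds cannot intersect
        tm = tris_m[mi]
        cm = tm.mean(axis=1)
        rm = np.linalg.norm(tm - cm[:, None, :], axis=2).max(axis=1)
        diff = cm - self.fixed_centers[fi]
        gap2 = np.einsum("ij,ij->i", diff, diff)
        near = gap2 <= (rm + self.fixed_radii[fi] + self.tol) ** 2
        mi, fi = mi[near], fi[near]
        if len(mi) == 0:
            return False
        chunk = 200_000
        for start in range(0, len(mi), chunk):
            sl = slice(start, start + chunk)
            if tri_pairs_intersect(tris_m[mi[sl]], self.tris[fi[sl]], self.tol,
                                   any_hit=True).any():
                return True
        return False

    def intersects(self, verts: np.ndarray, faces: np.ndarray,
                   moving_watertight: bool | None = None,
                   brute: bool = False,
                   containment_faces: np.ndarray | None = None) -> bool:
        """Full interpenetration test including mutual containment.

        *containment_faces* lets a caller that pre-culled far-away faces for
        the surface test still supply the complete closed surface for the
        ray-parity containment test.
        """
        if self.surfaces_intersect(verts, faces, brute=brute):
            return True
        if containment_faces is None:
            containment_faces = faces
        # disjoint surfaces: full containment is only possible when one
        # mesh's AABB lies inside the other's — cheap rejects first
        m_lo, m_hi = verts.min(axis=0), verts.max(axis=0)
        moving_inside_box = np.all(m_lo >= self.global_lo) and np.all(
            m_hi <= self.global_hi)
        fixed_inside_box = np.all(self.global_lo >= m_lo) and np.all(
            self.global_hi <= m_hi)
        if self.fixed_watertight and moving_inside_box and points_in_mesh(
            verts[containment_faces[0, :1]], self.tris
        )[0]:
            return True
        if fixed_inside_box:
            if moving_watertight is None:
                moving_watertight = TriMesh(verts, containment_faces).is_watertight()
            if moving_watertight and points_in_mesh(
                self.fixed.vertices[:1], verts[containment_faces]
            )[0]:
                return True
        return False


def check_collision(a: TriMesh, b: TriMesh, tol: float = 0.0,
                    brute: bool = False) -> bool:
    """True iff meshes *a* and *b* interpenetrate (see module docstring).

    With ``brute=True`` the all-pairs triangle test is run with no broad
    phase — the independent oracle the accelerated path must agree with.
    """
    checker = CollisionChecker(b, tol=tol)
    return checker.intersects(a.vertices, a.faces, brute=brute)


def count_self_intersections(mesh: TriMesh) -> int:
    """Count strictly interpenetrating triangle pairs within one mesh.

    Pairs sharing a vertex are excluded (adjacent faces always touch).
    """
    tris = mesh.triangles
    checker = CollisionChecker(mesh)
    mi, fi = checker._candidate_pairs(tris)
    keep = mi < fi
    mi, fi = mi[keep], fi[keep]
    if len(mi) == 0:
        return 0
    fa = mesh.faces[mi]
    fb = mesh.faces[fi]
    shared = (fa[:, :, None] == fb[:, None, :]).any(axis=(1, 2))
    mi, fi = mi[~shared], fi[~shared]
    if len(mi) == 0:
        return 0
    return int(tri_pairs_intersect(tris[mi], tris[fi]).sum())
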