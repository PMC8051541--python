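"""Spatial query primitives: closest points on triangle meshes and polylines,
segment/ray-triangle intersection, and a pruned triangle-triangle overlap test.

All queries are built on :class:`scipy.spatial.cKDTree` over element centroids
plus exact, vectorized geometric predicates, so they need no external spatial
index.  Candidate sets from the k-nearest-centroid phase are verified with a
radius re-query, which makes the closest-point results exact.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "closest_point_on_triangles",
    "SurfaceIndex",
    "PolylineIndex",
    "segments_cross_triangles",
    "ray_mesh_intersections",
    "intersecting_triangle_pairs",
]


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Exact closest point on each triangle for each (point, triangle) pair.

    Parameters
    ----------
    points : (..., 3) array
    triangles : (..., 3, 3) array broadcast-compatible with ``points``

    Returns
    -------
    (..., 3) array of closest points.

    Uses the barycentric clamping construction: project onto the triangle
    plane; if the projection is inside, done; otherwise take the nearest of
    the three clamped edge projections.
    """
    p = np.asarray(points, dtype=np.float64)
    tri = np.asarray(triangles, dtype=np.float64)
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]

    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("...i,...i", ab, ap)
    d2 = np.einsum("...i,...i", ac, ap)

    bp = p - b
    d3 = np.einsum("...i,...i", ab, bp)
    d4 = np.einsum("...i,...i", ac, bp)

    cp = p - c
    d5 = np.einsum("...i,...i", ab, cp)
    d6 = np.einsum("...i,...i", ac, cp)

    # Region tests after Ericson, "Real-Time Collision Detection".
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    out = np.empty(np.broadcast(p, a).shape, dtype=np.float64)

    # vertex regions
    m_a = (d1 <= 0) & (d2 <= 0)
    m_b = (d3 >= 0) & (d4 <= d3)
    m_c = (d6 >= 0) & (d5 <= d6)

    # edge AB
    denom_ab = d1 - d3
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(denom_ab != 0, d1 / denom_ab, 0.0)
    m_ab = (~m_a) & (~m_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)

    # edge AC
    denom_ac = d2 - d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(denom_ac != 0, d2 / denom_ac, 0.0)
    m_ac = (~m_a) & (~m_b) & (~m_c) & (~m_ab) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)

    # edge BC
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    m_bc = (
        (~m_a) & (~m_b) & (~m_c) & (~m_ab) & (~m_ac)
        & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    )

    m_in = ~(m_a | m_b | m_c | m_ab | m_ac | m_bc)
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_in = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w_in = np.where(denom != 0, vc / denom, 1.0 / 3.0)

    out[m_a] = np.broadcast_to(a, out.shape)[m_a]
    out[m_b] = np.broadcast_to(b, out.shape)[m_b]
    out[m_c] = np.broadcast_to(c, out.shape)[m_c]
    out[m_ab] = (a + v_ab[..., None] * ab)[m_ab]
    out[m_ac] = (a + w_ac[..., None] * ac)[m_ac]
    out[m_bc] = (b + w_bc[..., None] * (c - b))[m_bc]
    out[m_in] = (a + v_in[..., None] * ab + w_in[..., None] * ac)[m_in]
    return out


class SurfaceIndex:
    """Exact closest-point queries against a triangle mesh.

    Phase 1 finds the k nearest triangle centroids; phase 2 re-queries all
    centroids within (best candidate distance + max triangle circumradius),
    which guarantees the true closest triangle is examined.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 8):
        self.vertices = np.asarray(vertices, dtype=np.float64)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.triangles = self.vertices[self.faces]  # (T, 3, 3)
        self.centroids = self.triangles.mean(axis=1)
        # max distance from centroid to any triangle vertex: search slack
        self._reach = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self._max_reach = float(self._reach.max()) if len(self._reach) else 0.0
        self._tree = cKDTree(self.centroids)
        self._k = min(k, len(self.faces))
        e1 = self.triangles[:, 1] - self.triangles[:, 0]
        e2 = self.triangles[:, 2] - self.triangles[:, 0]
        n = np.cross(e1, e2)
        norm = np.linalg.norm(n, axis=1)
        norm[norm == 0] = 1.0
        self.face_normals = n / norm[:, None]

    def _best_among(self, points, cand):
        """cand: (P, K) triangle indices (may include -1 padding)."""
        valid = cand >= 0
        cand_safe = np.where(valid, cand, 0)
        tris = self.triangles[cand_safe]  # (P, K, 3, 3)
        cp = closest_point_on_triangles(points[:, None, :], tris)
        d2 = np.einsum("pki,pki->pk", cp - points[:, None, :], cp - points[:, None, :])
        d2[~valid] = np.inf
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        return (
            cp[rows, best],
            np.sqrt(d2[rows, best]),
            cand_safe[rows, best],
        )

    def query(self, points: np.ndarray):
        """Return (closest_points, distances, triangle_indices) for each point."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        _, idx = self._tree.query(points, k=self._k)
        idx = np.atleast_2d(idx.reshape(len(points), -1))
        cp, dist, fi = self._best_among(points, idx)

        # verification: a triangle can only beat the current best if its
        # centroid lies within dist + its own reach of the point
        radius = dist + self._max_reach + 1e-12
        need = self._tree.query_ball_point(points, radius)
        flat_pt: list[int] = []
        flat_tri: list[np.ndarray] = []
        for i, cands in enumerate(need):
            if len(cands) <= self._k:
                continue
            cands = np.asarray(cands, dtype=np.int64)
            d_cent = np.linalg.norm(self.centroids[cands] - points[i], axis=1)
            cands = cands[d_cent <= dist[i] + self._reach[cands] + 1e-12]
            if len(cands):
                flat_pt.append(np.full(len(cands), i, dtype=np.int64))
                flat_tri.append(cands)
        if flat_pt:
            pidx = np.concatenate(flat_pt)
            tidx = np.concatenate(flat_tri)
            cp2 = closest_point_on_triangles(points[pidx], self.triangles[tidx])
            d2 = np.linalg.norm(cp2 - points[pidx], axis=1)
            better = d2 < dist[pidx] - 1e-15
            if better.any():
                # keep the single best improvement per point
                order = np.lexsort((d2[better], pidx[better]))
                pi = pidx[better][order]
                first = np.unique(pi, return_index=True)[1]
                rows = pi[first]
                sel = np.flatnonzero(better)[order][first]
                cp[rows] = cp2[sel]
                dist[rows] = d2[sel]
                fi[rows] = tidx[sel]
        return cp, dist, fi


class PolylineIndex:
    """Closest-point queries against a set of 3D line segments."""

    def __init__(self, segments: np.ndarray):
        self.segments = np.asarray(segments, dtype=np.float64)  # (S, 2, 3)
        self.mid = self.segments.mean(axis=1)
        self._reach = np.linalg.norm(
            self.segments[:, 0] - self.segments[:, 1], axis=1
        ) / 2.0
        self._max_reach = float(self._reach.max()) if len(self._reach) else 0.0
        self._tree = cKDTree(self.mid)
        self._k = min(6, len(self.segments))

    def query(self, points: np.ndarray):
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        _, idx = self._tree.query(points, k=self._k)
        idx = np.atleast_2d(idx.reshape(len(points), -1))
        a = self.segments[idx, 0, :]
        b = self.segments[idx, 1, :]
        ab = b - a
        denom = np.einsum("pki,pki->pk", ab, ab)
        denom[denom == 0] = 1.0
        t = np.einsum("pki,pki->pk", points[:, None, :] - a, ab) / denom
        t = np.clip(t, 0.0, 1.0)
        cp = a + t[..., None] * ab
        d2 = np.einsum("pki,pki->pk", cp - points[:, None, :], cp - points[:, None, :])
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        cp_best = cp[rows, best]
        dist = np.sqrt(d2[rows, best])

        radius = dist + self._max_reach + 1e-12
        need = self._tree.query_ball_point(points, radius)
        for i, cands in enumerate(need):
            if len(cands) <= self._k:
                continue
            cands = np.asarray(cands)
            a = self.segments[cands, 0]
            b = self.segments[cands, 1]
            ab = b - a
            denom = np.einsum("ki,ki->k", ab, ab)
            denom[denom == 0] = 1.0
            t = np.clip(np.einsum("ki,ki->k", points[i] - a, ab) / denom, 0.0, 1.0)
            cpi = a + t[:, None] * ab
            di = np.linalg.norm(cpi - points[i], axis=1)
            j = np.argmin(di)
            if di[j] < dist[i]:
                dist[i] = di[j]
                cp_best[i] = cpi[j]
        return cp_best, dist


def _moller_trumbore(origins, directions, tri, eps=1e-12):
    """Vectorized ray-triangle intersection.

    origins, directions: (R, 3); tri: (T, 3, 3).
    Returns (R, T) array of ray parameters t (np.inf where no hit).
    """
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(directions[:, None, :], e2[None, :, :])  # (R, T, 3)
    a = np.einsum("ti,rti->rt", e1, h)
    parallel = np.abs(a) < eps
    a_safe = np.where(parallel, 1.0, a)
    s = origins[:, None, :] - v0[None, :, :]
    u = np.einsum("rti,rti->rt", s, h) / a_safe
    q = np.cross(s, e1[None, :, :])
    v = np.einsum("ri,rti->rt", directions, q) / a_safe
    t = np.einsum("ti,rti->rt", e2, q) / a_safe
    ok = (
        (~parallel)
        & (u >= -eps)
        & (v >= -eps)
        & (u + v <= 1 + eps)
        & (t > eps)
    )
    return np.where(ok, t, np.inf)


def ray_mesh_intersections(origin, direction, vertices, faces, max_dist=np.inf):
    """Sorted hit parameters t of a single ray against a mesh (brute force,
    chunked over faces)."""
    origin = np.asarray(origin, dtype=np.float64)[None, :]
    direction = np.asarray(direction, dtype=np.float64)
    direction = (direction / np.linalg.norm(direction))[None, :]
    tris = np.asarray(vertices, dtype=np.float64)[np.asarray(faces)]
    hits = []
    for start in range(0, len(tris), 200_000):
        t = _moller_trumbore(origin, direction, tris[start : start + 200_000])[0]
        t = t[np.isfinite(t)]
        hits.append(t[t <= max_dist])
    t = np.sort(np.concatenate(hits)) if hits else np.empty(0)
    if len(t) > 1:
        # a hit on an edge shared by two triangles reports once per triangle
        t = t[np.concatenate([[True], np.diff(t) > 1e-9])]
    return t


def segments_cross_triangles(segs, tris, eps=1e-10):
    """Boolean (S, T): does segment s properly intersect triangle t?

    segs: (S, 2, 3); tris: (T, 3, 3).
    """
    origins = segs[:, 0]
    d = segs[:, 1] - segs[:, 0]
    length = np.linalg.norm(d, axis=1)
    length[length == 0] = 1.0
    dirs = d / length[:, None]
    t = _moller_trumbore(origins, dirs, tris, eps=eps)
    return (t > eps) & (t < length[:, None] - eps)


def intersecting_triangle_pairs(vertices, faces, max_pairs=200_000):
    """Sampled self-intersection detector.

    Finds non-adjacent triangle pairs with overlapping bounding neighborhoods
    (centroid KD-tree pruned) and tests whether any edge of one pierces the
    other.  Pair testing is capped at ``max_pairs``; the return value is the
    list of intersecting (i, j) pairs among those examined.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    tris = vertices[faces]
    centroids = tris.mean(axis=1)
    reach = np.linalg.norm(tris - centroids[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(centroids)
    pairs = tree.query_pairs(2.0 * float(reach.max()) if len(reach) else 0.0,
                             output_type="ndarray")
    if len(pairs) == 0:
        return []
    # prune pairs whose spheres don't touch, then drop vertex-sharing pairs
    d = np.linalg.norm(centroids[pairs[:, 0]] - centroids[pairs[:, 1]], axis=1)
    pairs = pairs[d <= reach[pairs[:, 0]] + reach[pairs[:, 1]]]
    share = np.array(
        [len(set(faces[i]) & set(faces[j])) > 0 for i, j in pairs], dtype=bool
    )
    pairs = pairs[~share]
    pairs = pairs[:max_pairs]
    out = []
    for i, j in pairs:
        e_i = tris[i][[[0, 1], [1, 2], [2, 0]]]  # (3, 2, 3)
        e_j = tris[j][[[0, 1], [1, 2], [2, 0]]]
        if segments_cross_triangles(e_i, tris[j][None]).any() or \
           segments_cross_triangles(e_j, tris[i][None]).any():
            out.append((int(i), int(j)))
    return out
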