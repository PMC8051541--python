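"""Draft splint shell construction: normal offset, plane crop, isotropic remesh.

The splint's bar centerlines live on a surface offset a constant clearance
(default 2 mm, the bar radius) from the skin.  This module builds that shell:

1. :func:`offset_surface` displaces every vertex along its angle-weighted
   normal — connectivity-preserving and exact for smooth scans when the
   offset is small against the surface's radius of curvature.
2. :func:`plane_cut` crops the shell to the splint profile with exact
   triangle clipping (no caps; the new boundary lies on the cut plane).
3. :func:`remesh_isotropic` rebuilds the cropped shell into a quasi-uniform
   triangulation (edge split / collapse / flip / tangential smoothing with
   back-projection), whose edges become the bar centerlines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._spatial import PolylineIndex, SurfaceIndex
from .mesh_core import SurfaceMesh, weld_vertices

log = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


class TopologyError(ValueError):
    pass


@dataclass(frozen=True)
class CutPlane:
    """Clipping plane: keep the half-space on ``keep_side`` of ``normal``."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]
    keep_side: str = "positive"

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=np.float64)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            object.__setattr__(self, "normal", tuple(n / np.linalg.norm(n)))
        if self.keep_side not in ("positive", "negative"):
            raise ParameterError("keep_side must be 'positive' or 'negative'")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        n = np.asarray(self.normal)
        s = (np.atleast_2d(points) - np.asarray(self.point)) @ n
        return s if self.keep_side == "positive" else -s


@dataclass(frozen=True)
class RemeshParams:
    """Isotropic remeshing controls.

    target_edge_length : desired edge length h, mm.
    iterations : split/collapse/flip/smooth passes.
    smoothing_weight : tangential Laplacian step size in (0, 1].
    """

    target_edge_length: float
    iterations: int = 10
    smoothing_weight: float = 0.6

    def __post_init__(self):
        if self.target_edge_length <= 0:
            raise ParameterError("target_edge_length must be positive")
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")
        if not 0.0 < self.smoothing_weight <= 1.0:
            raise ParameterError("smoothing_weight must be in (0, 1]")


# ---------------------------------------------------------------------------
# offset


def angle_weighted_vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Unit vertex normals weighted by incident-corner angles.

    Angle weighting makes the normal independent of how the neighborhood is
    triangulated, which matters when offsetting scan meshes.
    """
    t = mesh.triangles()
    fn = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
    norms = np.linalg.norm(fn, axis=1)
    norms[norms == 0] = 1.0
    fn = fn / norms[:, None]

    out = np.zeros_like(mesh.vertices)
    for corner in range(3):
        a = t[:, corner]
        b = t[:, (corner + 1) % 3]
        c = t[:, (corner + 2) % 3]
        u = b - a
        v = c - a
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1) + 1e-300)
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(out, mesh.faces[:, corner], ang[:, None] * fn)
    lens = np.linalg.norm(out, axis=1)
    lens[lens == 0] = 1.0
    return out / lens[:, None]


def offset_surface(mesh: SurfaceMesh, distance: float) -> SurfaceMesh:
    """Displace every vertex by ``distance`` along its vertex normal.

    Connectivity is preserved exactly.  If any offset vertex ends up closer
    than 0.95 x distance to the input surface, a warning is logged — the
    telltale of local self-intersection in concave, tightly curved regions.
    """
    if distance <= 0:
        raise ParameterError("offset distance must be positive")
    if len(mesh.boundary_edges()) > 0:
        raise TopologyError("offset requires a closed input surface")
    normals = angle_weighted_vertex_normals(mesh)
    out = SurfaceMesh(mesh.vertices + distance * normals, mesh.faces.copy(),
                      closed=True)
    index = SurfaceIndex(mesh.vertices, mesh.faces)
    _, dist, _ = index.query(out.vertices)
    n_close = int((dist < 0.95 * distance).sum())
    if n_close:
        log.warning(
            "offset: %d of %d vertices closer than 0.95*d to the input "
            "surface (local self-intersection likely)", n_close, out.n_vertices)
    return out


# ---------------------------------------------------------------------------
# plane cut


def plane_cut(mesh: SurfaceMesh, plane: CutPlane, tol: float = 1e-9,
              drop_coplanar_faces: bool = False) -> SurfaceMesh:
    """Clip a mesh by a plane, keeping one side, without capping.

    Crossing triangles are cut exactly at the plane; cut points are computed
    once per mesh edge so the new boundary is a welded closed polyline lying
    on the plane.  If the plane misses the mesh entirely the input is
    returned unchanged with a warning.

    Faces lying entirely in the plane are kept on the positive side only,
    so complementary cuts partition the surface exactly; with
    ``drop_coplanar_faces`` they (and flat clip slivers) are discarded from
    both sides instead — the right behavior when the caller caps the cut,
    as a flat cap would double-cover them.
    """
    sd = plane.signed_distance(mesh.vertices)
    dropped = sd < -tol
    if not dropped.any():
        log.warning("plane_cut: plane does not remove anything; "
                    "returning input unchanged")
        return mesh.copy()
    if (sd <= tol).all():
        log.warning("plane_cut: plane drops the entire mesh; "
                    "returning input unchanged")
        return mesh.copy()

    verts = [v for v in mesh.vertices]
    cut_point: dict[tuple[int, int], int] = {}
    nrm = np.asarray(plane.normal)
    pt = np.asarray(plane.point)

    def cut(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        idx = cut_point.get(key)
        if idx is None:
            sa, sb = sd[a], sd[b]
            t = sa / (sa - sb)
            p = mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a])
            p = p - ((p - pt) @ nrm) * nrm  # snap exactly onto the plane
            idx = len(verts)
            verts.append(p)
            cut_point[key] = idx
        return idx

    coplanar_tol = max(tol, 1e-7)
    on_plane = np.abs(sd) <= coplanar_tol
    new_faces: list[tuple[int, int, int]] = []

    def emit(tri):
        # flat products (all corners essentially on the plane) are zero-area
        # slivers; assign them like coplanar faces
        if all(idx < mesh.n_vertices and on_plane[idx]
               or idx >= mesh.n_vertices for idx in tri):
            if drop_coplanar_faces or plane.keep_side == "negative":
                return
        new_faces.append(tri)

    for face in mesh.faces:
        drop = dropped[face]
        n_drop = int(drop.sum())
        if n_drop == 0:
            if on_plane[face].all() and (drop_coplanar_faces
                                         or plane.keep_side == "negative"):
                continue
            new_faces.append(tuple(face))
            continue
        if n_drop == 3:
            continue
        # rotate so the pattern is canonical, preserving orientation
        a, b, c = face
        da, db, dc = drop
        if n_drop == 1:
            while not dc:  # rotate until the dropped vertex is c
                a, b, c = b, c, a
                da, db, dc = db, dc, da
            p_bc = cut(b, c)
            p_ca = cut(c, a)
            emit((a, b, p_bc))
            emit((a, p_bc, p_ca))
        else:  # n_drop == 2: rotate until the kept vertex is a
            while da:
                a, b, c = b, c, a
                da, db, dc = db, dc, da
            p_ab = cut(a, b)
            p_ca = cut(c, a)
            emit((a, p_ab, p_ca))

    v, f = weld_vertices(np.asarray(verts), np.asarray(new_faces, dtype=np.int64),
                         tolerance=1e-9)
    # drop vertices no longer referenced
    used = np.unique(f)
    remap = -np.ones(len(v), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(v[used], remap[f], closed=False)


# ---------------------------------------------------------------------------
# isotropic remeshing


class _EditMesh:
    """Editable triangle mesh with incidence maps, for local remeshing ops."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.pos: list[np.ndarray] = [v.copy() for v in vertices]
        self.faces: dict[int, tuple[int, int, int]] = {}
        self.vertex_faces: dict[int, set[int]] = {}
        self.edge_faces: dict[tuple[int, int], set[int]] = {}
        self._next_fid = 0
        for f in faces:
            self.add_face(tuple(int(x) for x in f))

    @staticmethod
    def _ekey(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    def add_face(self, tri: tuple[int, int, int]) -> int:
        fid = self._next_fid
        self._next_fid += 1
        self.faces[fid] = tri
        for v in tri:
            self.vertex_faces.setdefault(v, set()).add(fid)
        for i in range(3):
            self.edge_faces.setdefault(
                self._ekey(tri[i], tri[(i + 1) % 3]), set()).add(fid)
        return fid

    def remove_face(self, fid: int) -> None:
        tri = self.faces.pop(fid)
        for v in tri:
            self.vertex_faces[v].discard(fid)
        for i in range(3):
            key = self._ekey(tri[i], tri[(i + 1) % 3])
            s = self.edge_faces.get(key)
            if s is not None:
                s.discard(fid)
                if not s:
                    del self.edge_faces[key]

    # -- queries ----------------------------------------------------------

    def is_boundary_edge(self, a: int, b: int) -> bool:
        return len(self.edge_faces.get(self._ekey(a, b), ())) == 1

    def is_boundary_vertex(self, v: int) -> bool:
        for fid in self.vertex_faces.get(v, ()):
            tri = self.faces[fid]
            i = tri.index(v)
            if self.is_boundary_edge(v, tri[(i + 1) % 3]) or \
               self.is_boundary_edge(v, tri[(i + 2) % 3]):
                return True
        return False

    def neighbors(self, v: int) -> set[int]:
        out: set[int] = set()
        for fid in self.vertex_faces.get(v, ()):
            out.update(self.faces[fid])
        out.discard(v)
        return out

    def valence(self, v: int) -> int:
        return len(self.neighbors(v))

    def edge_length(self, a: int, b: int) -> float:
        return float(np.linalg.norm(self.pos[a] - self.pos[b]))

    def face_normal(self, tri) -> np.ndarray:
        a, b, c = (self.pos[i] for i in tri)
        return np.cross(b - a, c - a)

    # -- edit operations --------------------------------------------------

    def split_edge(self, a: int, b: int) -> int | None:
        fids = list(self.edge_faces.get(self._ekey(a, b), ()))
        if not fids:
            return None
        m = len(self.pos)
        self.pos.append(0.5 * (self.pos[a] + self.pos[b]))
        for fid in fids:
            tri = self.faces[fid]
            # orient: does the face traverse a->b or b->a?
            ia = tri.index(a)
            if tri[(ia + 1) % 3] == b:
                c = tri[(ia + 2) % 3]
                self.remove_face(fid)
                self.add_face((a, m, c))
                self.add_face((m, b, c))
            else:
                c = tri[(ia + 1) % 3]
                self.remove_face(fid)
                self.add_face((b, m, c))
                self.add_face((m, a, c))
        return m

    def collapse_edge(self, a: int, b: int, target: np.ndarray) -> bool:
        """Collapse b into a, moving a to ``target``.  Returns success."""
        key = self._ekey(a, b)
        fids = self.edge_faces.get(key)
        if not fids:
            return False
        opposite = set()
        for fid in fids:
            opposite.update(self.faces[fid])
        opposite -= {a, b}
        # link condition: common one-ring = opposite vertices of the edge
        if self.neighbors(a) & self.neighbors(b) != opposite:
            return False
        old = self.pos[a]
        self.pos[a] = target.copy()
        # reject if any surviving face flips or degenerates
        survivors = (self.vertex_faces[a] | self.vertex_faces[b]) - set(fids)
        for fid in survivors:
            tri = tuple(a if v == b else v for v in self.faces[fid])
            n_new = self.face_normal(tri)
            if np.linalg.norm(n_new) < 1e-12:
                self.pos[a] = old
                return False
            n_old = self.face_normal(self.faces[fid])
            if np.dot(n_new, n_old) <= 0:
                self.pos[a] = old
                return False
        for fid in list(fids):
            self.remove_face(fid)
        for fid in list(self.vertex_faces.get(b, ())):
            tri = self.faces[fid]
            self.remove_face(fid)
            self.add_face(tuple(a if v == b else v for v in tri))
        self.vertex_faces.pop(b, None)
        return True

    def flip_edge(self, a: int, b: int) -> bool:
        key = self._ekey(a, b)
        fids = list(self.edge_faces.get(key, ()))
        if len(fids) != 2:
            return False
        f1, f2 = (self.faces[fid] for fid in fids)
        # orient so f1 traverses a->b
        if (f1.index(a) + 1) % 3 != f1.index(b):
            f1, f2 = f2, f1
            fids = fids[::-1]
        c = next(v for v in f1 if v not in (a, b))
        d = next(v for v in f2 if v not in (a, b))
        if c == d or d in (a, b):
            return False
        if self._ekey(c, d) in self.edge_faces:
            return False  # would create a duplicate edge
        n1, n2 = (self.face_normal((a, d, c)), self.face_normal((d, b, c)))
        if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
            return False
        ref = self.face_normal(f1) + self.face_normal(f2)
        if np.dot(n1, ref) <= 0 or np.dot(n2, ref) <= 0:
            return False
        for fid in fids:
            self.remove_face(fid)
        self.add_face((a, d, c))
        self.add_face((d, b, c))
        return True

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        pos = np.asarray(self.pos)
        faces = np.asarray(list(self.faces.values()), dtype=np.int64)
        used = np.unique(faces)
        remap = -np.ones(len(pos), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return pos[used], remap[faces]


def _valence_deviation(em: _EditMesh, v: int) -> int:
    target = 4 if em.is_boundary_vertex(v) else 6
    return em.valence(v) - target


def remesh_isotropic(mesh: SurfaceMesh, params: RemeshParams) -> SurfaceMesh:
    """Incremental isotropic remeshing toward a uniform edge length h.

    Each iteration: split edges > 4/3 h, collapse edges < 4/5 h, flip edges
    toward valence 6 (4 on the boundary), tangential smoothing, projection of
    every vertex back to the *original* surface.  Boundary vertices slide
    only along the original boundary polyline, so crop profiles survive.
    """
    h = params.target_edge_length
    extents = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
    nonflat = extents[extents > 1e-9]
    if len(nonflat) == 0 or h >= 0.5 * nonflat.min():
        raise ParameterError(
            f"target edge length {h} too large for mesh extents {extents}")

    surface = SurfaceIndex(mesh.vertices, mesh.faces)
    boundary_idx: PolylineIndex | None = None
    loops = mesh.boundary_loops()
    if loops:
        segs = []
        for loop in loops:
            pts = mesh.vertices[loop]
            segs.append(np.stack([pts, np.roll(pts, -1, axis=0)], axis=1))
        boundary_idx = PolylineIndex(np.concatenate(segs))

    em = _EditMesh(mesh.vertices, mesh.faces)
    high = 4.0 / 3.0 * h
    low = 4.0 / 5.0 * h

    for _ in range(params.iterations):
        # 1. split long edges
        for a, b in list(em.edge_faces.keys()):
            if (a, b) in em.edge_faces and em.edge_length(a, b) > high:
                em.split_edge(a, b)

        # 2. collapse short edges
        for a, b in list(em.edge_faces.keys()):
            if (a, b) not in em.edge_faces:
                continue
            if em.edge_length(a, b) >= low:
                continue
            ba, bb = em.is_boundary_vertex(a), em.is_boundary_vertex(b)
            if ba and bb:
                if not em.is_boundary_edge(a, b):
                    continue  # interior chord between boundary vertices
                target = 0.5 * (em.pos[a] + em.pos[b])
                keep, gone = a, b
            elif ba:
                keep, gone, target = a, b, em.pos[a]
            elif bb:
                keep, gone, target = b, a, em.pos[b]
            else:
                keep, gone = a, b
                target = 0.5 * (em.pos[a] + em.pos[b])
            # guard: collapse must not create overly long edges
            ok = all(
                np.linalg.norm(target - em.pos[n]) <= high
                for n in (em.neighbors(keep) | em.neighbors(gone)) - {keep, gone}
            )
            if ok:
                em.collapse_edge(keep, gone, target)

        # 3. valence-improving flips
        for a, b in list(em.edge_faces.keys()):
            if (a, b) not in em.edge_faces or em.is_boundary_edge(a, b):
                continue
            fids = list(em.edge_faces[(a, b)])
            if len(fids) != 2:
                continue
            f1, f2 = (em.faces[f] for f in fids)
            c = next(v for v in f1 if v not in (a, b))
            d = next(v for v in f2 if v not in (a, b))
            before = sum(_valence_deviation(em, v) ** 2 for v in (a, b, c, d))
            after = (
                (_valence_deviation(em, a) - 1) ** 2
                + (_valence_deviation(em, b) - 1) ** 2
                + (_valence_deviation(em, c) + 1) ** 2
                + (_valence_deviation(em, d) + 1) ** 2
            )
            if after < before:
                em.flip_edge(a, b)

        # 4. tangential smoothing + 5. back-projection
        boundary = {v for v in em.vertex_faces if em.is_boundary_vertex(v)}
        new_pos: dict[int, np.ndarray] = {}
        for v in em.vertex_faces:
            nbrs = em.neighbors(v)
            if not nbrs:
                continue
            if v in boundary:
                bnbrs = [n for n in nbrs if em.is_boundary_edge(v, n)]
                if len(bnbrs) != 2:
                    continue
                g = 0.5 * (em.pos[bnbrs[0]] + em.pos[bnbrs[1]])
                new_pos[v] = em.pos[v] + params.smoothing_weight * (g - em.pos[v])
            else:
                g = np.mean([em.pos[n] for n in nbrs], axis=0)
                n = np.zeros(3)
                for fid in em.vertex_faces[v]:
                    n += em.face_normal(em.faces[fid])
                nl = np.linalg.norm(n)
                if nl > 0:
                    n /= nl
                d = g - em.pos[v]
                d -= np.dot(d, n) * n
                new_pos[v] = em.pos[v] + params.smoothing_weight * d
        for v, p in new_pos.items():
            em.pos[v] = p

        vids = sorted(em.vertex_faces)
        pts = np.asarray([em.pos[v] for v in vids])
        on_boundary = np.asarray([v in boundary for v in vids])
        if on_boundary.any() and boundary_idx is not None:
            cp, _ = boundary_idx.query(pts[on_boundary])
            for v, p in zip(np.asarray(vids)[on_boundary], cp):
                em.pos[v] = p
        interior = ~on_boundary
        if interior.any():
            cp, _, _ = surface.query(pts[interior])
            for v, p in zip(np.asarray(vids)[interior], cp):
                em.pos[v] = p

    v, f = em.to_arrays()
    out = SurfaceMesh(v, f, closed=len(mesh.boundary_edges()) == 0)
    log.info("remesh: %d->%d vertices, %d->%d faces (h=%.3g)",
             mesh.n_vertices, out.n_vertices, mesh.n_faces, out.n_faces, h)
    return out
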