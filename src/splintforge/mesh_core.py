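"""Mesh data model, STL/OBJ I/O, validation, and wireframe extraction.

The pipeline's central containers are :class:`SurfaceMesh` — an indexed
triangle mesh in millimetres — and :class:`LatticeGraph`, the wireframe whose
edges become the centerlines of the printed bars.  File parsing is delegated
to :mod:`trimesh`; the OBJ writer emits minimal ``v``/``f`` records because
that is all downstream stages consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from ._spatial import intersecting_triangle_pairs

log = logging.getLogger(__name__)

WELD_TOLERANCE_MM = 1e-4  # far below 0.2 mm FDM layer resolution


class MeshFormatError(ValueError):
    """Unreadable or unsupported mesh file."""


class MeshValidationError(ValueError):
    """Mesh violates a structural precondition."""


@dataclass
class SurfaceMesh:
    """Indexed triangle mesh; coordinates in mm, per-face winding outward.

    ``closed`` is a declaration of intent ("this mesh should be watertight"),
    checked by :func:`validate_mesh`, not enforced on construction.
    """

    vertices: np.ndarray  # (V, 3) float64
    faces: np.ndarray     # (F, 3) int64
    closed: bool = False

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be (F, 3)")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshValidationError("face index out of range")

    # -- basic derived quantities -------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.face_areas().sum())

    def edges_unique(self) -> np.ndarray:
        """Unique undirected edges, each row sorted (low, high)."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def boundary_edges(self) -> np.ndarray:
        """Edges used by exactly one face."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def boundary_loops(self) -> list[np.ndarray]:
        """Boundary polylines as ordered vertex-index loops."""
        edges = self.boundary_edges()
        if len(edges) == 0:
            return []
        adj: dict[int, list[int]] = {}
        for a, b in edges:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        seen = set()
        loops = []
        for start in sorted(adj):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            prev, cur = None, start
            while True:
                nxts = [n for n in adj[cur] if n != prev]
                if not nxts:
                    break
                nxt = nxts[0]
                if nxt == start:
                    break
                loop.append(nxt)
                seen.add(nxt)
                prev, cur = cur, nxt
            loops.append(np.asarray(loop, dtype=np.int64))
        return loops

    def volume(self) -> float:
        """Signed enclosed volume (divergence theorem); meaningful when closed."""
        t = self.triangles()
        return float(np.einsum("ij,ij->i", t[:, 0],
                               np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.closed)


@dataclass
class LatticeGraph:
    """Wireframe of the splint: node positions plus unique undirected edges.

    Edges are the centerlines of the printed bars.  An optional back-reference
    to the source mesh faces lets quality statistics use triangles.
    """

    nodes: np.ndarray            # (N, 3) float64
    edges: np.ndarray            # (E, 2) int64, each row sorted
    source_faces: np.ndarray | None = None

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.edges = np.ascontiguousarray(self.edges, dtype=np.int64)
        if len(self.edges):
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise MeshValidationError("lattice contains a self-loop edge")
            canon = np.sort(self.edges, axis=1)
            if len(np.unique(canon, axis=0)) != len(canon):
                raise MeshValidationError("lattice contains duplicate edges")
            self.edges = canon
            used = np.unique(self.edges)
            if len(used) != len(self.nodes):
                raise MeshValidationError("lattice has unused nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_lengths(self) -> np.ndarray:
        d = self.nodes[self.edges[:, 0]] - self.nodes[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def is_connected(self) -> bool:
        if self.n_nodes <= 1:
            return True
        m = coo_matrix(
            (np.ones(self.n_edges), (self.edges[:, 0], self.edges[:, 1])),
            shape=(self.n_nodes, self.n_nodes),
        )
        n_comp, _ = connected_components(m, directed=False)
        return n_comp == 1


@dataclass
class ValidationReport:
    watertight: bool
    winding_consistent: bool
    boundary_loop_count: int
    nonmanifold_edge_count: int
    self_intersection_count: int
    volume_mm3: float | None
    n_vertices: int = 0
    n_faces: int = 0
    notes: list[str] = field(default_factory=list)

    def ok(self, expect_closed: bool) -> bool:
        if self.nonmanifold_edge_count > 0:
            return False
        if expect_closed:
            return (self.watertight and self.winding_consistent
                    and self.boundary_loop_count == 0
                    and (self.volume_mm3 or 0.0) > 0.0)
        return self.boundary_loop_count > 0


def weld_vertices(vertices: np.ndarray, faces: np.ndarray,
                  tolerance: float = WELD_TOLERANCE_MM):
    """Merge vertices closer than ``tolerance`` (grid quantization) and drop
    degenerate faces.  Returns (vertices, faces)."""
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    key = np.round(vertices / tolerance).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True,
                                  return_inverse=True)
    order = np.argsort(first)          # keep original vertex order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = vertices[first[order]]
    new_faces = rank[inverse][faces]
    keep = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 2] != new_faces[:, 0])
    )
    return new_vertices, new_faces[keep]


def read_mesh(path, format: str = "auto") -> SurfaceMesh:
    """Read an STL (binary or ASCII) or OBJ mesh.

    Duplicate vertices within the weld tolerance are merged so STL facet
    soups regain shared connectivity.
    """
    path = str(path)
    if format == "auto":
        lower = path.lower()
        if lower.endswith(".stl"):
            format = "stl"
        elif lower.endswith(".obj"):
            format = "obj"
        else:
            raise MeshFormatError(f"cannot infer format of {path!r}")
    if format not in ("stl", "obj"):
        raise MeshFormatError(f"unsupported format {format!r}")
    try:
        loaded = trimesh.load(path, file_type=format, process=False,
                              force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise MeshFormatError(f"could not parse {path!r}: {exc}") from exc
    if loaded is None or len(loaded.faces) == 0:
        raise MeshValidationError(f"{path!r} contains no faces")
    v, f = weld_vertices(np.asarray(loaded.vertices), np.asarray(loaded.faces))
    mesh = SurfaceMesh(v, f)
    log.info("read %s: %d vertices, %d faces", path, mesh.n_vertices,
             mesh.n_faces)
    return mesh


def write_mesh(mesh: SurfaceMesh, path, format: str = "auto") -> None:
    """Write STL (binary) or OBJ (``v``/``f`` records only)."""
    if mesh.n_faces == 0:
        raise MeshValidationError("refusing to write an empty mesh")
    path = str(path)
    if format == "auto":
        lower = path.lower()
        format = "stl" if lower.endswith(".stl") else "obj" \
            if lower.endswith(".obj") else None
        if format is None:
            raise MeshFormatError(f"cannot infer format of {path!r}")
    if format == "stl":
        if len(mesh.boundary_edges()) > 0:
            log.warning("writing open shell %s as STL: not printable as-is",
                        path)
        mesh.to_trimesh().export(path, file_type="stl")
    elif format == "obj":
        with open(path, "w") as fh:
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in mesh.faces + 1:   # OBJ is 1-based
                fh.write(f"f {f[0]} {f[1]} {f[2]}\n")
    else:
        raise MeshFormatError(f"unsupported format {format!r}")


def validate_mesh(mesh: SurfaceMesh, expect_closed: bool = False,
                  check_self_intersections: bool = False) -> ValidationReport:
    """Structural report: watertightness, boundary loops, manifoldness,
    enclosed volume, and (optionally) a sampled self-intersection count."""
    tm = mesh.to_trimesh()
    e = np.sort(np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]],
                           mesh.faces[:, [2, 0]]]), axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    nonmanifold = int((counts > 2).sum())
    loops = mesh.boundary_loops()
    watertight = bool(tm.is_watertight)
    winding = bool(tm.is_winding_consistent)
    volume = float(tm.volume) if watertight else None
    n_self = 0
    if check_self_intersections:
        n_self = len(intersecting_triangle_pairs(mesh.vertices, mesh.faces))
    report = ValidationReport(
        watertight=watertight,
        winding_consistent=winding,
        boundary_loop_count=len(loops),
        nonmanifold_edge_count=nonmanifold,
        self_intersection_count=n_self,
        volume_mm3=volume,
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
    )
    if expect_closed and not report.ok(True):
        report.notes.append("expected closed mesh fails watertightness")
    return report


def extract_lattice(mesh: SurfaceMesh) -> LatticeGraph:
    """Wireframe of a mesh: nodes are vertices, edges are unique mesh edges.

    Unreferenced vertices are dropped so the lattice invariant (every node
    used by at least one edge) holds.
    """
    edges = mesh.edges_unique()
    used = np.unique(mesh.faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    faces = remap[mesh.faces]
    return LatticeGraph(mesh.vertices[used], remap[edges],
                        source_faces=faces)
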