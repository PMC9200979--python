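"""Triangle-mesh data model, OBJ/PLY I/O and closed-surface geometry.

Everything downstream (calibration, trait extraction, dissection) runs on
:class:`TriangleMesh`: an indexed triangle surface with a physical scale
attached.  Volumes use the divergence theorem on signed tetrahedra, so they
require a watertight, consistently outward-oriented surface.

Coordinate convention for crowns is right-handed with +Z pointing from the
root tips toward the stem and the soil line at z = 0; raw photogrammetry
exports arrive in an arbitrary frame and are restored by the preparation
module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import trimesh as _tm

from .errors import EmptyMeshError, MeshFormatError, NotWatertightError
from .triangulate import triangulate_rings

log = logging.getLogger(__name__)

_DEDUP_DECIMALS = 9  # vertices within 1e-9 model units are merged at load
_DEGENERATE_AREA = 1e-12


@dataclass
class Plane:
    """Oriented plane given by a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be non-zero")
        self.normal = n / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.point) @ self.normal


@dataclass
class TriangleMesh:
    """Indexed triangle surface with a physical length scale.

    ``unit_scale`` is the physical length (cm) of one model unit; it is 1.0
    once a mesh has been calibrated against the reference object.
    """

    vertices: np.ndarray
    faces: np.ndarray
    unit_scale: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or (len(self.vertices) and
                                       self.vertices.shape[1] != 3):
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or (len(self.faces) and
                                    self.faces.shape[1] != 3):
            raise ValueError("faces must be an (m, 3) array")
        if len(self.faces) and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    # -- basic queries ----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    @property
    def bounds(self) -> np.ndarray:
        if self.is_empty:
            raise EmptyMeshError("empty mesh has no bounds")
        used = self.vertices[np.unique(self.faces)]
        return np.vstack([used.min(axis=0), used.max(axis=0)])

    @property
    def extents(self) -> np.ndarray:
        b = self.bounds
        return b[1] - b[0]

    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def edges_sorted(self) -> np.ndarray:
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        return np.sort(e, axis=1)

    @property
    def is_watertight(self) -> bool:
        """Strict edge-manifold closure: every edge in exactly two faces."""
        if self.is_empty:
            return False
        _, counts = np.unique(self.edges_sorted(), axis=0, return_counts=True)
        return bool((counts == 2).all())

    def boundary_loops(self) -> list[np.ndarray]:
        """Closed chains of boundary vertices, following face orientation."""
        if self.is_empty:
            return []
        directed = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                              self.faces[:, [2, 0]]])
        keys = {(int(a), int(b)) for a, b in directed}
        boundary = [(b, a) for (a, b) in keys if (b, a) not in keys]
        succ: dict[int, list[int]] = {}
        for a, b in boundary:
            succ.setdefault(a, []).append(b)
        loops = []
        while succ:
            start = next(iter(succ))
            loop = [start]
            cur = start
            while True:
                nxts = succ.get(cur)
                if not nxts:
                    break
                nxt = nxts.pop()
                if not nxts:
                    del succ[cur]
                if nxt == start:
                    break
                loop.append(nxt)
                cur = nxt
            if len(loop) >= 3:
                loops.append(np.array(loop, dtype=np.int64))
        return loops

    # -- transforms -------------------------------------------------------
    def transformed(self, matrix: np.ndarray) -> "TriangleMesh":
        """Apply a 4x4 homogeneous transform to the vertices."""
        m = np.asarray(matrix, dtype=float)
        v = self.vertices @ m[:3, :3].T + m[:3, 3]
        return replace(self, vertices=v, faces=self.faces.copy())

    def scaled(self, factor: float) -> "TriangleMesh":
        return replace(self, vertices=self.vertices * float(factor),
                       faces=self.faces.copy())

    def copy(self) -> "TriangleMesh":
        return replace(self, vertices=self.vertices.copy(),
                       faces=self.faces.copy())

    # -- interop ----------------------------------------------------------
    def to_trimesh(self) -> _tm.Trimesh:
        return _tm.Trimesh(vertices=self.vertices.copy(),
                           faces=self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh: _tm.Trimesh, unit_scale: float = 1.0,
                     label: str = "") -> "TriangleMesh":
        return cls(vertices=np.asarray(mesh.vertices, dtype=float),
                   faces=np.asarray(mesh.faces, dtype=np.int64),
                   unit_scale=unit_scale, label=label)


# -- cleaning -------------------------------------------------------------

def _dedup_and_clean(vertices: np.ndarray, faces: np.ndarray,
                     label: str) -> TriangleMesh:
    """Merge vertices within 1e-9 model units, drop degenerate faces."""
    if len(faces) == 0:
        raise EmptyMeshError(f"{label or 'mesh'}: no faces")
    rounded = np.round(vertices, _DEDUP_DECIMALS)
    uniq, inverse = np.unique(rounded, axis=0, return_inverse=True)
    faces = inverse[faces]
    # drop faces with repeated vertices
    ok = ((faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2])
          & (faces[:, 2] != faces[:, 0]))
    faces = faces[ok]
    if len(faces):
        tri = uniq[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        n_deg = int((areas < _DEGENERATE_AREA).sum())
        if n_deg:
            log.info("%s: removed %d degenerate faces", label or "mesh", n_deg)
        faces = faces[areas >= _DEGENERATE_AREA]
    if len(faces) == 0:
        raise EmptyMeshError(f"{label or 'mesh'}: no non-degenerate faces")
    used = np.unique(faces)
    remap = -np.ones(len(uniq), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(vertices=uniq[used], faces=remap[faces], label=label)


# -- I/O ------------------------------------------------------------------

def _read_obj(path: str) -> tuple[np.ndarray, np.ndarray]:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tag, *rest = line.split()
            if tag == "v":
                if len(rest) < 3:
                    raise MeshFormatError(
                        f"{path}:{lineno}: vertex needs 3 coordinates")
                try:
                    verts.append([float(x) for x in rest[:3]])
                except ValueError as exc:
                    raise MeshFormatError(
                        f"{path}:{lineno}: bad vertex coordinate") from exc
            elif tag == "f":
                idx = []
                for tok in rest:
                    head = tok.split("/")[0]
                    try:
                        i = int(head)
                    except ValueError as exc:
                        raise MeshFormatError(
                            f"{path}:{lineno}: bad face index {tok!r}") from exc
                    if i == 0:
                        raise MeshFormatError(
                            f"{path}:{lineno}: OBJ face indices are 1-based, "
                            "got 0")
                    idx.append(i - 1 if i > 0 else len(verts) + i)
                if len(idx) < 3:
                    raise MeshFormatError(
                        f"{path}:{lineno}: face needs at least 3 vertices")
                for k in range(1, len(idx) - 1):  # fan-triangulate n-gons
                    faces.append([idx[0], idx[k], idx[k + 1]])
            # vn/vt/usemtl/o/g/s lines parsed and discarded
    if not verts:
        raise MeshFormatError(f"{path}: no vertex data found")
    v = np.asarray(verts, dtype=float)
    f = np.asarray(faces, dtype=np.int64) if faces else np.empty((0, 3),
                                                                 np.int64)
    if len(f) and (f.min() < 0 or f.max() >= len(v)):
        raise MeshFormatError(f"{path}: face references missing vertex")
    return v, f


def read_mesh(path: str, fmt: str | None = None) -> TriangleMesh:
    """Read an OBJ or PLY file into a cleaned, triangulated mesh.

    Polygonal faces are fan-triangulated; duplicate vertices are merged
    within 1e-9 model units; ``unit_scale`` starts at 1.0 (uncalibrated).
    """
    p = str(path)
    fmt = (fmt or p.rsplit(".", 1)[-1]).lower()
    if fmt == "obj":
        v, f = _read_obj(p)
        return _dedup_and_clean(v, f, label=p)
    if fmt == "ply":
        try:
            loaded = _tm.load(p, file_type="ply", process=False, force="mesh")
        except Exception as exc:
            raise MeshFormatError(f"{p}: unreadable PLY ({exc})") from exc
        if loaded.faces.shape[0] == 0:
            raise EmptyMeshError(f"{p}: PLY contains no faces")
        return _dedup_and_clean(np.asarray(loaded.vertices),
                                np.asarray(loaded.faces, dtype=np.int64), p)
    raise MeshFormatError(f"{p}: unsupported format {fmt!r}")


def write_mesh(mesh: TriangleMesh, path: str, fmt: str | None = None) -> None:
    """Write OBJ (native) or ASCII PLY (via trimesh)."""
    if mesh.is_empty:
        raise EmptyMeshError("refusing to write an empty mesh")
    p = str(path)
    fmt = (fmt or p.rsplit(".", 1)[-1]).lower()
    if fmt == "obj":
        with open(p, "w", encoding="utf-8") as fh:
            if mesh.label:
                fh.write(f"# {mesh.label}\n")
            for v in mesh.vertices:
                # full precision: lossy coordinates can merge distinct
                # vertices on re-read and open the surface
                fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    elif fmt == "ply":
        mesh.to_trimesh().export(p, file_type="ply", encoding="ascii")
    else:
        raise MeshFormatError(f"{p}: unsupported format {fmt!r}")


# -- geometry -------------------------------------------------------------

def signed_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (cm^3) of a watertight, outward-oriented mesh.

    Divergence-theorem sum of signed tetrahedra spanned by the origin and
    each face, scaled by ``unit_scale`` cubed.
    """
    if mesh.is_empty:
        raise EmptyMeshError("cannot compute volume of an empty mesh")
    if not mesh.is_watertight:
        raise NotWatertightError(
            "mesh is not watertight; repair with close_holes first")
    tri = mesh.triangles()
    vol = np.einsum("ij,ij->", tri[:, 0],
                    np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(vol) * mesh.unit_scale ** 3


def surface_area(mesh: TriangleMesh) -> float:
    """Total triangle area (cm^2), scaled by ``unit_scale`` squared."""
    if mesh.is_empty:
        raise EmptyMeshError("cannot compute area of an empty mesh")
    tri = mesh.triangles()
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    return float(areas.sum()) * mesh.unit_scale ** 2


def connected_components(mesh: TriangleMesh) -> list[TriangleMesh]:
    """Partition faces into edge-connected components (largest first)."""
    if mesh.is_empty:
        return []
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components as _cc

    edges = mesh.edges_sorted()
    face_idx = np.tile(np.arange(mesh.n_faces), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges_s, face_s = edges[order], face_idx[order]
    same = (edges_s[:-1] == edges_s[1:]).all(axis=1)
    a, b = face_s[:-1][same], face_s[1:][same]
    n = mesh.n_faces
    adj = coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
    n_comp, labels = _cc(adj, directed=False)
    out = []
    for c in range(n_comp):
        faces_c = mesh.faces[labels == c]
        used = np.unique(faces_c)
        remap = -np.ones(mesh.n_vertices, dtype=np.int64)
        remap[used] = np.arange(len(used))
        out.append(TriangleMesh(vertices=mesh.vertices[used],
                                faces=remap[faces_c],
                                unit_scale=mesh.unit_scale,
                                label=mesh.label))
    out.sort(key=lambda m: m.n_faces, reverse=True)
    return out


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0,
                                                                    0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def cap_planar_boundaries(mesh: TriangleMesh, plane: Plane,
                          tol: float = 1e-8) -> TriangleMesh:
    """Cap boundary loops lying on ``plane`` with ear-clipped cross-sections.

    Nested loops (annular sections) are resolved even-odd.  Cap triangles
    reuse the existing boundary vertices, so the join is exactly watertight,
    and are oriented outward: toward -normal when the surface lies on the
    positive side of the plane.
    """
    loops = mesh.boundary_loops()
    scale = float(np.linalg.norm(mesh.extents))
    on_plane = []
    for loop in loops:
        d = plane.signed_distance(mesh.vertices[loop])
        if np.abs(d).max() <= max(tol * scale, 1e-9):
            on_plane.append(loop)
    if not on_plane:
        return mesh
    u, v = _plane_basis(plane.normal)
    rel = mesh.vertices - plane.point
    pts2d = np.column_stack([rel @ u, rel @ v])
    tris = triangulate_rings(pts2d, on_plane)
    if len(tris) == 0:
        return mesh
    # CCW triangles in the (u, v) frame face +normal (u x v = normal);
    # flip when the surface sits on the positive side so caps face outward.
    side = float(np.mean(plane.signed_distance(mesh.vertices)))
    if side > 0:
        tris = tris[:, ::-1]
    new_f = np.vstack([mesh.faces, tris])
    return TriangleMesh(mesh.vertices.copy(), new_f, mesh.unit_scale,
                        mesh.label)


def plane_cut(mesh: TriangleMesh,
              plane: Plane) -> tuple[TriangleMesh, TriangleMesh]:
    """Cut a watertight mesh, returning capped (front, back) halves.

    Front is the side the plane normal points into.  Volumes of the two
    closed halves sum to the input volume.  A plane missing the mesh
    returns the input and an empty mesh.
    """
    if mesh.is_empty:
        raise EmptyMeshError("cannot cut an empty mesh")
    d = plane.signed_distance(mesh.vertices)
    empty = TriangleMesh(np.empty((0, 3)), np.empty((0, 3), dtype=np.int64),
                         mesh.unit_scale, mesh.label)
    if (d >= 0).all():
        return mesh.copy(), empty
    if (d <= 0).all():
        return empty, mesh.copy()
    if not mesh.is_watertight:
        raise NotWatertightError("plane_cut requires a watertight mesh")
    front = slice_open(mesh, plane, keep_positive=True)
    back = slice_open(mesh, plane, keep_positive=False)
    front = cap_planar_boundaries(front, plane)
    back = cap_planar_boundaries(back, plane)
    return front, back


def slice_open(mesh: TriangleMesh, plane: Plane,
               keep_positive: bool) -> TriangleMesh:
    """Slice off one side of the plane without capping (works on open
    meshes); keeps the positive-normal side when ``keep_positive``."""
    tm = mesh.to_trimesh()
    n = plane.normal if keep_positive else -plane.normal
    sliced = _tm.intersections.slice_mesh_plane(
        tm, plane_normal=n, plane_origin=plane.point, cap=False)
    if sliced is None or len(sliced.faces) == 0:
        return TriangleMesh(np.empty((0, 3)),
                            np.empty((0, 3), dtype=np.int64),
                            mesh.unit_scale, mesh.label)
    return _dedup_and_clean(np.asarray(sliced.vertices),
                            np.asarray(sliced.faces, dtype=np.int64),
                            mesh.label)
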