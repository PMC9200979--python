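"""Turn a raw photogrammetry export into an analysis-ready crown.

The pipeline mirrors the manual modelling workflow: clear floating noise
components, close holes by volumetric remeshing, rescale against the
cuboid reference object, restore the canonical crown frame (+Z from root
tips toward the stem, soil line at z = 0) and remove the stem section.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh as _tm
from scipy import ndimage
from skimage.measure import marching_cubes

from . import _voxel
from .errors import (CalibrationError, CrownPhenoError, EmptyMeshError,
                     OrientationError)
from .mesh import Plane, TriangleMesh, plane_cut

log = logging.getLogger(__name__)

#: known reference-box dimensions (cm), sorted ascending
DEFAULT_REFERENCE_DIMS_CM = (12.5, 12.5, 34.0)
DEFAULT_OCTREE_DEPTH = 8


@dataclass
class CalibrationResult:
    """Outcome of reference-object scale calibration."""

    scale_factor: float  # cm per model unit
    reference_dims_measured: np.ndarray  # sorted OBB extents after scaling
    reference_dims_known: np.ndarray  # sorted known extents (cm)


def remove_noise_components(mesh: TriangleMesh,
                            min_fraction: float = 0.01) -> TriangleMesh:
    """Drop floating components smaller than ``min_fraction`` of the largest
    component's face count."""
    if mesh.is_empty:
        raise EmptyMeshError("cannot denoise an empty mesh")
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must be in (0, 1)")
    from .mesh import connected_components

    comps = connected_components(mesh)
    cutoff = min_fraction * comps[0].n_faces
    keep = [c for c in comps if c.n_faces >= cutoff]
    removed = len(comps) - len(keep)
    if removed:
        log.info("%s: removed %d noise components",
                 mesh.label or "mesh", removed)
    if len(keep) == 1:
        out = keep[0]
        return TriangleMesh(out.vertices, out.faces, mesh.unit_scale,
                            mesh.label)
    verts = np.vstack([c.vertices for c in keep])
    offs = np.cumsum([0] + [c.n_vertices for c in keep[:-1]])
    faces = np.vstack([c.faces + o for c, o in zip(keep, offs)])
    return TriangleMesh(verts, faces, mesh.unit_scale, mesh.label)


def _fan_cap_boundaries(mesh: TriangleMesh) -> TriangleMesh:
    """Topologically close every boundary loop with a centroid fan.

    Winding of the fans is irrelevant downstream: the voxel stage uses
    crossing parity only.
    """
    loops = mesh.boundary_loops()
    if not loops:
        return mesh
    verts = [mesh.vertices]
    faces = [mesh.faces]
    nv = mesh.n_vertices
    for loop in loops:
        pts = mesh.vertices[loop]
        centroid = pts.mean(axis=0)
        verts.append(centroid[None, :])
        n = len(loop)
        fan = np.column_stack([loop, np.roll(loop, -1),
                               np.full(n, nv, dtype=np.int64)])
        faces.append(fan)
        nv += 1
    return TriangleMesh(np.vstack(verts), np.vstack(faces),
                        mesh.unit_scale, mesh.label)


def close_holes(mesh: TriangleMesh, octree_depth: int = DEFAULT_OCTREE_DEPTH,
                closing_radius: int = 3,
                smooth_iterations: int = 8) -> TriangleMesh:
    """Produce a watertight surface by volumetric remeshing.

    Boundary loops are first capped so the surface encloses a region, then
    the solid is voxelized at pitch = bounding-box diagonal / 2**depth,
    morphologically closed (``closing_radius`` voxels, which amalgamates
    crevices narrower than the kernel — the resolution-dependent bias the
    split-half protocol mitigates), internal pockets are filled, and the
    isosurface is re-extracted and smoothed.
    """
    if mesh.is_empty:
        raise EmptyMeshError("cannot close holes of an empty mesh")
    capped = _fan_cap_boundaries(mesh)
    diag = float(np.linalg.norm(capped.extents))
    if diag <= 0:
        raise CrownPhenoError("degenerate mesh: zero extent")
    nominal = diag / (2 ** octree_depth)
    ext = capped.extents
    # per-axis pitch snapped to the bounding box so both bbox faces sit
    # exactly midway between voxel centers: planar caps flush with the box
    # (stem cut, split cross-section) are then placed exactly by the
    # isosurface instead of being shaved by up to half a voxel
    n_cells = np.maximum(np.round(ext / nominal).astype(int), 1)
    pitch = np.where(ext > 1e-12, ext / n_cells, nominal)
    margin = closing_radius + 2
    lo = capped.bounds[0] - (margin + 0.5) * pitch
    shape = tuple(int(n_cells[i]) + 2 * margin + 2 for i in range(3))
    occ = _voxel.occupancy(capped.vertices, capped.faces, lo, pitch, shape)
    if occ.sum() < 8:
        raise CrownPhenoError("no enclosed volume: surface does not bound "
                              "a solid region")
    if closing_radius > 0:
        r = closing_radius
        zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
        ball = (xx ** 2 + yy ** 2 + zz ** 2) <= r ** 2
        occ = ndimage.binary_closing(occ, structure=ball)
    occ = ndimage.binary_fill_holes(occ)
    # very mild field smoothing resolves marching-cubes ambiguities while
    # keeping the level-0.5 surface on the voxel boundary (volume change on
    # closed inputs stays well under 1%); surface fairing is done on the
    # extracted mesh by Taubin's shrink-free filter
    field = ndimage.gaussian_filter(occ.astype(np.float32), sigma=0.4)
    verts, faces, _, _ = marching_cubes(field, level=0.5,
                                        spacing=tuple(pitch))
    verts = verts + lo
    out = _tm.Trimesh(vertices=verts, faces=faces, process=True)
    if smooth_iterations > 0:
        _tm.smoothing.filter_taubin(out, iterations=smooth_iterations)
    if out.fill_holes() is False or not out.is_watertight:
        # rare marching-cubes pinholes: retry on the raw binary field
        verts, faces, _, _ = marching_cubes(occ.astype(np.float32),
                                            level=0.5,
                                            spacing=tuple(pitch))
        out = _tm.Trimesh(vertices=verts + lo, faces=faces, process=True)
        out.fill_holes()
    result = TriangleMesh(np.asarray(out.vertices),
                          np.asarray(out.faces, dtype=np.int64),
                          mesh.unit_scale, mesh.label)
    # marching cubes may emit inward orientation; enforce positive volume
    if result.is_watertight:
        tri = result.triangles()
        vol = np.einsum("ij,ij->", tri[:, 0],
                        np.cross(tri[:, 1], tri[:, 2])) / 6.0
        if vol < 0:
            result = TriangleMesh(result.vertices, result.faces[:, ::-1],
                                  result.unit_scale, result.label)
    return result


def calibrate_scale(scene: TriangleMesh, reference: TriangleMesh,
                    known_dim_cm: float, dim_selector: str = "longest",
                    ) -> tuple[TriangleMesh, CalibrationResult]:
    """Rescale a scene so the reference box matches its known dimension.

    The reference extents come from its minimal oriented bounding box,
    because the box lies at arbitrary pose in the scene.
    """
    if reference.is_empty:
        raise CalibrationError("reference mesh is empty")
    if known_dim_cm <= 0:
        raise CalibrationError("known dimension must be positive")
    obb = reference.to_trimesh().bounding_box_oriented
    extents = np.sort(np.asarray(obb.primitive.extents, dtype=float))
    if extents[0] <= 0 or not np.all(np.isfinite(extents)):
        raise CalibrationError("reference mesh is degenerate")
    selector = {"shortest": 0, "middle": 1, "longest": 2}
    if dim_selector not in selector:
        raise CalibrationError(f"unknown dim_selector {dim_selector!r}")
    measured = extents[selector[dim_selector]]
    scale = known_dim_cm / measured
    scaled_scene = TriangleMesh(scene.vertices * scale, scene.faces.copy(),
                                unit_scale=1.0, label=scene.label)
    result = CalibrationResult(
        scale_factor=scale,
        reference_dims_measured=extents * scale,
        reference_dims_known=np.sort(
            np.asarray(DEFAULT_REFERENCE_DIMS_CM, dtype=float)),
    )
    log.info("%s: calibrated, scale=%.6g cm/unit", scene.label or "scene",
             scale)
    return scaled_scene, result


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c < -1 + 1e-12:
        # 180 degrees: rotate about any perpendicular axis
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _tm.transformations.rotation_matrix(np.pi, axis)[:3, :3]
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def _fibonacci_sphere(n: int = 96) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])


def _hub_center(verts: np.ndarray, iters: int = 15) -> np.ndarray:
    """Mean-shift toward the density peak: the hub where roots and the
    stem converge carries the highest local surface density."""
    span = float(np.linalg.norm(verts.max(axis=0) - verts.min(axis=0)))
    radius = 0.25 * span
    c = verts.mean(axis=0)
    for _ in range(iters):
        d2 = ((verts - c) ** 2).sum(axis=1)
        sel = verts[d2 < radius ** 2]
        if len(sel) < 10:
            break
        nc = sel.mean(axis=0)
        if np.linalg.norm(nc - c) < 1e-6 * span:
            c = nc
            break
        c = nc
        radius = max(0.6 * radius, 0.08 * span)
    return c


def _radius_profile(verts: np.ndarray, center: np.ndarray, u: np.ndarray,
                    probe: float, bin_w: float = 1.5):
    """Per-bin centered median radius profile of the extreme protrusion
    along ``u``; returns (fractional taper, mean radius, bin centroids)."""
    proj = (verts - center) @ u
    pmax = proj.max()
    mask = proj > pmax - probe
    if mask.sum() < 30:
        return None
    pts = verts[mask]
    p = proj[mask]
    lat = (pts - center) - np.outer(p, u)
    n_bins = max(int(np.ceil(probe / bin_w)), 3)
    edges = np.linspace(pmax - probe, pmax, n_bins + 1)
    radii, centroids, dispersion = [], [], 0.0
    for b in range(n_bins):
        sel = (p >= edges[b]) & (p < edges[b + 1] + (b == n_bins - 1))
        if sel.sum() < 8:
            return None  # sparse or broken protrusion
        lb = lat[sel]
        cb = lb.mean(axis=0)
        rr = np.linalg.norm(lb - cb, axis=1)
        r_b = float(np.median(rr))
        # a tube's cross-section radii concentrate tightly; a slab that
        # catches several root tips scatters them
        mad = float(np.median(np.abs(rr - r_b)))
        dispersion = max(dispersion, mad / max(r_b, 1e-9))
        radii.append(r_b)
        mid = 0.5 * (edges[b] + edges[b + 1])
        centroids.append(center + mid * u + cb)
    radii = np.array(radii)
    mean_r = float(radii.mean())
    slope = np.polyfit(0.5 * (edges[:-1] + edges[1:]), radii, 1)[0]
    taper = abs(float(slope)) * probe / max(mean_r, 1e-9)
    return taper, mean_r, np.asarray(centroids), dispersion


def _stem_axis_estimate(verts: np.ndarray, probe: float = 6.0,
                        max_stem_radius: float = 4.0,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Locate the stem stub: the only protrusion with a constant radius.

    Rays from the hub density peak are scanned over a sphere; for each,
    the extreme slab's median-radius profile is fit — storage-root tips
    taper toward the tip while the stem stub is a near-constant-radius
    cylinder no thicker than ``max_stem_radius`` cm.  The winning
    direction is refined by the line through the slab's cross-section
    centroids.  Raises OrientationError when no cylinder-like protrusion
    exists.
    """
    span = float(np.linalg.norm(verts.max(axis=0) - verts.min(axis=0)))
    probe = min(probe, 0.3 * span)
    hub = _hub_center(verts)
    best, best_taper = None, np.inf
    for u in _fibonacci_sphere(128):
        res = _radius_profile(verts, hub, u, probe)
        if res is None:
            continue
        taper, mean_r, _, disp = res
        if mean_r > max_stem_radius or disp > 0.6:
            continue  # too thick or not a single tube
        score = taper + 0.5 * disp  # a real stem is low on both
        if score < best_taper:
            best_taper, best = score, u
    if best is None or best_taper > 0.45:
        raise OrientationError(
            "no identifiable stem stub (no constant-radius protrusion); "
            "supply stem_axis")
    axis = best.astype(float)
    point = hub
    for _ in range(3):  # refine: line through cross-section centroids
        res = _radius_profile(verts, hub, axis, probe)
        if res is None:
            break
        _, _, cents, _ = res
        d = cents[-1] - cents[0]
        norm = np.linalg.norm(d)
        if norm < 1e-9 or (d / norm) @ axis < np.cos(np.radians(40)):
            break
        axis = d / norm
        point = cents.mean(axis=0)
    return axis, point


def orient_crown(mesh: TriangleMesh,
                 stem_axis: tuple[np.ndarray, np.ndarray] | None = None,
                 ) -> TriangleMesh:
    """Rigidly transform a crown into the canonical frame.

    The stem axis is aligned to +Z and the soil line (stem-crown junction,
    where the cross-section widens from the stem radius to the crown) is
    placed at z = 0.  ``stem_axis`` optionally overrides detection with
    (point_on_crown, point_on_stem_tip).
    """
    if mesh.is_empty:
        raise EmptyMeshError("cannot orient an empty mesh")
    verts = mesh.vertices
    if stem_axis is not None:
        p0, p1 = (np.asarray(x, dtype=float) for x in stem_axis)
        axis = p1 - p0
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise OrientationError("stem_axis points coincide")
        axis = axis / norm
        origin = verts.mean(axis=0)
    else:
        axis, origin = _stem_axis_estimate(verts)
    rot = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))
    v = (verts - origin) @ rot.T
    # junction scan: walk down from the stem tip recording where the
    # cross-section first widens past 1.3x and 1.8x the stem radius;
    # since the crown shoulder widens smoothly, the junction is placed
    # at the apex of the circle through those two widening points
    # (exact for a spherical shoulder, a small consistent offset
    # otherwise) rather than at the threshold crossing itself
    z = v[:, 2]
    z_top, z_bot = z.max(), z.min()
    step = max((z_top - z_bot) / 150.0, 1e-6)
    top_slab = v[z > z_top - 5 * step]
    r_stem = max(np.percentile(np.hypot(top_slab[:, 0], top_slab[:, 1]),
                               90), 1e-9)
    marks: dict[float, tuple[float, float]] = {}
    zc = z_top - 5 * step
    while zc > z_bot and len(marks) < 2:
        slab = v[(z > zc - step) & (z <= zc)]
        if len(slab) >= 5:
            r = float(np.percentile(np.hypot(slab[:, 0], slab[:, 1]), 98))
            for thresh in (1.3, 1.8):
                if thresh not in marks and r > thresh * r_stem:
                    marks[thresh] = (zc - 0.5 * step, r)
        zc -= step
    if 1.3 in marks:
        junction = marks[1.3][0]
        if 1.8 in marks and marks[1.8][0] < marks[1.3][0]:
            (z1, r1), (z2, r2) = marks[1.3], marks[1.8]
            c = ((z1 ** 2 - z2 ** 2) - (r2 ** 2 - r1 ** 2)) \
                / (2.0 * (z1 - z2))
            rad2 = (c - z1) ** 2 + r1 ** 2
            if c < z1 and rad2 > 0:
                apex = c + np.sqrt(rad2)
                if z1 <= apex <= z1 + 3.0:
                    junction = apex
    else:
        junction = z_bot
    v[:, 2] -= junction
    return TriangleMesh(v, mesh.faces.copy(), mesh.unit_scale, mesh.label)


def remove_stem(mesh: TriangleMesh,
                cut_height_cm: float = 0.0) -> TriangleMesh:
    """Cut the crown at z = ``cut_height_cm`` and keep the part below,
    closed with a planar cap.  A plane above the whole mesh returns the
    input unchanged with a warning."""
    if cut_height_cm < 0:
        raise ValueError("cut_height_cm must be >= 0")
    if mesh.is_empty:
        raise EmptyMeshError("cannot cut an empty mesh")
    if mesh.bounds[1][2] <= cut_height_cm:
        log.warning("%s: cut plane above mesh; nothing removed",
                    mesh.label or "mesh")
        return mesh.copy()
    plane = Plane([0.0, 0.0, cut_height_cm], [0.0, 0.0, 1.0])
    _, below = plane_cut(mesh, plane)
    return below
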