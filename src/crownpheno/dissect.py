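"""Digital dissection of a crown into individual storage roots.

The hub (the fused central region around the stem base) is cleared by a
spherical cut and each remaining connected component becomes one root
segment.  Per-root measurements run on a cross-section centerline: planes
perpendicular to the locally re-estimated root direction, stepped along
the root, with the polyline through the cross-section centroids standing
in for the root's axis.

Angle convention: basal angles are measured between the basal quarter of
the centerline and the horizontal soil plane — 0 deg is a flat, spreading
root and 90 deg points straight down — so the "lowest angles" summary
selects the shallowest roots.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DissectionError, EmptyMeshError
from .mesh import TriangleMesh, connected_components
from .prep import _fan_cap_boundaries

log = logging.getLogger(__name__)

SECTION_STEP_CM = 1.0  # centerline cross-section spacing
RESEED_EVERY = 5  # sections between direction re-estimates


@dataclass
class RootSegment:
    """One digitally dissected storage root."""

    mesh: TriangleMesh
    root_id: int = 0
    length: float = 0.0  # cm, centerline + basal extension
    basal_angle: float = 0.0  # deg from horizontal
    max_diameter: float = 0.0  # cm, equivalent-circle
    volume: float = 0.0  # cm^3
    attachment_point: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    basal_extension: float = 0.0  # cm clipped away by the hub clearance
    fused: bool = False  # multiple attachment scars on one component


def _abs_volume(mesh: TriangleMesh) -> float:
    tri = mesh.triangles()
    return abs(float(np.einsum("ij,ij->", tri[:, 0],
                               np.cross(tri[:, 1], tri[:, 2])) / 6.0))


def segment_roots(mesh: TriangleMesh, hub_radius: float,
                  hub_center=None, min_volume: float = 5.0,
                  attach_radius: float | None = None,
                  measure: bool = True) -> list[RootSegment]:
    """Dissect a prepped crown into root segments.

    Faces within ``hub_radius`` of the hub center (default one hub radius
    below the soil line on the stem axis) are removed; each remaining
    component above ``min_volume`` cm^3 becomes a segment.  Components
    carrying more than one attachment scar are flagged fused.
    """
    if mesh.is_empty:
        raise EmptyMeshError("cannot dissect an empty mesh")
    if hub_radius <= 0:
        raise DissectionError("hub_radius must be positive")
    center = (np.array([0.0, 0.0, -hub_radius]) if hub_center is None
              else np.asarray(hub_center, dtype=float))
    attach_r = hub_radius if attach_radius is None else float(attach_radius)
    # a fixed margin absorbs soil-line placement error and face-centroid
    # quantization; without it a sliver of hub surface can survive and
    # keep every root in one component
    clearance = hub_radius + 0.6
    centroids = mesh.triangles().mean(axis=1)
    in_sphere = np.linalg.norm(centroids - center, axis=1) <= clearance
    # also clear the soil-line cap left by stem removal: a narrow cylinder
    # around the stem axis above the hub equator
    rel = centroids - center
    in_cap = ((np.hypot(rel[:, 0], rel[:, 1]) <= 0.6 * hub_radius)
              & (rel[:, 2] > 0.5 * hub_radius))
    keep = ~(in_sphere | in_cap)
    if not keep.any():
        raise DissectionError("no roots found: hub clearance removed "
                              "every face")
    cleared = TriangleMesh(mesh.vertices.copy(), mesh.faces[keep],
                           mesh.unit_scale, mesh.label)
    segments = []
    for comp in connected_components(cleared):
        closed = _fan_cap_boundaries(comp)
        vol = _abs_volume(closed) * mesh.unit_scale ** 3
        if vol < min_volume:
            continue
        # attachment scars: boundary loops of the raw component that hug
        # the clearance sphere
        scars = []
        for loop in comp.boundary_loops():
            pts = comp.vertices[loop]
            r = np.linalg.norm(pts - center, axis=1)
            if np.median(r) < clearance + 0.8:
                scars.append(pts.mean(axis=0))
        attachment = scars[0] if scars else comp.vertices.mean(axis=0)
        # signed: the scar ring can sit slightly inside the clearance
        # sphere (boundary vertices outlive their removed faces), in
        # which case the centerline starts before the true attachment
        ext = (float(np.linalg.norm(attachment - center)) - attach_r
               if scars else 0.0)
        segments.append(RootSegment(mesh=closed, volume=vol,
                                    attachment_point=np.asarray(attachment),
                                    basal_extension=ext,
                                    fused=len(scars) > 1))
    if not segments:
        raise DissectionError("no roots found above the volume threshold")
    segments.sort(key=lambda s: -s.volume)
    for i, s in enumerate(segments):
        s.root_id = i + 1
    if measure:
        for s in segments:
            try:
                s.length = root_length(s)
                s.basal_angle = root_basal_angle(s)
                s.max_diameter = root_max_diameter(s)
                # fused pairs diverging from the hub show repeated
                # multi-loop cross-sections near the base
                if _centerline(s)[2] >= 2:
                    s.fused = True
            except DissectionError as exc:
                log.warning("root %d: measurement failed (%s)", s.root_id,
                            exc)
    return segments


def _section_loops(tmesh, origin: np.ndarray,
                   normal: np.ndarray) -> list[np.ndarray]:
    """Closed cross-section polylines of the mesh with one plane."""
    sec = tmesh.section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        return []
    return [np.asarray(d) for d in sec.discrete if len(d) >= 3]


def _polygon_area_3d(loop: np.ndarray, normal: np.ndarray) -> float:
    c = loop.mean(axis=0)
    rel = loop - c
    cross = np.cross(rel[:-1], rel[1:]).sum(axis=0)
    return abs(float(cross @ normal)) / 2.0


def _centerline(segment: RootSegment,
                step: float = SECTION_STEP_CM,
                reseed: int = RESEED_EVERY,
                ) -> tuple[np.ndarray, list[float], int]:
    """March cross-sections along the root, re-estimating the direction.

    Returns (centroid polyline including basal/tip end points, section
    areas, number of multi-loop stations in the basal 60% — a signature
    of roots fused at the hub that diverge outward).  Raises when fewer
    than two valid cross-sections exist.  The result is cached on the
    segment: every per-root measurement shares one walk.
    """
    cached = getattr(segment, "_centerline_cache", None)
    if cached is not None:
        return cached
    mesh = segment.mesh
    tm = mesh.to_trimesh()
    verts = mesh.vertices
    # seed direction: principal axis, pointed away from the attachment
    vc = verts - verts.mean(axis=0)
    _, _, vt = np.linalg.svd(vc, full_matrices=False)
    d = vt[0]
    if (verts.mean(axis=0) - segment.attachment_point) @ d < 0:
        d = -d
    start = np.asarray(segment.attachment_point, dtype=float)
    centroids = [start]
    areas: list[float] = []
    multi_stations: list[int] = []
    d_cur = d.copy()
    span = float(np.linalg.norm(mesh.extents))
    max_sections = int(np.ceil(3 * span / step)) + 4
    for i in range(max_sections):
        # the first section hugs the base so the basal diameter is seen
        origin = centroids[-1] + d_cur * (step if i else 0.15 * step)
        loops = _section_loops(tm, origin, d_cur)
        if not loops:
            break
        if len(loops) > 1:
            multi_stations.append(i)
        cands = [(np.linalg.norm(lp.mean(axis=0) - origin), lp)
                 for lp in loops]
        dist, loop = min(cands, key=lambda t: t[0])
        if dist > 3 * step + 2 * (np.sqrt(max(areas[-1:] or [1.0])
                                          / np.pi)):
            break  # nearest loop belongs to another branch
        c = loop.mean(axis=0)
        centroids.append(c)
        areas.append(_polygon_area_3d(loop, d_cur))
        if len(centroids) >= 2 and (i + 1) % reseed == 0:
            back = min(reseed, len(centroids) - 1)
            new_d = centroids[-1] - centroids[-1 - back]
            n = np.linalg.norm(new_d)
            if n > 1e-9:
                d_cur = 0.5 * d_cur + 0.5 * new_d / n
                d_cur /= np.linalg.norm(d_cur)
    if len(centroids) < 3 or len(areas) < 2:
        raise DissectionError("fewer than 2 valid cross-sections; segment "
                              "too short or degenerate")
    # extend to the tip: farthest vertex beyond the last centroid
    proj = (verts - centroids[-1]) @ d_cur
    tip_ext = float(proj.max())
    if tip_ext > 0:
        centroids.append(centroids[-1] + d_cur * tip_ext)
    n_multi = sum(1 for i in multi_stations if i <= 0.6 * len(areas))
    result = (np.asarray(centroids), areas, n_multi)
    segment._centerline_cache = result
    return result


def root_length(segment: RootSegment) -> float:
    """Centerline length (cm), attachment to tip."""
    centroids, _, _ = _centerline(segment)
    steps = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    return float(steps.sum()) + segment.basal_extension


def root_basal_angle(segment: RootSegment) -> float:
    """Angle (deg) between the basal quarter of the centerline and the
    horizontal plane, clamped to [0, 90]."""
    centroids, _, _ = _centerline(segment)
    steps = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    arc = np.r_[0.0, np.cumsum(steps)]
    quarter = 0.25 * arc[-1]
    k = max(int(np.searchsorted(arc, quarter)), 1)
    delta = centroids[k] - centroids[0]
    horiz = float(np.hypot(delta[0], delta[1]))
    ang = np.degrees(np.arctan2(-delta[2], horiz))
    return float(np.clip(ang, 0.0, 90.0))


def root_max_diameter(segment: RootSegment) -> float:
    """Maximum equivalent-circle diameter 2*sqrt(A/pi) over sections."""
    _, areas, _ = _centerline(segment)
    return float(2.0 * np.sqrt(max(areas) / np.pi))


def crown_root_angle(angles, k: int = 3) -> float:
    """Crown-level root angle: mean of the ``k`` lowest basal angles.

    With fewer than ``k`` roots, the mean of all angles is returned with
    a warning.
    """
    vals = sorted(float(a) for a in angles)
    if not vals:
        raise DissectionError("no root angles supplied")
    if len(vals) < k:
        warnings.warn(f"only {len(vals)} roots for k={k}; averaging all",
                      stacklevel=2)
        return float(np.mean(vals))
    return float(np.mean(vals[:k]))
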