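"""Polygon triangulation used to cap planar cuts and boundary loops.

Cross-sections of a closed surface are simple polygons, possibly nested
(annular sections through hollow shapes).  Outer rings are triangulated by
ear clipping; hole rings are classified even-odd by containment depth and
joined to their enclosing ring with bridge edges (max-x visibility
construction), giving a simple polygon that ear clipping can consume.

All routines are index-based: rings are sequences of indices into a shared
2D point array, and output triangles reference those same indices, so caps
stitch exactly onto existing mesh vertices.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Point, Polygon


def signed_area(pts: np.ndarray, ring: np.ndarray) -> float:
    """Signed area of a ring (positive = counter-clockwise)."""
    p = pts[ring]
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _is_ear(pts: np.ndarray, idx: list[int], i: int, eps: float) -> bool:
    n = len(idx)
    a, b, c = pts[idx[(i - 1) % n]], pts[idx[i]], pts[idx[(i + 1) % n]]
    cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    if cross <= eps:  # reflex or degenerate corner
        return False
    others = [idx[j] for j in range(n)
              if j not in ((i - 1) % n, i, (i + 1) % n)]
    if not others:
        return True
    q = pts[others]
    d0 = (b[0] - a[0]) * (q[:, 1] - a[1]) - (b[1] - a[1]) * (q[:, 0] - a[0])
    d1 = (c[0] - b[0]) * (q[:, 1] - b[1]) - (c[1] - b[1]) * (q[:, 0] - b[0])
    d2 = (a[0] - c[0]) * (q[:, 1] - c[1]) - (a[1] - c[1]) * (q[:, 0] - c[0])
    inside = (d0 > eps) & (d1 > eps) & (d2 > eps)
    return not bool(inside.any())


def earclip(pts: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Ear-clip a simple polygon given as indices into ``pts``.

    Returns (m, 3) triangles of point indices whose winding matches the
    input ring orientation.
    """
    ring = np.asarray(ring, dtype=np.int64)
    n = len(ring)
    if n < 3:
        return np.empty((0, 3), dtype=np.int64)
    flipped = signed_area(pts, ring) < 0
    work = ring[::-1] if flipped else ring
    span = max(float(np.ptp(pts[ring, 0])), float(np.ptp(pts[ring, 1])),
               1e-30)
    eps = 1e-12 * span * span
    idx = list(work)
    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3:
        m = len(idx)
        clipped = False
        for i in range(m):
            if _is_ear(pts, idx, i, eps):
                tris.append((idx[(i - 1) % m], idx[i], idx[(i + 1) % m]))
                del idx[i]
                clipped = True
                break
        if not clipped:
            # numerically stuck (touching bridge corners): clip the most
            # convex corner and continue
            best, best_cross = 0, -np.inf
            for i in range(m):
                a, b, c = (pts[idx[(i - 1) % m]], pts[idx[i]],
                           pts[idx[(i + 1) % m]])
                cr = ((b[0] - a[0]) * (c[1] - a[1])
                      - (b[1] - a[1]) * (c[0] - a[0]))
                if cr > best_cross:
                    best, best_cross = i, cr
            tris.append((idx[(best - 1) % m], idx[best], idx[(best + 1) % m]))
            del idx[best]
        guard += 1
        if guard > 4 * n:
            break
    if len(idx) == 3:
        tris.append((idx[0], idx[1], idx[2]))
    out = np.array(tris, dtype=np.int64)
    if flipped and len(out):
        out = out[:, ::-1]
    return out


def _bridge_hole(pts: np.ndarray, outer: list[int],
                 hole: list[int]) -> list[int]:
    """Splice a CW hole ring into a CCW outer ring via a visibility bridge."""
    hx = pts[hole, 0]
    m_i = int(np.argmax(hx))
    M = pts[hole[m_i]]
    best_t, best_edge = np.inf, None
    n = len(outer)
    for j in range(n):
        p1, p2 = pts[outer[j]], pts[outer[(j + 1) % n]]
        if (p1[1] - M[1]) * (p2[1] - M[1]) > 0:
            continue
        dy = p2[1] - p1[1]
        if abs(dy) < 1e-30:
            x_hit = max(p1[0], p2[0])
        else:
            t = (M[1] - p1[1]) / dy
            x_hit = p1[0] + t * (p2[0] - p1[0])
        if x_hit >= M[0] - 1e-12 and x_hit - M[0] < best_t:
            best_t, best_edge = x_hit - M[0], j
    if best_edge is None:  # not actually enclosed; drop the hole
        return outer
    j = best_edge
    p1, p2 = pts[outer[j]], pts[outer[(j + 1) % n]]
    cand = j if p1[0] > p2[0] else (j + 1) % n
    I = np.array([M[0] + best_t, M[1]])
    P = pts[outer[cand]]
    tri = np.array([M, I, P])
    best_metric = np.inf
    for k in range(n):
        q = pts[outer[k]]
        a, b, c = tri
        d0 = (b[0] - a[0]) * (q[1] - a[1]) - (b[1] - a[1]) * (q[0] - a[0])
        d1 = (c[0] - b[0]) * (q[1] - b[1]) - (c[1] - b[1]) * (q[0] - b[0])
        d2 = (a[0] - c[0]) * (q[1] - c[1]) - (a[1] - c[1]) * (q[0] - c[0])
        if min(d0, d1, d2) > 1e-12:
            metric = abs(np.arctan2(q[1] - M[1], q[0] - M[0]))
            if metric < best_metric:
                best_metric, cand = metric, k
    hole_seq = hole[m_i:] + hole[:m_i] + [hole[m_i]]
    return (outer[:cand + 1] + hole_seq + [outer[cand]] + outer[cand + 1:])


def triangulate_rings(pts: np.ndarray,
                      rings: list[np.ndarray]) -> np.ndarray:
    """Triangulate nested rings under even-odd classification.

    ``rings`` are index arrays into ``pts`` (2D).  Returns triangles as
    point-index triples, wound CCW in the plane of ``pts``.
    """
    rings = [np.asarray(r, dtype=np.int64) for r in rings if len(r) >= 3]
    if not rings:
        return np.empty((0, 3), dtype=np.int64)
    areas = [abs(signed_area(pts, r)) for r in rings]
    order = list(np.argsort(areas)[::-1])
    polys = [Polygon(pts[rings[i]]).buffer(0) for i in order]
    depth = np.zeros(len(order), dtype=int)
    for a in range(len(order)):
        pa = Point(pts[rings[order[a]][0]])
        for b in range(a):
            if polys[b].contains(pa):
                depth[a] += 1
    tris_out = []
    for a in range(len(order)):
        if depth[a] % 2:
            continue
        outer = rings[order[a]]
        if signed_area(pts, outer) < 0:
            outer = outer[::-1]
        merged = list(outer)
        for b in range(len(order)):
            if b == a or depth[b] != depth[a] + 1:
                continue
            if not polys[a].contains(Point(pts[rings[order[b]][0]])):
                continue
            hole = rings[order[b]]
            if signed_area(pts, hole) > 0:
                hole = hole[::-1]
            merged = _bridge_hole(pts, merged, list(hole))
        tris = earclip(pts, np.asarray(merged, dtype=np.int64))
        if len(tris):
            tris_out.append(tris)
    if not tris_out:
        return np.empty((0, 3), dtype=np.int64)
    return np.vstack(tris_out)
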