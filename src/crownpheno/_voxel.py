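"""Voxel occupancy of a closed triangle surface by z-column ray parity.

A voxel center is inside the surface when an odd number of triangle
crossings lie above it along +z.  The rasterizer is orientation-agnostic
(only crossing parity matters), which lets hole caps be attached with
arbitrary winding before voxelization.  Grid columns are jittered by a tiny
irrational fraction of the pitch so rays never pass exactly through edges.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# fixed sub-voxel jitter keeps rays off triangle edges; value is arbitrary
# but must stay constant for determinism
_JITTER = np.array([0.31830988618, 0.15915494309, 0.23606797749])


@njit(cache=True)
def _accumulate_flips(tri, x0, y0, z0, px, py, pz, nx, ny, nz, flips):
    for t in range(tri.shape[0]):
        ax, ay, az = tri[t, 0, 0], tri[t, 0, 1], tri[t, 0, 2]
        bx, by, bz = tri[t, 1, 0], tri[t, 1, 1], tri[t, 1, 2]
        cx, cy, cz = tri[t, 2, 0], tri[t, 2, 1], tri[t, 2, 2]
        xmin = min(ax, bx, cx)
        xmax = max(ax, bx, cx)
        ymin = min(ay, by, cy)
        ymax = max(ay, by, cy)
        i0 = max(0, int(np.ceil((xmin - x0) / px)))
        i1 = min(nx - 1, int(np.floor((xmax - x0) / px)))
        j0 = max(0, int(np.ceil((ymin - y0) / py)))
        j1 = min(ny - 1, int(np.floor((ymax - y0) / py)))
        d = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
        if d == 0.0:
            continue  # vertical triangle: no z-crossing contribution
        inv = 1.0 / d
        for i in range(i0, i1 + 1):
            qx = x0 + i * px
            for j in range(j0, j1 + 1):
                qy = y0 + j * py
                u = ((qx - ax) * (cy - ay) - (qy - ay) * (cx - ax)) * inv
                v = ((bx - ax) * (qy - ay) - (by - ay) * (qx - ax)) * inv
                if u < 0.0 or v < 0.0 or u + v > 1.0:
                    continue
                z = az + u * (bz - az) + v * (cz - az)
                # number of voxel centers strictly below the crossing
                k = int(np.floor((z - z0) / pz)) + 1
                if k < 0:
                    k = 0
                elif k > nz:
                    k = nz
                flips[i, j, k] += 1


def occupancy(vertices: np.ndarray, faces: np.ndarray, origin: np.ndarray,
              pitch, shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean inside/outside grid sampled at voxel centers.

    ``origin`` is the center of voxel (0, 0, 0); ``shape`` is (nx, ny, nz);
    ``pitch`` may be a scalar or a per-axis 3-vector.
    """
    nx, ny, nz = shape
    p = np.broadcast_to(np.asarray(pitch, dtype=float), (3,))
    tri = np.ascontiguousarray(vertices[faces], dtype=np.float64)
    jit = origin - _JITTER * p * 1e-3
    flips = np.zeros((nx, ny, nz + 1), dtype=np.uint16)
    _accumulate_flips(tri, jit[0], jit[1], jit[2], p[0], p[1], p[2],
                      nx, ny, nz, flips)
    # crossings above center k = suffix sum of flips over bins k+1..nz
    suffix = np.cumsum(flips[:, :, ::-1], axis=2, dtype=np.int64)[:, :, ::-1]
    return (suffix[:, :, 1:] % 2).astype(bool)
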