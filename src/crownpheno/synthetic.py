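"""Procedural root-crown meshes with exact ground truth.

A synthetic crown is the implicit union of three analytic primitives: a
vertical stem cylinder, a hub sphere buried just below the soil line, and
curved tapered root tubes radiating from the hub.  The mesh is extracted
from the union signed-distance field by marching cubes, which mimics the
single fused surface photogrammetry produces (concatenating per-part tube
meshes would double-count hub overlaps in any divergence-theorem volume).

Ground truth volumes come from a voxel occupancy count on the same
analytic geometry (1 mm grid by default) — the stand-in for the
water-displacement reference measurements used for real crowns — and are
independent of the mesh-processing pipeline under test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import marching_cubes

from .errors import DomainError, EmptyMeshError
from .mesh import TriangleMesh, surface_area

log = logging.getLogger(__name__)

DEFAULT_ORACLE_PITCH_CM = 0.1
DEFAULT_MESH_PITCH_CM = 0.3


@dataclass
class RootSpec:
    """One storage root: placement angles, size and curvature."""

    azimuth_deg: float
    inclination_deg: float  # from horizontal; 0 = flat, 90 = straight down
    length_cm: float
    basal_radius_cm: float
    tip_radius_cm: float
    curvature_per_cm: float = 0.0  # downward bend of the centerline


@dataclass
class SyntheticCrownSpec:
    """Full generator parameterisation; the seed governs jitter only."""

    roots: list[RootSpec]
    stem_radius_cm: float = 2.0
    stem_height_cm: float = 10.0
    hub_radius_cm: float = 4.0
    mesh_pitch_cm: float = DEFAULT_MESH_PITCH_CM
    seed: int = 0

    def __post_init__(self) -> None:
        for r in self.roots:
            if r.length_cm <= 0 or r.basal_radius_cm <= 0 \
                    or r.tip_radius_cm <= 0:
                raise DomainError("root lengths and radii must be positive")
            if not 0 <= r.inclination_deg <= 90:
                raise DomainError("inclination must be in [0, 90] degrees")


@dataclass
class GroundTruth:
    """Oracle trait values recomputable bit-identically from the spec."""

    oracle_volume: float  # crown volume below the soil line, cm^3
    oracle_volume_full: float  # including stem, cm^3
    oracle_area: float  # surface area of the generated mesh, cm^2
    root_count: int
    root_lengths: np.ndarray  # cm, attachment to tip along the centerline
    root_basal_angles: np.ndarray  # deg from horizontal, basal-25% chord
    root_basal_diameters: np.ndarray  # cm
    cylinder_volume: float  # minimal vertical enclosing cylinder, cm^3
    compactness: float  # %
    support_normal: np.ndarray = field(
        default_factory=lambda: np.array([0.0, -1.0, 0.0]))
    oracle_pitch: float = DEFAULT_ORACLE_PITCH_CM
    warnings: list = field(default_factory=list)


# -- analytic primitives --------------------------------------------------

class _Sphere:
    def __init__(self, center, radius):
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)

    def bbox(self):
        r = self.radius
        return self.center - r, self.center + r

    def fill(self, occ, lo, pitch):
        _fill_region(occ, lo, pitch, self.bbox(),
                     lambda p: ((p - self.center) ** 2).sum(axis=-1)
                     <= self.radius ** 2)

    def carve_sdf(self, F, lo, pitch, margin):
        def sdf(p):
            return np.sqrt(((p - self.center) ** 2).sum(axis=-1)) - self.radius
        _carve_region(F, lo, pitch, self.bbox(), sdf, margin)


class _VerticalCylinder:
    def __init__(self, z0, z1, radius):
        self.z0, self.z1, self.radius = float(z0), float(z1), float(radius)

    def bbox(self):
        r = self.radius
        return (np.array([-r, -r, self.z0]), np.array([r, r, self.z1]))

    def fill(self, occ, lo, pitch):
        def inside(p):
            return ((p[..., 0] ** 2 + p[..., 1] ** 2 <= self.radius ** 2)
                    & (p[..., 2] >= self.z0) & (p[..., 2] <= self.z1))
        _fill_region(occ, lo, pitch, self.bbox(), inside)

    def carve_sdf(self, F, lo, pitch, margin):
        def sdf(p):
            dr = np.hypot(p[..., 0], p[..., 1]) - self.radius
            dz = np.maximum(self.z0 - p[..., 2], p[..., 2] - self.z1)
            return np.maximum(dr, dz)
        _carve_region(F, lo, pitch, self.bbox(), sdf, margin)


class _RootTube:
    """Curved tapered tube: rounded cone-chain clipped by a flat base."""

    def __init__(self, root: RootSpec, start: np.ndarray,
                 embed_cm: float = 0.0, seg_len: float = 1.0):
        az = np.radians(root.azimuth_deg)
        # integrate the centerline: inclination grows with curvature
        ds = 0.1
        n = max(int(np.ceil(root.length_cm / ds)), 2)
        s = np.linspace(0.0, root.length_cm, n + 1)
        alpha = np.radians(root.inclination_deg) + root.curvature_per_cm * s
        dirs = np.column_stack([np.cos(alpha) * np.cos(az),
                                np.cos(alpha) * np.sin(az),
                                -np.sin(alpha)])
        pts = np.zeros((n + 1, 3))
        pts[1:] = np.cumsum(0.5 * (dirs[:-1] + dirs[1:]) * np.diff(s)[:, None],
                            axis=0)
        pts += np.asarray(start, dtype=float)
        self.fine_pts = pts
        self.fine_s = s
        self.d0 = dirs[0]
        self.tip_point = pts[-1]
        self.d_tip = dirs[-1]
        radii = (root.basal_radius_cm
                 + (root.tip_radius_cm - root.basal_radius_cm)
                 * s / root.length_cm)
        # base extension keeps the union seamless inside the hub
        self.base_point = pts[0] - self.d0 * embed_cm
        # coarse nodes for distance queries
        stride = max(int(round(seg_len / ds)), 1)
        idx = np.unique(np.r_[np.arange(0, n + 1, stride), n])
        self.nodes = np.vstack([self.base_point, pts[idx]])
        self.radii = np.r_[radii[0], radii[idx]]
        self.max_r = float(radii.max())
        self.spec = root

    def bbox(self):
        r = self.max_r
        return self.nodes.min(axis=0) - r, self.nodes.max(axis=0) + r

    def _tube_dist(self, p: np.ndarray) -> np.ndarray:
        """min over segments of (distance to segment - local radius)."""
        flat = p.reshape(-1, 3)
        best = np.full(len(flat), np.inf)
        for k in range(len(self.nodes) - 1):
            a, b = self.nodes[k], self.nodes[k + 1]
            ra, rb = self.radii[k], self.radii[k + 1]
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0:
                continue
            t = np.clip((flat - a) @ ab / denom, 0.0, 1.0)
            closest = a + t[:, None] * ab
            d = np.linalg.norm(flat - closest, axis=1) - (ra + (rb - ra) * t)
            np.minimum(best, d, out=best)
        return best.reshape(p.shape[:-1])

    def _segment_fn(self, k):
        a, b = self.nodes[k], self.nodes[k + 1]
        ra, rb = self.radii[k], self.radii[k + 1]
        ab = b - a
        denom = float(ab @ ab)

        def dist(p):
            if denom == 0:
                return np.full(p.shape[:-1], np.inf)
            t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
            closest = a + t[..., None] * ab
            return (np.linalg.norm(p - closest, axis=-1)
                    - (ra + (rb - ra) * t))

        r = max(ra, rb)
        bmin = np.minimum(a, b) - r
        bmax = np.maximum(a, b) + r
        return dist, (bmin, bmax)

    def fill(self, occ, lo, pitch):
        # per-segment sub-boxes keep the work proportional to tube volume;
        # base and tip are clipped flat so the generator length is exactly
        # the attachment-to-tip centerline arc
        for k in range(len(self.nodes) - 1):
            dist, bbox = self._segment_fn(k)

            def inside(p, dist=dist):
                base = (p - self.base_point) @ self.d0
                tip = (p - self.tip_point) @ self.d_tip
                return (dist(p) <= 0.0) & (base >= 0.0) & (tip <= 0.0)

            _fill_region(occ, lo, pitch, bbox, inside)

    def carve_sdf(self, F, lo, pitch, margin):
        for k in range(len(self.nodes) - 1):
            dist, bbox = self._segment_fn(k)

            def sdf(p, dist=dist):
                base = -((p - self.base_point) @ self.d0)
                tip = (p - self.tip_point) @ self.d_tip
                return np.maximum(np.maximum(dist(p), base), tip)

            _carve_region(F, lo, pitch, bbox, sdf, margin)

    # ground-truth summaries -------------------------------------------
    def truth_basal_angle(self) -> float:
        quarter = 0.25 * self.fine_s[-1]
        k = int(np.searchsorted(self.fine_s, quarter))
        delta = self.fine_pts[k] - self.fine_pts[0]
        horiz = np.hypot(delta[0], delta[1])
        return float(np.clip(np.degrees(np.arctan2(-delta[2], horiz)),
                             0.0, 90.0))


def _grid_range(lo, pitch, bmin, bmax, shape):
    i0 = np.maximum(np.floor((bmin - lo) / pitch).astype(int), 0)
    i1 = np.minimum(np.ceil((bmax - lo) / pitch).astype(int) + 1,
                    np.asarray(shape))
    return i0, i1


def _region_points(lo, pitch, i0, i1):
    axes = [lo[d] + np.arange(i0[d], i1[d]) * pitch for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)


def _fill_region(occ, lo, pitch, bbox, inside_fn, chunk=32):
    bmin, bmax = bbox
    i0, i1 = _grid_range(lo, pitch, bmin, bmax, occ.shape)
    if np.any(i0 >= i1):
        return
    for z0 in range(i0[2], i1[2], chunk):
        z1 = min(z0 + chunk, i1[2])
        pts = _region_points(lo, pitch, (i0[0], i0[1], z0),
                             (i1[0], i1[1], z1))
        occ[i0[0]:i1[0], i0[1]:i1[1], z0:z1] |= inside_fn(pts)


def _carve_region(F, lo, pitch, bbox, sdf_fn, margin, chunk=32):
    bmin, bmax = np.asarray(bbox[0]) - margin, np.asarray(bbox[1]) + margin
    i0, i1 = _grid_range(lo, pitch, bmin, bmax, F.shape)
    if np.any(i0 >= i1):
        return
    for z0 in range(i0[2], i1[2], chunk):
        z1 = min(z0 + chunk, i1[2])
        pts = _region_points(lo, pitch, (i0[0], i0[1], z0),
                             (i1[0], i1[1], z1))
        region = F[i0[0]:i1[0], i0[1]:i1[1], z0:z1]
        np.minimum(region, sdf_fn(pts).astype(np.float32), out=region)


# -- generator ------------------------------------------------------------

def _build_primitives(spec: SyntheticCrownSpec):
    prims = []
    hub_center = np.array([0.0, 0.0, -spec.hub_radius_cm])
    if spec.hub_radius_cm > 0:
        prims.append(_Sphere(hub_center, spec.hub_radius_cm))
    if spec.stem_height_cm > 0 and spec.stem_radius_cm > 0:
        z0 = -spec.hub_radius_cm if spec.hub_radius_cm > 0 else 0.0
        prims.append(_VerticalCylinder(z0, spec.stem_height_cm,
                                       spec.stem_radius_cm))
    tubes = []
    for root in spec.roots:
        az, inc = np.radians(root.azimuth_deg), np.radians(
            root.inclination_deg)
        d0 = np.array([np.cos(inc) * np.cos(az), np.cos(inc) * np.sin(az),
                       -np.sin(inc)])
        if spec.hub_radius_cm > 0:
            start = hub_center + spec.hub_radius_cm * d0
            embed = 0.5 * spec.hub_radius_cm
        else:
            start = np.zeros(3)
            embed = 0.0
        tubes.append(_RootTube(root, start, embed_cm=embed))
    return prims, tubes


def roots_intersect_beyond_hub(spec: SyntheticCrownSpec,
                               clearance_cm: float | None = None,
                               margin_cm: float = 1.0) -> bool:
    """True when any two root tubes come within ``margin_cm`` of touching
    outside the hub clearance sphere (they would fuse into one segment)."""
    _, tubes = _build_primitives(spec)
    clearance = (clearance_cm if clearance_cm is not None
                 else spec.hub_radius_cm)
    hub_center = np.array([0.0, 0.0, -spec.hub_radius_cm])
    for i in range(len(tubes)):
        for j in range(i + 1, len(tubes)):
            a, b = tubes[i], tubes[j]
            pa = a.fine_pts[::5]
            ra = np.interp(a.fine_s[::5], a.fine_s,
                           np.linspace(a.spec.basal_radius_cm,
                                       a.spec.tip_radius_cm,
                                       len(a.fine_s)))
            outside = np.linalg.norm(pa - hub_center, axis=1) > clearance
            if not outside.any():
                continue
            d = b._tube_dist(pa[outside]) - ra[outside]
            if float(d.min()) < margin_cm:
                return True
    return False


def generate_crown(spec: SyntheticCrownSpec,
                   oracle_pitch: float = DEFAULT_ORACLE_PITCH_CM,
                   ) -> tuple[TriangleMesh, GroundTruth]:
    """Generate a watertight crown mesh and its ground-truth ledger.

    The mesh is marching cubes on the union SDF at ``spec.mesh_pitch_cm``;
    the ledger volumes are voxel counts of the analytic occupancy at
    ``oracle_pitch`` (overlaps at the hub are therefore counted once).
    Output is deterministic for a given (spec, oracle_pitch).
    """
    if not spec.roots and spec.hub_radius_cm <= 0 \
            and spec.stem_height_cm <= 0:
        raise EmptyMeshError("spec describes no geometry")
    prims, tubes = _build_primitives(spec)
    every = prims + tubes
    bmins = np.array([p.bbox()[0] for p in every])
    bmaxs = np.array([p.bbox()[1] for p in every])

    # mesh from the union SDF
    pitch = spec.mesh_pitch_cm
    pad = 3 * pitch
    lo = bmins.min(axis=0) - pad
    hi = bmaxs.max(axis=0) + pad
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / pitch)) + 1 for d in range(3))
    far = np.float32(4 * pitch)
    F = np.full(shape, far, dtype=np.float32)
    for p in every:
        p.carve_sdf(F, lo, pitch, margin=3 * pitch)
    np.clip(F, -far, far, out=F)
    verts, faces, _, _ = marching_cubes(F, level=0.0,
                                        spacing=(pitch, pitch, pitch))
    verts = verts + lo
    mesh = TriangleMesh(verts, np.asarray(faces, dtype=np.int64),
                        label=f"synthetic_crown_seed{spec.seed}")
    tri = mesh.triangles()
    vol = np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    if vol < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1],
                            label=mesh.label)

    # oracle occupancy
    op = oracle_pitch
    olo = bmins.min(axis=0) - 2 * op
    ohi = bmaxs.max(axis=0) + 2 * op
    oshape = tuple(int(np.ceil((ohi[d] - olo[d]) / op)) + 1 for d in range(3))
    occ = np.zeros(oshape, dtype=bool)
    for p in every:
        p.fill(occ, olo, op)
    voxel = op ** 3
    full_volume = float(occ.sum()) * voxel
    # crown = below the soil line z = 0 (the stem-removal cut)
    zc = olo[2] + np.arange(oshape[2]) * op
    below = occ[:, :, zc <= 0.0]
    crown_volume = float(below.sum()) * voxel
    ii, jj, kk = np.nonzero(below)
    if len(ii) == 0:
        raise EmptyMeshError("no crown volume below the soil line")
    xs = olo[0] + ii * op
    ys = olo[1] + jj * op
    zs = zc[zc <= 0.0][kk]
    r_max = float(np.hypot(xs, ys).max()) + 0.5 * op
    height = float(zs.max() - zs.min()) + op
    cylinder_volume = float(np.pi * r_max ** 2 * height)
    compact = 100.0 * crown_volume / cylinder_volume

    warnings = []
    if len(tubes) > 1 and roots_intersect_beyond_hub(spec):
        warnings.append("roots intersect beyond the hub clearance")
        log.warning("synthetic crown: %s", warnings[-1])

    truth = GroundTruth(
        oracle_volume=crown_volume,
        oracle_volume_full=full_volume,
        oracle_area=surface_area(mesh),
        root_count=len(tubes),
        root_lengths=np.array([t.spec.length_cm for t in tubes]),
        root_basal_angles=np.array([t.truth_basal_angle() for t in tubes]),
        root_basal_diameters=np.array(
            [2.0 * t.spec.basal_radius_cm for t in tubes]),
        cylinder_volume=cylinder_volume,
        compactness=compact,
        oracle_pitch=op,
        warnings=warnings,
    )
    return mesh, truth


# -- photogrammetry defect models ----------------------------------------

def inject_blind_area_defect(mesh: TriangleMesh,
                             support_normal=(0.0, -1.0, 0.0),
                             depth: float = 1.0) -> TriangleMesh:
    """Remove faces near the supporting plane, emulating the photographic
    blind area where the crown rests on the background sheet.

    ``support_normal`` points from the crown toward the support; the
    supporting plane is tangent to the mesh on that side and every face
    whose centroid lies within ``depth`` of it is deleted.
    """
    if mesh.is_empty:
        raise EmptyMeshError("cannot inject defect into an empty mesh")
    n = np.asarray(support_normal, dtype=float)
    n = n / np.linalg.norm(n)
    d = mesh.vertices @ n
    extent = d.max() - d.min()
    if depth >= extent:
        raise DomainError(f"defect depth {depth} exceeds mesh extent "
                          f"{extent:.3g} along the support normal")
    centroids = mesh.triangles().mean(axis=1) @ n
    keep = centroids <= d.max() - depth
    if keep.all():
        return mesh.copy()
    return TriangleMesh(mesh.vertices.copy(), mesh.faces[keep],
                        mesh.unit_scale, mesh.label)


def jitter_vertices(mesh: TriangleMesh, sigma: float,
                    seed: int = 0) -> TriangleMesh:
    """Isotropic Gaussian vertex displacement (reconstruction noise)."""
    if sigma < 0:
        raise DomainError("sigma must be >= 0")
    if sigma == 0:
        return mesh.copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=mesh.vertices.shape)
    return TriangleMesh(mesh.vertices + noise, mesh.faces.copy(),
                        mesh.unit_scale, mesh.label)


# -- cohort and trial-design builders -------------------------------------

def random_crown_spec(seed: int, n_roots: tuple[int, int] = (5, 8),
                      length_range=(12.0, 22.0),
                      basal_radius_range=(2.0, 3.2),
                      tip_radius_range=(0.6, 1.0),
                      inclination_range=(15.0, 55.0),
                      curvature_range=(0.0, 0.012),
                      hub_radius_cm: float = 4.0,
                      stem_radius_cm: float = 2.0,
                      stem_height_cm: float = 10.0,
                      mesh_pitch_cm: float = DEFAULT_MESH_PITCH_CM,
                      ) -> SyntheticCrownSpec:
    """Draw one realistic crown: azimuths jittered around an even circle
    (without replacement, guaranteeing angular spread), sizes uniform in
    the stated ranges."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(n_roots[0], n_roots[1] + 1))
    base = np.linspace(0.0, 360.0, k, endpoint=False)
    az = base + rng.uniform(-0.25, 0.25, k) * (360.0 / k)
    az = (az + rng.uniform(0, 360)) % 360
    roots = [RootSpec(azimuth_deg=float(az[i]),
                      inclination_deg=float(rng.uniform(*inclination_range)),
                      length_cm=float(rng.uniform(*length_range)),
                      basal_radius_cm=float(rng.uniform(*basal_radius_range)),
                      tip_radius_cm=float(rng.uniform(*tip_radius_range)),
                      curvature_per_cm=float(rng.uniform(*curvature_range)))
             for i in range(k)]
    return SyntheticCrownSpec(roots=roots, stem_radius_cm=stem_radius_cm,
                              stem_height_cm=stem_height_cm,
                              hub_radius_cm=hub_radius_cm,
                              mesh_pitch_cm=mesh_pitch_cm, seed=seed)


def separated_crown_spec(seed: int, max_tries: int = 50,
                         **kwargs) -> SyntheticCrownSpec:
    """A crown whose roots are verified not to touch outside the hub:
    thin-rooted draws are rejection-sampled until the pairwise clearance
    check passes (dissection benchmark conditions)."""
    kwargs.setdefault("basal_radius_range", (1.0, 1.4))
    kwargs.setdefault("tip_radius_range", (0.4, 0.6))
    kwargs.setdefault("n_roots", (5, 7))
    kwargs.setdefault("length_range", (14.0, 24.0))
    kwargs.setdefault("hub_radius_cm", 5.5)
    for t in range(max_tries):
        spec = random_crown_spec(seed * 1000 + t, **kwargs)
        if not roots_intersect_beyond_hub(spec):
            return spec
    raise DomainError("could not draw a separated crown; relax parameters")


def make_trial_dataset(n_test_genotypes: int, n_checks: int, n_blocks: int,
                       variance_components: dict, trait_means: dict,
                       seed: int = 0) -> pd.DataFrame:
    """Simulate an augmented-RCBD field trial.

    Checks are replicated in every block; test genotypes appear once,
    assigned round-robin to blocks.  Each trait value is
    mean + genotype + block + error with independent Gaussian effects of
    the stated variances (sigma2_G, sigma2_block, sigma2_e).
    """
    if n_checks < 2 or n_blocks < 2:
        raise DomainError("need at least 2 checks and 2 blocks")
    s2g = float(variance_components.get("sigma2_G", 0.0))
    s2b = float(variance_components.get("sigma2_block", 0.0))
    s2e = float(variance_components.get("sigma2_e", 0.0))
    if min(s2g, s2b, s2e) < 0:
        raise DomainError("variance components must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for t, (trait, mean) in enumerate(sorted(trait_means.items())):
        g_check = rng.normal(0, np.sqrt(s2g), n_checks)
        g_test = rng.normal(0, np.sqrt(s2g), n_test_genotypes)
        b_eff = rng.normal(0, np.sqrt(s2b), n_blocks)
        for b in range(n_blocks):
            for c in range(n_checks):
                val = mean + g_check[c] + b_eff[b] + rng.normal(
                    0, np.sqrt(s2e))
                rows.append((f"check_{c + 1}", f"block_{b + 1}", True,
                             trait, val))
        for g in range(n_test_genotypes):
            b = g % n_blocks
            val = mean + g_test[g] + b_eff[b] + rng.normal(0, np.sqrt(s2e))
            rows.append((f"test_{g + 1}", f"block_{b + 1}", False,
                         trait, val))
    long = pd.DataFrame(rows, columns=["genotype", "block", "is_check",
                                       "trait", "value"])
    wide = long.pivot_table(index=["genotype", "block", "is_check"],
                            columns="trait", values="value").reset_index()
    wide.columns.name = None
    return wide
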