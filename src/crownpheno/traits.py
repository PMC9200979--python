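"""Whole-crown traits: volume (split-half protocol), surface area,
diameter, cylinder soil volume, compactness, density and shape ratios.

All operations assume the canonical crown frame (+Z stem-ward, soil line
at z = 0, stem axis on x = y = 0) with the stem already removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .errors import DomainError, EmptyMeshError
from .mesh import Plane, TriangleMesh, plane_cut, signed_volume, surface_area
from .prep import DEFAULT_OCTREE_DEPTH, close_holes
from .mesh import slice_open

log = logging.getLogger(__name__)


@dataclass
class CrownTraits:
    """The per-plant 3D trait vector with provenance."""

    crown_volume: float | None = None  # cm^3, split-half protocol
    crown_surface_area: float | None = None  # cm^2
    crown_diameter: float | None = None  # cm
    cylinder_soil_volume: float | None = None  # cm^3
    compactness: float | None = None  # %
    root_density: float | None = None  # g/cm^3
    surface_to_volume: float | None = None  # 1/cm
    root_number: int | None = None
    crown_root_angle: float | None = None  # deg, mean of 3 lowest
    mean_root_length: float | None = None  # cm
    root_weight: float | None = None  # kg, field input passed through
    per_root: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    TRAIT_COLUMNS = ("crown_volume_cm3", "crown_surface_area_cm2",
                     "crown_diameter_cm", "cylinder_soil_volume_cm3",
                     "compactness_pct", "root_density_g_cm3",
                     "surface_to_volume_per_cm", "root_number",
                     "crown_root_angle_deg", "mean_root_length_cm",
                     "root_weight_kg")

    def to_row(self) -> dict:
        vals = (self.crown_volume, self.crown_surface_area,
                self.crown_diameter, self.cylinder_soil_volume,
                self.compactness, self.root_density, self.surface_to_volume,
                self.root_number, self.crown_root_angle,
                self.mean_root_length, self.root_weight)
        return dict(zip(self.TRAIT_COLUMNS, vals))


def split_plane(mesh: TriangleMesh,
                support_normal=(0.0, -1.0, 0.0)) -> Plane:
    """The split-half cut: a vertical plane through the stem axis whose
    normal follows the support-side direction, separating the blind areas
    of the two photographed sides."""
    n = np.asarray(support_normal, dtype=float).copy()
    n[2] = 0.0  # vertical plane contains the stem axis
    if np.linalg.norm(n) < 1e-12:
        n = np.array([0.0, -1.0, 0.0])
    return Plane([0.0, 0.0, 0.0], n)


def crown_volume_split(mesh: TriangleMesh,
                       support_normal=(0.0, -1.0, 0.0),
                       octree_depth: int = DEFAULT_OCTREE_DEPTH,
                       ) -> float:
    """Crown volume (cm^3) by the split-half protocol.

    The crown is cut by the vertical plane through the stem axis; each
    half is closed independently and the two volumes are summed.  For a
    watertight input the cut cross-sections themselves close the halves
    exactly; an input with open defects has each half volumetrically
    remeshed at a pitch set by the half's own (smaller) bounding box,
    which is what reduces the blind-area amalgamation bias relative to
    repairing the intact crown.
    """
    if mesh.is_empty:
        raise EmptyMeshError("cannot measure an empty crown")
    plane = split_plane(mesh, support_normal)
    if mesh.is_watertight:
        front, back = plane_cut(mesh, plane)
        total = 0.0
        for half in (front, back):
            if not half.is_empty:
                total += signed_volume(half)
        return total
    total = 0.0
    for keep in (True, False):
        half = slice_open(mesh, plane, keep_positive=keep)
        if half.is_empty:
            continue
        closed = close_holes(half, octree_depth=octree_depth)
        total += signed_volume(closed)
    return total


def crown_diameter(mesh: TriangleMesh) -> float:
    """Maximum horizontal caliper (cm): the largest pairwise distance of
    vertices projected onto the soil plane."""
    if mesh.is_empty:
        raise EmptyMeshError("cannot measure an empty crown")
    pts = mesh.vertices[:, :2]
    if len(pts) > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (collinear) projections
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max())) * mesh.unit_scale


def cylinder_soil_volume(mesh: TriangleMesh) -> float:
    """Volume (cm^3) of the minimal vertical cylinder around the stem axis
    that encloses the crown: r = max radial vertex distance, h = z extent."""
    if mesh.is_empty:
        raise EmptyMeshError("cannot measure an empty crown")
    v = mesh.vertices
    r = float(np.hypot(v[:, 0], v[:, 1]).max())
    h = float(v[:, 2].max() - v[:, 2].min())
    return float(np.pi * r * r * h) * mesh.unit_scale ** 3


def compactness(crown_volume: float, cylinder_volume: float) -> float:
    """CRC compactness (%): crown volume as a share of its cylinder soil
    volume."""
    if cylinder_volume <= 0:
        raise DomainError("cylinder volume must be positive")
    if crown_volume <= 0:
        raise DomainError("crown volume must be positive")
    if crown_volume > cylinder_volume * (1 + 1e-9):
        raise DomainError("crown volume exceeds its enclosing cylinder")
    return 100.0 * crown_volume / cylinder_volume


def root_density(root_weight: float, crown_volume: float) -> float:
    """Root density (g/cm^3) from field fresh weight (kg) and 3D volume."""
    if root_weight <= 0 or crown_volume <= 0:
        raise DomainError("weight and volume must be positive")
    return 1000.0 * root_weight / crown_volume


def surface_to_volume_ratio(area: float, volume: float) -> float:
    """Shape descriptor (1/cm): high for long or thin roots."""
    if area <= 0 or volume <= 0:
        raise DomainError("area and volume must be positive")
    return area / volume


def compute_all_traits(mesh: TriangleMesh, root_weight: float | None = None,
                       support_normal=(0.0, -1.0, 0.0),
                       octree_depth: int = DEFAULT_OCTREE_DEPTH,
                       hub_radius: float = 4.0,
                       k_lowest_angles: int = 3,
                       min_root_volume: float = 5.0,
                       dissect: bool = True) -> CrownTraits:
    """Populate every crown trait from a prepped crown mesh.

    Root-level traits come from digital dissection and are marked missing
    (None) when dissection fails or is disabled; root density is missing
    without a recorded field weight.
    """
    if mesh.is_empty:
        raise EmptyMeshError("cannot phenotype an empty mesh")
    t = CrownTraits(root_weight=root_weight)
    closed = mesh if mesh.is_watertight else close_holes(
        mesh, octree_depth=octree_depth)
    t.crown_volume = crown_volume_split(mesh, support_normal, octree_depth)
    t.crown_surface_area = surface_area(closed)
    t.crown_diameter = crown_diameter(closed)
    t.cylinder_soil_volume = cylinder_soil_volume(closed)
    t.compactness = compactness(min(t.crown_volume, t.cylinder_soil_volume),
                                t.cylinder_soil_volume)
    t.surface_to_volume = surface_to_volume_ratio(t.crown_surface_area,
                                                  t.crown_volume)
    if root_weight is not None:
        t.root_density = root_density(root_weight, t.crown_volume)
    if dissect:
        from .dissect import crown_root_angle, segment_roots
        try:
            segments = segment_roots(closed, hub_radius=hub_radius,
                                     min_volume=min_root_volume)
            t.per_root = segments
            t.root_number = len(segments)
            t.crown_root_angle = crown_root_angle(
                [s.basal_angle for s in segments], k=k_lowest_angles)
            t.mean_root_length = float(
                np.mean([s.length for s in segments]))
        except Exception as exc:  # partial result, dissection marked missing
            log.warning("%s: dissection failed (%s); root traits missing",
                        mesh.label or "crown", exc)
    t.provenance = {
        "octree_depth": octree_depth,
        "support_normal": list(np.asarray(support_normal, dtype=float)),
        "hub_radius_cm": hub_radius,
        "k_lowest_angles": k_lowest_angles,
        "min_root_volume_cm3": min_root_volume,
        "input_watertight": bool(mesh.is_watertight),
        "n_faces": mesh.n_faces,
    }
    return t
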