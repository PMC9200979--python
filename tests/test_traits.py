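"""Whole-crown trait extraction."""

import numpy as np
import pytest
import trimesh

from crownpheno import (DomainError, TriangleMesh, compactness,
                        compute_all_traits, crown_diameter,
                        crown_volume_split, cylinder_soil_volume,
                        root_density, signed_volume, surface_area,
                        surface_to_volume_ratio)
from crownpheno.prep import remove_stem


@pytest.fixture(scope="module")
def prepped_crown(crown_seed3):
    _, mesh, truth = crown_seed3
    return remove_stem(mesh), truth


class TestCrownVolumeSplit:
    def test_watertight_matches_direct_volume(self, prepped_crown):
        crown, _ = prepped_crown
        direct = signed_volume(crown)
        split = crown_volume_split(crown)
        assert split == pytest.approx(direct, rel=0.005)

    def test_unit_cube(self, unit_cube):
        assert crown_volume_split(unit_cube) == pytest.approx(1.0,
                                                              rel=0.005)


class TestCrownDiameter:
    def test_vertical_cylinder(self):
        cyl = TriangleMesh.from_trimesh(
            trimesh.creation.cylinder(radius=10.0, height=5.0,
                                      sections=256))
        assert crown_diameter(cyl) == pytest.approx(20.0, rel=1e-3)

    def test_horizontal_projection_not_3d_extent(self):
        # tips at x = -15 and +25 on y = 0, far apart in z: the trait is
        # the horizontal caliper, so depth must not inflate it
        pts = np.array([[-15, 0, 0], [25, 0, -40], [0, 1, 0], [0, -1, -40]],
                       dtype=float)
        mesh = TriangleMesh(pts, np.array([[0, 2, 3], [1, 2, 3]]))
        assert crown_diameter(mesh) == pytest.approx(40.0)

    def test_matches_bruteforce(self, prepped_crown):
        crown, _ = prepped_crown
        sub = crown.vertices[::7, :2]
        d2 = ((sub[:, None] - sub[None, :]) ** 2).sum(-1)
        brute = float(np.sqrt(d2.max()))
        dec = TriangleMesh(crown.vertices[::7],
                           np.zeros((1, 3), dtype=np.int64))
        assert crown_diameter(dec) == pytest.approx(brute, rel=1e-9)


class TestCylinderSoilVolume:
    def test_coaxial_cylinder(self):
        cyl = TriangleMesh.from_trimesh(
            trimesh.creation.cylinder(radius=5.0, height=10.0,
                                      sections=512))
        assert cylinder_soil_volume(cyl) == pytest.approx(
            np.pi * 25 * 10, rel=0.01)

    def test_unit_cube_half_diagonal(self, unit_cube):
        # origin-centered unit cube: r = sqrt(2)/2, h = 1 -> pi/2
        assert cylinder_soil_volume(unit_cube) == pytest.approx(
            np.pi / 2, rel=1e-6)

    def test_contains_crown_volume(self, prepped_crown):
        crown, _ = prepped_crown
        assert cylinder_soil_volume(crown) >= crown_volume_split(crown)


class TestScalarTraits:
    def test_compactness_arithmetic(self):
        assert compactness(500.0, 1000.0) == pytest.approx(50.0)
        assert compactness(1e-4, 1000.0) == pytest.approx(1e-5)

    def test_cylinder_against_itself_is_100(self):
        cyl = TriangleMesh.from_trimesh(
            trimesh.creation.cylinder(radius=5.0, height=10.0,
                                      sections=512))
        v = signed_volume(cyl)
        assert compactness(v, cylinder_soil_volume(cyl)) == pytest.approx(
            100.0, rel=0.01)

    def test_compactness_domain_errors(self):
        with pytest.raises(DomainError):
            compactness(10.0, 0.0)
        with pytest.raises(DomainError):
            compactness(1001.0, 1000.0)

    def test_root_density(self):
        assert root_density(1.0, 1000.0) == pytest.approx(1.0)
        assert root_density(2.5, 5000.0) == pytest.approx(0.5)
        with pytest.raises(DomainError):
            root_density(1.0, 0.0)

    def test_surface_to_volume(self, icosphere5):
        assert surface_to_volume_ratio(6.0, 1.0) == pytest.approx(6.0)
        assert surface_to_volume_ratio(24.0, 8.0) == pytest.approx(3.0)
        sv = surface_to_volume_ratio(surface_area(icosphere5),
                                     signed_volume(icosphere5))
        assert sv == pytest.approx(3.0 / 5.0, rel=0.01)

    def test_sphere_minimizes_sv_among_equal_volume_solids(self):
        sphere = trimesh.creation.icosphere(3, 1.0)
        v = sphere.volume
        cube = trimesh.creation.box([v ** (1 / 3)] * 3)
        slab = trimesh.creation.box([4 * v ** (1 / 3),
                                     v ** (1 / 3) / 2,
                                     v ** (1 / 3) / 2])
        sv = lambda m: m.area / m.volume  # noqa: E731
        assert sv(sphere) < sv(cube) < sv(slab)


class TestComputeAllTraits:
    def test_every_field_populated(self, dissection_suite):
        item = dissection_suite[0]
        crown = remove_stem(item["mesh"])
        truth = item["truth"]
        t = compute_all_traits(crown, root_weight=2.0,
                               hub_radius=item["spec"].hub_radius_cm)
        assert t.crown_volume == pytest.approx(truth.oracle_volume,
                                               rel=0.05)
        assert t.cylinder_soil_volume == pytest.approx(
            truth.cylinder_volume, rel=0.05)
        assert t.compactness == pytest.approx(truth.compactness, rel=0.1)
        assert t.root_number == truth.root_count
        assert t.root_density == pytest.approx(
            2000.0 / t.crown_volume, rel=1e-9)
        assert t.surface_to_volume == pytest.approx(
            t.crown_surface_area / t.crown_volume, rel=1e-9)
        assert 0 < t.crown_root_angle <= 90
        assert t.mean_root_length > 0
        assert t.provenance["octree_depth"] == 8

    def test_missing_weight_marks_density_missing(self, dissection_suite):
        item = dissection_suite[1]
        crown = remove_stem(item["mesh"])
        t = compute_all_traits(crown, root_weight=None,
                               hub_radius=item["spec"].hub_radius_cm,
                               dissect=False)
        assert t.root_density is None
        assert t.root_number is None
        assert t.crown_volume > 0

    def test_empty_mesh_errors(self):
        empty = TriangleMesh(np.empty((0, 3)),
                             np.empty((0, 3), dtype=np.int64))
        with pytest.raises(Exception):
            compute_all_traits(empty)

    def test_rotation_about_z_invariance(self, dissection_suite):
        item = dissection_suite[2]
        crown = remove_stem(item["mesh"])
        M = trimesh.transformations.rotation_matrix(0.9, [0, 0, 1])
        spun = crown.transformed(M)
        d0 = crown_diameter(crown)
        d1 = crown_diameter(spun)
        assert d1 == pytest.approx(d0, rel=1e-9)
        assert cylinder_soil_volume(spun) == pytest.approx(
            cylinder_soil_volume(crown), rel=1e-9)

    def test_scaling_laws(self, dissection_suite):
        item = dissection_suite[3]
        crown = remove_stem(item["mesh"])
        s = 1.5
        big = crown.scaled(s)
        assert crown_diameter(big) == pytest.approx(
            crown_diameter(crown) * s, rel=1e-9)
        assert cylinder_soil_volume(big) == pytest.approx(
            cylinder_soil_volume(crown) * s ** 3, rel=1e-9)
        # compactness is scale-free
        c0 = compactness(signed_volume(crown),
                         cylinder_soil_volume(crown))
        c1 = compactness(signed_volume(big), cylinder_soil_volume(big))
        assert c1 == pytest.approx(c0, rel=1e-9)
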