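"""Mesh data model, I/O and closed-surface geometry."""

import numpy as np
import pytest
import trimesh

from crownpheno import (EmptyMeshError, MeshFormatError, NotWatertightError,
                        Plane, TriangleMesh, connected_components,
                        plane_cut, read_mesh, signed_volume, surface_area,
                        write_mesh)

QUAD_CUBE_OBJ = """\
v 0 0 0
v 1 0 0
v 1 1 0
v 0 1 0
v 0 0 1
v 1 0 1
v 1 1 1
v 0 1 1
f 1 4 3 2
f 5 6 7 8
f 1 2 6 5
f 2 3 7 6
f 3 4 8 7
f 4 1 5 8
"""


class TestReadWrite:
    def test_quad_cube_fan_triangulated(self, tmp_path):
        p = tmp_path / "cube.obj"
        p.write_text(QUAD_CUBE_OBJ)
        m = read_mesh(str(p))
        assert m.n_vertices == 8
        assert m.n_faces == 12
        assert m.is_watertight
        assert signed_volume(m) == pytest.approx(1.0)
        assert m.unit_scale == 1.0

    def test_zero_index_is_format_error(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 0 1 2\n")
        with pytest.raises(MeshFormatError, match="1-based"):
            read_mesh(str(p))

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.obj"
        p.write_text("")
        with pytest.raises((MeshFormatError, EmptyMeshError)):
            read_mesh(str(p))

    @pytest.mark.parametrize("fmt", ["obj", "ply"])
    def test_roundtrip_cube(self, tmp_path, unit_cube, fmt):
        p = tmp_path / f"cube.{fmt}"
        write_mesh(unit_cube, str(p))
        back = read_mesh(str(p))
        assert signed_volume(back) == pytest.approx(1.0, rel=1e-6)
        assert back.n_vertices == unit_cube.n_vertices

    def test_roundtrip_crown_preserves_vertices(self, tmp_path,
                                                crown_seed3):
        _, mesh, _ = crown_seed3
        p = tmp_path / "crown.obj"
        write_mesh(mesh, str(p))
        back = read_mesh(str(p))
        assert back.n_vertices == mesh.n_vertices
        assert signed_volume(back) == pytest.approx(signed_volume(mesh),
                                                    rel=1e-5)


class TestVolumeArea:
    def test_unit_cube(self, unit_cube):
        assert signed_volume(unit_cube) == pytest.approx(1.0)
        assert surface_area(unit_cube) == pytest.approx(6.0)

    def test_reference_cuboid(self, reference_box):
        # 12.5 x 12.5 x 34 cm: V = 5312.5, A = 2(ab + ah + bh) = 2012.5
        assert signed_volume(reference_box) == pytest.approx(5312.5)
        assert surface_area(reference_box) == pytest.approx(2012.5)

    def test_icosphere_near_analytic(self, icosphere5):
        assert signed_volume(icosphere5) == pytest.approx(
            4 / 3 * np.pi * 125, rel=0.01)
        assert surface_area(icosphere5) == pytest.approx(
            4 * np.pi * 25, rel=0.01)

    def test_agrees_with_trimesh(self, crown_seed3):
        """Cross-check the divergence-theorem sum against trimesh."""
        _, mesh, _ = crown_seed3
        ref = mesh.to_trimesh()
        assert signed_volume(mesh) == pytest.approx(ref.volume, rel=1e-9)
        assert surface_area(mesh) == pytest.approx(ref.area, rel=1e-9)

    def test_unit_scale_cubes_volume(self, unit_cube):
        scaled = TriangleMesh(unit_cube.vertices, unit_cube.faces,
                              unit_scale=2.5)
        assert signed_volume(scaled) == pytest.approx(2.5 ** 3)
        assert surface_area(scaled) == pytest.approx(6 * 2.5 ** 2)

    def test_open_mesh_refused(self, unit_cube):
        open_mesh = TriangleMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(NotWatertightError, match="close_holes"):
            signed_volume(open_mesh)

    def test_rigid_motion_invariance(self, crown_seed3):
        _, mesh, _ = crown_seed3
        v0, a0 = signed_volume(mesh), surface_area(mesh)
        rng = np.random.default_rng(42)
        for _ in range(3):
            R = trimesh.transformations.random_rotation_matrix(
                rng.random(3))
            R[:3, 3] = rng.uniform(-30, 30, 3)
            moved = mesh.transformed(R)
            assert signed_volume(moved) == pytest.approx(v0, rel=1e-6)
            assert surface_area(moved) == pytest.approx(a0, rel=1e-6)

    def test_uniform_scaling_laws(self, crown_seed3):
        _, mesh, _ = crown_seed3
        s = 1.7
        big = mesh.scaled(s)
        assert signed_volume(big) == pytest.approx(
            signed_volume(mesh) * s ** 3, rel=1e-9)
        assert surface_area(big) == pytest.approx(
            surface_area(mesh) * s ** 2, rel=1e-9)


class TestComponents:
    def test_two_cubes(self, unit_cube):
        other = TriangleMesh(unit_cube.vertices + 5.0, unit_cube.faces)
        both = TriangleMesh(
            np.vstack([unit_cube.vertices, other.vertices]),
            np.vstack([unit_cube.faces, other.faces + 8]))
        comps = connected_components(both)
        assert len(comps) == 2
        assert all(c.n_faces == 12 for c in comps)

    def test_single_cube(self, unit_cube):
        assert len(connected_components(unit_cube)) == 1

    def test_cube_plus_tetrahedra(self, unit_cube):
        tet = trimesh.creation.icosahedron()
        verts = [unit_cube.vertices]
        faces = [unit_cube.faces]
        off = 8
        rng = np.random.default_rng(0)
        for i in range(50):
            verts.append(tet.vertices * 0.05 + rng.uniform(3, 50, 3))
            faces.append(np.asarray(tet.faces) + off)
            off += len(tet.vertices)
        mesh = TriangleMesh(np.vstack(verts), np.vstack(faces))
        comps = connected_components(mesh)
        assert len(comps) == 51
        assert sum(c.n_faces for c in comps) == mesh.n_faces


class TestPlaneCut:
    def test_cube_midplane(self, unit_cube):
        front, back = plane_cut(unit_cube, Plane([0, 0, 0], [0, 0, 1]))
        assert front.is_watertight and back.is_watertight
        assert signed_volume(front) == pytest.approx(0.5, rel=1e-9)
        assert signed_volume(back) == pytest.approx(0.5, rel=1e-9)

    def test_sphere_cap_analytic(self):
        sp = TriangleMesh.from_trimesh(trimesh.creation.icosphere(4, 5.0))
        front, back = plane_cut(sp, Plane([0, 0, 2.5], [0, 0, 1]))
        h, r = 2.5, 5.0
        cap = np.pi * h * h * (3 * r - h) / 3
        assert signed_volume(front) == pytest.approx(cap, rel=0.02)
        assert (signed_volume(front) + signed_volume(back)
                == pytest.approx(signed_volume(sp), rel=1e-6))

    def test_plane_outside_returns_input_and_empty(self, unit_cube):
        front, back = plane_cut(unit_cube, Plane([0, 0, 10], [0, 0, 1]))
        assert front.is_empty
        assert signed_volume(back) == pytest.approx(1.0)

    def test_torus_annular_section(self):
        """Horizontal cut through a torus needs an annular (nested) cap."""
        tor = TriangleMesh.from_trimesh(trimesh.creation.torus(
            major_radius=5.0, minor_radius=1.0, major_sections=64,
            minor_sections=32))
        front, back = plane_cut(tor, Plane([0, 0, 0], [0, 0, 1]))
        assert front.is_watertight and back.is_watertight
        assert (signed_volume(front) + signed_volume(back)
                == pytest.approx(signed_volume(tor), rel=1e-3))

    def test_volume_conservation_random_planes(self, crown_seed3):
        _, mesh, _ = crown_seed3
        total = signed_volume(mesh)
        rng = np.random.default_rng(7)
        for _ in range(4):
            n = rng.normal(size=3)
            point = mesh.vertices.mean(axis=0) + rng.uniform(-5, 5, 3)
            front, back = plane_cut(mesh, Plane(point, n))
            parts = sum(signed_volume(m) for m in (front, back)
                        if not m.is_empty)
            assert parts == pytest.approx(total, rel=1e-3)

    def test_open_mesh_refused(self, unit_cube):
        open_mesh = TriangleMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(NotWatertightError):
            plane_cut(open_mesh, Plane([0, 0, 0], [0, 0, 1]))
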