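"""Shared fixtures: analytic solids and synthetic crown cohorts.

Cohort fixtures are session-scoped because crown generation and
volumetric repair dominate the suite's runtime; every test works from
the same deterministic seeds.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest
import trimesh

from crownpheno import (SyntheticCrownSpec, RootSpec, TriangleMesh,
                        generate_crown, inject_blind_area_defect,
                        random_crown_spec, separated_crown_spec)
from crownpheno.mesh import signed_volume
from crownpheno.prep import close_holes, remove_stem
from crownpheno.traits import crown_volume_split

logging.getLogger("crownpheno").setLevel(logging.ERROR)

DEFECT_DEPTH_CM = 1.5
N_VOLUME_COHORT = 20
N_DISSECTION_SUITE = 20


def tm(mesh: trimesh.Trimesh) -> TriangleMesh:
    return TriangleMesh.from_trimesh(mesh)


@pytest.fixture(scope="session")
def unit_cube() -> TriangleMesh:
    return tm(trimesh.creation.box((1.0, 1.0, 1.0)))


@pytest.fixture(scope="session")
def reference_box() -> TriangleMesh:
    return tm(trimesh.creation.box((12.5, 12.5, 34.0)))


@pytest.fixture(scope="session")
def icosphere5() -> TriangleMesh:
    return tm(trimesh.creation.icosphere(subdivisions=3, radius=5.0))


@pytest.fixture(scope="session")
def frustum_crown():
    """Single straight tapered root, 30 cm, radii 4 -> 1, no stem/hub."""
    spec = SyntheticCrownSpec(roots=[RootSpec(0.0, 0.0, 30.0, 4.0, 1.0)],
                              stem_radius_cm=0.0, stem_height_cm=0.0,
                              hub_radius_cm=0.0, mesh_pitch_cm=0.25)
    return generate_crown(spec)


@pytest.fixture(scope="session")
def crown_seed3():
    """One realistic default-draw crown with ground truth."""
    spec = random_crown_spec(seed=3)
    mesh, truth = generate_crown(spec)
    return spec, mesh, truth


def dense_volume_spec(seed: int):
    """Benchmark crown for the volume protocol: densely packed roots so
    inter-root crevices (the amalgamation substrate) exist."""
    return random_crown_spec(seed=seed, n_roots=(10, 14),
                             length_range=(12.0, 20.0),
                             basal_radius_range=(2.2, 3.2),
                             tip_radius_range=(0.6, 1.0),
                             inclination_range=(10.0, 50.0),
                             hub_radius_cm=5.0)


@pytest.fixture(scope="session")
def defect_cohort():
    """The split-half volume benchmark: dense crowns, blind-area defect,
    intact and split-half estimates plus the voxel oracle."""
    rows = []
    for seed in range(1, N_VOLUME_COHORT + 1):
        spec = dense_volume_spec(seed)
        full, truth = generate_crown(spec)
        crown = remove_stem(full)
        defect = inject_blind_area_defect(crown, truth.support_normal,
                                          DEFECT_DEPTH_CM)
        intact = signed_volume(close_holes(defect))
        split = crown_volume_split(defect,
                                   support_normal=truth.support_normal)
        rows.append({"seed": seed, "oracle": truth.oracle_volume,
                     "intact": intact, "split": split})
    return rows


@pytest.fixture(scope="session")
def dissection_suite():
    """Separated-root crowns (verified non-contact): half straight, half
    curved, with per-root ground truth."""
    out = []
    for i in range(N_DISSECTION_SUITE):
        curved = i % 2 == 1
        spec = separated_crown_spec(
            seed=100 + i,
            curvature_range=(0.004, 0.012) if curved else (0.0, 0.0))
        mesh, truth = generate_crown(spec)
        out.append({"spec": spec, "mesh": mesh, "truth": truth,
                    "curved": curved})
    return out
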