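"""High-level single-crown and batch pipelines used by the CLI and the
examples: raw mesh -> denoise -> repair -> calibrate -> orient -> stem
removal -> trait extraction."""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from . import prep
from .config import RunConfig
from .errors import CrownPhenoError
from .mesh import TriangleMesh, read_mesh
from .traits import CrownTraits, compute_all_traits

log = logging.getLogger(__name__)


def phenotype_crown(mesh: TriangleMesh,
                    reference: TriangleMesh | None = None,
                    root_weight: float | None = None,
                    config: RunConfig | None = None,
                    oriented: bool = False,
                    dissect: bool = True) -> CrownTraits:
    """Run the full preparation and trait pipeline on one crown.

    ``reference`` is the separately supplied reference-box mesh; when
    None the scene is assumed already calibrated to cm.  ``oriented``
    skips stem-axis detection for meshes already in the canonical frame.
    """
    cfg = config or RunConfig()
    stage = "noise removal"
    try:
        t0 = time.time()
        crown = prep.remove_noise_components(mesh, cfg.noise_min_fraction)
        if reference is not None:
            stage = "calibration"
            crown, calib = prep.calibrate_scale(
                crown, reference, cfg.known_dim_cm,
                cfg.reference_dim_selector)
        if not oriented:
            stage = "orientation"
            crown = prep.orient_crown(crown)
        stage = "stem removal"
        if not crown.is_watertight:
            crown = prep.close_holes(crown, cfg.repair_octree_depth,
                                     cfg.repair_closing_radius)
        crown = prep.remove_stem(crown, cfg.stem_cut_height_cm)
        stage = "trait extraction"
        traits = compute_all_traits(
            crown, root_weight=root_weight,
            support_normal=cfg.support_normal,
            octree_depth=cfg.repair_octree_depth,
            hub_radius=cfg.hub_radius_cm,
            k_lowest_angles=cfg.k_lowest_angles,
            min_root_volume=cfg.min_root_volume_cm3,
            dissect=dissect)
        traits.provenance["elapsed_s"] = round(time.time() - t0, 2)
        return traits
    except CrownPhenoError as exc:
        raise CrownPhenoError(f"{stage}: {exc}") from exc


def phenotype_file(mesh_path: str, reference_path: str | None = None,
                   root_weight: float | None = None,
                   config: RunConfig | None = None,
                   **kwargs) -> CrownTraits:
    mesh = read_mesh(mesh_path)
    ref = read_mesh(reference_path) if reference_path else None
    return phenotype_crown(mesh, ref, root_weight, config, **kwargs)


def phenotype_batch(manifest: pd.DataFrame,
                    config: RunConfig | None = None,
                    **kwargs) -> pd.DataFrame:
    """Phenotype every row of a manifest (plant_id, mesh_path, optional
    reference_path / root_weight_kg / genotype / block / is_check).

    Failures are logged per plant and reported in an ``error`` column;
    they do not abort the batch.
    """
    if len(manifest) == 0:
        raise CrownPhenoError("empty manifest")
    if "plant_id" not in manifest.columns or "mesh_path" not in \
            manifest.columns:
        raise CrownPhenoError("manifest needs plant_id and mesh_path")
    rows = []
    for _, rec in manifest.iterrows():
        row = {"plant_id": rec["plant_id"]}
        for meta in ("genotype", "block", "is_check"):
            if meta in manifest.columns:
                row[meta] = rec[meta]
        try:
            weight = rec.get("root_weight_kg")
            weight = None if pd.isna(weight) else float(weight)
            traits = phenotype_file(
                rec["mesh_path"],
                rec.get("reference_path") if "reference_path"
                in manifest.columns and pd.notna(
                    rec.get("reference_path")) else None,
                root_weight=weight, config=config, **kwargs)
            row.update(traits.to_row())
            row["error"] = ""
        except Exception as exc:
            log.error("plant %s failed: %s", rec["plant_id"], exc)
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
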