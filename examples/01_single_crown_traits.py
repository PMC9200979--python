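"""Phenotype one synthetic root crown end to end.

Generates a crown with known ground truth, runs the preparation and
trait pipeline (stem removal, split-half volume, dissection) and prints
each trait next to the generator's oracle value where one exists.
"""

from crownpheno import RunConfig, generate_crown, phenotype_crown
from crownpheno.synthetic import separated_crown_spec

spec = separated_crown_spec(seed=55, n_roots=(4, 4),
                            length_range=(12.0, 16.0))
mesh, truth = generate_crown(spec)

traits = phenotype_crown(mesh, root_weight=1.5,
                         config=RunConfig(hub_radius_cm=spec.hub_radius_cm))

print("trait                         measured     oracle")
rows = [
    ("crown volume (cm^3)", traits.crown_volume, truth.oracle_volume),
    ("surface area (cm^2)", traits.crown_surface_area, None),
    ("crown diameter (cm)", traits.crown_diameter, None),
    ("cylinder soil volume (cm^3)", traits.cylinder_soil_volume,
     truth.cylinder_volume),
    ("compactness (%)", traits.compactness, truth.compactness),
    ("surface:volume (1/cm)", traits.surface_to_volume, None),
    ("root density (g/cm^3)", traits.root_density, None),
    ("root number", traits.root_number, truth.root_count),
    ("crown root angle (deg)", traits.crown_root_angle, None),
    ("mean root length (cm)", traits.mean_root_length,
     float(truth.root_lengths.mean())),
]
for name, measured, oracle in rows:
    right = "" if oracle is None else f"{oracle:10.2f}"
    print(f"{name:29s} {measured:10.2f} {right}")
print("\nOracle values come from a 1 mm voxel count on the analytic "
      "crown geometry;\nmeasured values from the mesh pipeline "
      "(split-half volume, digital dissection).")
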