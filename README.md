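# crownpheno

3D phenotyping of cassava root crowns (CRCs) from photogrammetry
meshes.

Cassava breeding trials excavate whole root crowns — the cluster of
storage roots at the stem base — and until recently recorded little
more than weight and a visual score, because detailed measurement in
the field is slow and the crowns deteriorate within days.  Close-range
photogrammetry changes that: ~25–40 photos of a crown lying on a
background sheet, with a cardboard box of known size as a scale
reference, reconstruct a triangle mesh from which architecture can be
measured digitally.  `crownpheno` is the analysis half of that
platform: it takes the exported mesh and produces the ten 3D traits
used for genetic analysis, plus the trial statistics layer breeders
run on them.

## What it computes

Per crown, after repair, calibration and stem removal:

| trait | definition |
|---|---|
| crown volume *V* (cm³) | split-half protocol: cut along the stem axis, close each half, sum |
| crown surface area *A* (cm²) | triangle-area sum of the closed crown |
| crown diameter (cm) | maximum horizontal caliper |
| cylinder soil volume *V_c* (cm³) | minimal vertical cylinder about the stem axis, π r² h |
| compactness (%) | 100 · V / V_c |
| root density (g/cm³) | 1000 · fresh weight (kg) / V |
| surface-to-volume ratio (1/cm) | A / V |
| root number | connected root segments after digital hub dissection |
| crown root angle (°) | mean of the 3 lowest basal angles (0° = spreading, 90° = vertical) |
| mean root length (cm) | centerline length, attachment to tip |

Crown volume uses the split-half protocol because hole-closing
(volumetric remeshing at a resolution tied to the model's bounding box)
amalgamates the spaces inside a packed crown; splitting halves the
bounding box, refines the remesh and removes most of that bias.

Downstream, for an augmented randomized complete block design (RCBD)
with replicated checks: Federer-adjusted genotype means, ANOVA,
broad-sense heritability H² = σ²_G/(σ²_G+σ²ₑ), trait correlation
matrices with significance stars, correlation-matrix PCA, and normal
Q–Q / Shapiro–Wilk checks.

A synthetic crown generator (implicit union of stem, hub and curved
tapered roots, meshed by marching cubes, with a 1 mm voxel occupancy
oracle for ground truth) makes the whole pipeline testable without
field data, including photogrammetry defect models (blind-area face
removal, vertex jitter) and simulated breeding trials.

## Worked example

```sh
python examples/01_single_crown_traits.py
```

```
trait                         measured     oracle
crown volume (cm^3)               827.63     830.50
surface area (cm^2)               664.18
crown diameter (cm)                32.23
cylinder soil volume (cm^3)     22464.61   22640.96
compactness (%)                     3.68       3.67
surface:volume (1/cm)               0.80
root density (g/cm^3)               1.81
root number                         4.00       4.00
crown root angle (deg)             32.97
mean root length (cm)              14.42      14.28
```

A four-root synthetic crown is generated with exact ground truth, run
through the full pipeline (orientation, stem removal, split-half
volume, digital dissection), and each measured trait is printed next to
the voxel-oracle value: volume within 0.4%, root count exact, mean
length within 0.15 cm.  The other examples show
the split-half-vs-intact comparison on defective crowns, the trial
statistics layer, and the low-level mesh operations.

The same pipeline runs from the shell:

```sh
crownpheno simulate -n 5 --seed 1 -o cohort/       # meshes + truth ledger
crownpheno phenotype crown.obj --reference box.obj --weight 2.1
crownpheno batch manifest.csv -o cohort_traits.csv
crownpheno validate cohort/ledger.csv cohort_traits.csv
crownpheno trial-stats trial.csv -o stats/
```

## Layout

- `src/crownpheno/mesh.py` — mesh model, OBJ/PLY I/O, volumes, plane cuts
- `src/crownpheno/prep.py` — noise clearing, volumetric hole closing, calibration, orientation, stem removal
- `src/crownpheno/traits.py`, `dissect.py` — crown traits and per-root dissection
- `src/crownpheno/synthetic.py` — crown generator, voxel oracle, defect models, trial simulator
- `src/crownpheno/stats.py` — validation regression, correlations, PCA, augmented RCBD, heritability
- `src/crownpheno/cli.py`, `pipeline.py` — batch pipeline and the `crownpheno` command
- `docs/methods.md` — models, conventions and numerical choices
- `examples/` — one narrative script per capability

The package consumes meshes; photogrammetric reconstruction itself
(photo alignment, dense matching) is upstream and out of scope.
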