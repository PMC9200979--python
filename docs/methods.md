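# Methods

`crownpheno` measures cassava root-crown architecture from triangle
meshes produced by close-range photogrammetry.  This note records the
models, conventions, numerical choices and limitations behind each
stage, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate convention and preparation

Crowns are analysed in a canonical right-handed frame: the stem axis on
+Z, the soil line (stem–crown junction) at z = 0, the crown below.
Photogrammetry exports arrive in an arbitrary frame because crowns are
photographed lying on their side, so preparation proceeds:

1. **Noise clearing** — connected components smaller than a fraction
   (default 1%) of the largest component's face count are dropped.  The
   largest component is never removed.
2. **Hole closing** (below).
3. **Scale calibration** — the scene is rescaled so the reference box
   (12.5 × 12.5 × 34 cm cuboid) matches a known dimension.  Extents are
   taken from the box's minimal oriented bounding box because it lies at
   an arbitrary pose; the calibrated dimension is configurable
   (`longest` by default — the protocol does not fix which side the
   operator used, so this is the package's choice).
4. **Orientation** — the stem axis is found as the only protrusion with
   a near-constant radius profile.  Rays from the hub density peak
   (mean-shift on the vertices) are scanned over 128 sphere directions;
   each extreme slab is binned along the ray and the per-bin median
   radius (after per-bin centering, which absorbs obliqueness and
   curvature) is fit for taper.  Storage-root tips taper strongly;
   the stem does not.  Candidates are rejected when the radius exceeds
   an anatomical stem bound (4 cm) or when per-bin radius dispersion
   indicates the slab spans several structures.  The winner is refined
   by the line through the slab's cross-section centroids.  On rotated
   synthetic crowns the axis is recovered to about 1 degree (the test
   bound is 5 degrees).  A `stem_axis` override exists for irregular
   crowns.  The soil line is found by walking down from the stem tip
   and recording where the cross-section radius crosses 1.3x and 1.8x
   the stem radius; because the crown shoulder widens smoothly, a bare
   threshold crossing sits 1–3 cm below the junction, so the two
   crossings instead determine the shoulder's circle and the soil line
   is placed at its apex — exact for a spherical shoulder, within
   ~0.3 cm on the synthetic crowns.
5. **Stem removal** — a capped plane cut at z = 0 (configurable height);
   a cut plane above the mesh is a warning, not an error.

## Hole closing as volumetric remeshing

Photogrammetry meshes have holes (the blind area where the crown rests
on the background sheet) and the volume computation requires a closed
surface.  `close_holes` rebuilds the surface volumetrically:

- boundary loops are first capped with centroid fans.  Fan winding is
  irrelevant because the voxel stage classifies voxel centers by ray
  parity, and a fan's coverage parity equals the polygon's even–odd
  interior for any simple loop;
- the capped solid is voxelized at pitch = bounding-box diagonal /
  2^depth (depth 8 by default, the octree-depth convention of mesh
  sculpting tools).  The pitch is snapped per axis so both bounding-box
  faces fall exactly midway between voxel centers; otherwise planar caps
  flush with the bounding box (a stem cut, a split cross-section) sit on
  the voxel lattice and the isosurface shaves them by up to half a
  voxel — a systematic bias we measured at about −0.5% per half crown;
- a morphological closing (3-voxel ball) seals crevices and residual
  pinholes, internal pockets are filled, and the isosurface is extracted
  by marching cubes (a 0.4-voxel Gaussian on the indicator resolves
  ambiguous cells) and faired with Taubin's shrink-free filter.

On closed convex inputs the whole pipeline changes volume by well under
1% (icosphere: ≈0.03%).  Its one deliberate bias is the closing step:
concave crevices narrower than the kernel are **amalgamated** into the
solid, and the kernel's physical size scales with the bounding box.
This reproduces, at mesh scale, the behaviour of bbox-relative
volumetric remeshing: spaces inside a densely packed crown are absorbed
into the measured volume, more so the larger the model.

## Split-half crown volume

Crown volume is measured by cutting the crown with the vertical plane
through the stem axis (normal along the support-side direction),
closing each half independently, and summing.  For a watertight input
the cut cross-sections close the halves exactly, so the split estimate
equals the direct volume.  For a defective input each half is
volumetrically remeshed at a pitch set by its own, smaller bounding
box.  Finer pitch means less crevice amalgamation, so the summed half
volumes carry less of the blind-area bias than a repair of the intact
crown — the mechanism behind the protocol's accuracy gain, and the
reason model splitting improves resolution-limited volume estimates
generally.  On the benchmark cohort (below) the intact estimate is
biased high by a few tenths of a percent to ~1% and the split estimate
sits within ~0.2% of the oracle.

## Traits

- **Crown diameter**: maximum pairwise distance of vertices projected
  onto the soil plane (horizontal caliper, computed on the 2D convex
  hull).  The projection is deliberate: a deep vertical root must not
  inflate "diameter".
- **Cylinder soil volume**: π r² h of the minimal *vertical* cylinder
  about the stem axis (r = max radial vertex distance, h = vertical
  extent).  The axis is constrained because the trait models occupied
  soil space under the plant, not an abstract enclosing cylinder.
- **Compactness**: 100 × crown volume / cylinder soil volume, in
  (0, 100].
- **Root density**: 1000 × field fresh weight (kg) / crown volume
  (cm³), in g/cm³.
- **Surface-to-volume ratio**: area / volume (1/cm); low for short or
  thick roots.

## Digital dissection

The hub — the fused region around the stem base where roots merge — is
cleared by removing faces within one hub radius (plus a fixed 0.6 cm
margin that absorbs soil-line placement error) of a point one hub
radius below the soil line, together with a narrow axial cylinder that
removes the stem-cut cap.  Remaining connected components above a
volume floor (5 cm³, suppressing fibrous stubs) are root segments.
Fused roots are flagged, not split, on either of two signals: more
than one attachment scar on a component, or repeated multi-loop
cross-sections in the basal 60% of the centerline walk (a pair merged
at the hub that diverges outward); near-coaxial overlapping roots are
geometrically one root and stay unflagged.

Per-root measurements march cross-sections along the root: planes
perpendicular to the locally re-estimated direction at 1 cm steps
(re-seeded every 5 sections), centroids joined into a centerline.
Length is the polyline length extended to the tip apex plus a basal
extension where the clearance cut removed the attachment; maximum
diameter is the largest equivalent-circle diameter 2√(A/π) over
sections; the basal angle is the angle between the basal quarter of
the centerline and the horizontal plane (0° = spreading, 90° =
straight down) — with this datum the crown-level "mean of the three
lowest angles" selects the shallowest roots.  The angle datum is a
package convention (field protocols rarely state one) and can be
switched to a stem-axis reference by subtracting from 90.

## Synthetic crowns and ground truth

A synthetic crown is the implicit union of a stem cylinder, a buried
hub sphere, and curved tapered root tubes (constant-curvature
centerlines bending downward, linear radius taper, flat base and tip
caps).  The mesh is extracted from the union signed-distance field by
marching cubes (default 0.3 cm grid) — one fused surface, like
photogrammetry output, with hub overlaps counted once.  Ground truth
comes from a voxel occupancy count of the same analytic geometry at
1 mm (halving the pitch moves the volume by well under 1%), standing in
for the water-displacement reference used with real crowns; the truth
ledger also stores per-root lengths, basal-quarter chord angles, basal
diameters, the enclosing-cylinder volume and compactness.  Because the
tube surface is an envelope of spheres, its radius exceeds the nominal
taper by a factor 1/cos(taper angle) — under 1% for the shapes used —
which is shared by mesh and oracle and only visible against closed-form
frustum formulas.

The defect model removes faces whose centroids lie within a depth of
the supporting plane on the support side (−y by default, recorded in
the ledger), emulating the blind area.  Vertex jitter models
reconstruction noise.  `roots_intersect_beyond_hub` checks pairwise
tube clearance outside the hub; the separated-suite builder rejection
samples until crowns are verified contact-free, which is what "well
separated" means operationally for exact root counting.

**Benchmark conditions.** The volume benchmark uses 20 densely packed
crowns (10–14 roots, basal radii 2.2–3.2 cm, hub 5 cm) with a 1.5 cm
blind-area defect: dense packing creates the inter-root crevices on
which amalgamation acts, as in real crowns where roots press against
each other.  Sparse star-shaped crowns show no split-vs-intact
difference (both errors < 0.5%), so a sparse cohort would test nothing.
The dissection suite uses 20 thinner-rooted, verified-separated crowns
(half with straight roots, half curved).  What passing shows: the
pipeline recovers volumes, counts, lengths and angles under controlled
defects.  What it does not show: robustness to real photogrammetry
artefacts (webbed surfaces, texture-driven noise, broken roots), which
have no generative model here.

## Trial statistics

The augmented RCBD layer follows the classical check-based analysis:
block effects are block means of the replicated checks minus the grand
check mean; unreplicated test entries are adjusted by subtracting their
block's effect; the ANOVA partitions blocks, checks, adjusted tests and
the check-replication error, whose mean square estimates σ²ₑ.

Broad-sense heritability is H² = σ²_G / (σ²_G + σ²ₑ).  The genotypic
variance is estimated from the variance of adjusted test values with
the correction σ̂²_G = Var(adjusted) − σ²ₑ·(1 + 1/c), where c is the
number of checks: each adjusted value carries the block-effect
estimation error σ²ₑ/c, and omitting the correction biases H² upward
by ~0.14 at H² = 0.1 under the default design.  Negative estimates are
floored at zero and flagged.  Monte-Carlo recovery at the trial design
size (9 blocks, 5 checks, 29 tests, 200 replicates) is within 0.05 of
the injected H² across 0.1–0.9.

Correlations are pairwise-deleted Pearson r with two-sided P from
t = r√(df/(1−r²)), df = n − 2, starred at 0.05/0.01/0.001; no
multiple-testing correction is applied by default (matching common
trait-matrix practice; a Bonferroni pass can be applied downstream).
PCA is an eigendecomposition of the trait correlation matrix; loadings
are variable–component correlations, each component oriented so its
largest-magnitude loading is positive, with |loading| > 0.45 flagged.
Adjusted means are the intended PCA input.  The normality check returns
normal Q–Q pairs plus the Shapiro–Wilk statistic.

## Numerical choices

- Watertightness is the strict edge-manifold test (every edge in
  exactly two faces).  Volumes are divergence-theorem sums of signed
  tetrahedra and require a watertight, outward-oriented surface; the
  error message points at `close_holes`.
- OBJ reading honours 1-based indices (index 0 is a format error naming
  the line), fan-triangulates n-gons, merges vertices within 1e-9 model
  units and drops degenerate faces (area < 1e-12) with a logged count.
- Planar cut caps are ear-clipped; nested cross-sections (annular cuts)
  are classified even–odd by containment depth, and holes are bridged
  into their outer ring before clipping.  Cap triangles reuse boundary
  vertices, so the join is exactly watertight.
- Cohort sizes (20 crowns per benchmark, 0.3 cm mesh pitch, 1 mm oracle
  pitch) are the package's standard benchmark conditions; they keep a
  full run in the minutes range on one CPU while the oracle convergence
  property holds.

## Known limitations

- The blind-area model removes surface; it does not hallucinate webbed
  geometry the way dense stereo matching can.  The amalgamation bias is
  therefore expressed through the repair stage, not the defect itself.
- Root dissection assumes storage roots radiating from a single hub;
  branched roots and fibrous laterals are out of scope, and fused roots
  are flagged rather than separated.
- The junction (soil line) is extrapolated from the shoulder's radius
  profile assuming a smooth, roughly circular widening; crowns with an
  abrupt or asymmetric shoulder will carry a small (sub-centimetre on
  the synthetic suite) stem remnant or deficit.
- Heritability uses the classical check-error estimator, not REML; with
  strong block-by-genotype interaction it will be optimistic.
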