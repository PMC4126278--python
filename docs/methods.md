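# Methods

## The universal joint-surface coordinate system

Each bone's articular surface is flattened to a rectangle. The
medial–lateral axis *u* is defined by two reader-supplied endpoints, the
most medial and most lateral sagittal slices of the compartment; *u* maps
affinely onto that slice range and is rounded to the nearest slice
(`slice_for_u`). The anterior–posterior axis *v* is the normalized arc
length along the traced bone–cartilage boundary of a slice, anterior
endpoint at *v* = 0, with linear interpolation within polyline segments
(`arclength_parameterize`). Because the endpoints are anatomical, one
location table serves every knee; right knees need no special handling
beyond their medial/lateral slice indices, and `mirror_contour_set`
verifies the convention.

Two conventions the contour data cannot express are fixed here:

* **Tie rounding.** When *u* lands exactly half-way between two slices,
  the slice *farther from the medial end* is chosen. This rule is its own
  mirror image, so reversing the acquisition direction reverses every
  slice choice exactly — ties included — which is what makes left/right
  normalization byte-reproducible.
* **Anterior-first storage.** Suppliers contract to store boundary points
  anterior-first; `check_orientation` flags slices whose endpoint
  direction disagrees with the stack majority, since a single reversed
  trace would silently flip *v* on that slice.

## Measurement

**Thickness** (`measure_thickness`). At a boundary point, the local unit
tangent is taken by a symmetric arc-length difference (0.2 mm half-width,
equivalent to averaging the adjacent segment directions); the normal is
oriented toward the cartilage side using the nearest cartilage-surface
point, which stays correct near the ends of strongly curved boundaries
where centroid heuristics flip sign. The thickness is the distance to the
first normal-ray crossing of the cartilage surface, capped at 15 mm
(`search_cap`); a miss inside the cartilage footprint falls back to the
nearest-point distance. Points outside the footprint — the arc interval
between the projections of the cartilage surface's endpoints, with 0.1 mm
slack — are denuded and return 0, as do points where the surface has
collapsed onto the bone.

**Cartilage length** (`measure_length`). The boundary is sampled every
0.2 mm (`length_step`) and the covered fraction (thickness > 10⁻⁶ mm)
multiplied by the total arc length. The covered-extent reading of
"anterior–posterior cartilage length" is deliberate: it makes every form
of cartilage loss — thinning, shrinking coverage, denuded bone — push the
CDI downward, so the index's sign has a single interpretation.

**Aggregation** (`compute_cdi`). CDI = Σ tᵢ·Lᵢ·voxel per bone. The voxel
factor defaults to the slice thickness d_z (0.7 mm), giving mm³; an
in-plane-area alternative (d_x·d_y) is available via `voxel_mode="dxdy"`
for sensitivity analysis, since the product form admits either reading.
Locations whose slice lacks a usable contour contribute 0 and are
flagged rather than aborting the knee — severely damaged knees
legitimately have unmeasurable sites — but a bone with *no* measurable
location raises an error. Height adjustment divides by standing height in
metres (the magnitudes of adjusted values then sit in the 10²–10³ range
for mm³-scale raw CDIs). Values are rounded to 2 decimals only in output
tables; full precision is kept internally.

## Informative-location discovery

`project_denuded` marks a 50×50 (u, v) bin denuded when the measured
thickness at the bin centre is ≤ 0 mm (threshold configurable);
`accumulate_frequency` counts denuded knees per bin. `select_informative`
places sites in the most frequently denuded region two ways:

* **grid** (default, the 9-per-bone pattern): the bounding box of the
  *top-decile region* — bins with frequency ≥ 90 % of the map maximum —
  is subdivided 3×3 and sites placed at the cell centres (tercile
  midpoints). Centres rather than tercile boundary lines were chosen
  because nine interior sites cover the box evenly and never sit on its
  edge.
* **peaks**: the n highest-frequency bins subject to a minimum (u, v)
  separation (default 0.05), ties broken by lexicographic (u, v) order.

Both are deterministic and invariant to rescaling all counts. The shipped
default table (`default_informative_locations`) is a 3×3 grid per bone
over the central weight-bearing region (u ∈ {0.3, 0.5, 0.7},
v ∈ {0.35, 0.5, 0.65}); it is an *illustrative* default — the exact
coordinates used on real OAI knees are not public — and user tables can be
substituted via JSON.

## Phantoms and what they do and do not emulate

The simulator (`phantom.py`) builds stylized medial compartments: the
femoral condyle as a circular arc (default radius 22 mm, half-angle
0.70 rad ≈ 31 mm boundary) and the tibial plateau as a shallow arc
(radius 60 mm, half-angle 0.24 rad ≈ 29 mm), swept identically across a
31-slice, 0.7 mm stack (OAI DESS in-plane geometry 0.365 × 0.456 mm).
Cartilage is the outward offset of the bone arc by the ground-truth field
t(u, v) = max(T0 − thinning − Σ defect depths, 0), with hard-disc defects
in map coordinates; full-depth defects create denuded areas. Because the
field is analytic, ground-truth CDI is computable by dense integration
(`PhantomTruth.cdi`) and the pipeline recovers it to well under 1 % on
noise-free phantoms.

Severity strata encode JSN-like grades by planted denuded-area fraction
(grade 0: none; 1: ≈ 7 %; 2: ≈ 20 %; 3: ≈ 38 % of the map), with baseline
thickness declining ~0.25 mm per grade. Cohorts mix strata
(default 42/30/25/3 %, mirroring the emulated validation sample), draw
heights from N(1.69, 0.09) m, and give progressors (stratum-dependent
probability) 0.10–0.22 mm of follow-up thinning plus defect growth versus
0.01–0.06 mm for non-progressors; covariates (KL grade, JSW, HKA,
progression flags) are generated consistently with the planted severity.
Reader noise is i.i.d. N(0, sd²) jitter on every contour point plus an
optional one-slice endpoint misidentification.

What the phantoms deliberately omit: image intensities and segmentation
error structure, anatomical shape variation along the stack, correlated
(smooth) tracing error, cartilage swelling, osteophytes, and partial-volume
effects. Passing tests therefore demonstrate that the *computational*
pipeline is correct and responsive under known geometry and noise — not
that the index attains any particular reliability or validity on real MR
images, which requires access-controlled data.

## Statistics

ICCs follow the Shrout–Fleiss two-way single-measurement forms computed
from mean squares: ICC(3,1) = (MSR−MSE)/(MSR+(k−1)MSE) for intra-tester
(raters fixed) and ICC(2,1), which adds (k/n)(MSC−MSE) to the denominator,
for inter-tester (raters random, systematic shifts penalized). SRM is
mean change / SD of change with the n−1 denominator (used throughout).
Spearman, OLS linear trend (grades treated as continuous, two-sided slope
t-test on n−2 df) and the independent t-test delegate to scipy; Welch is
the t-test default with pooled available for sensitivity. Undefined
statistics (zero variance, constant vectors) raise typed errors instead
of returning sentinels. Significance is reported against α = 0.05 with no
multiple-testing correction, matching the validation design the package
supports.

## Numerical choices and limitations

* Simulation sizes in tests and the acceptance script (20-knee re-read
  cohorts, 50-knee × 20-replicate discovery sweeps, 500-run null
  calibrations) were chosen as the smallest sizes at which the checked
  properties are statistically stable; all are seeded.
* Polyline discretization errors are quadratic in vertex spacing; at the
  default 101 points per contour they are orders of magnitude below the
  0.05 mm tolerances used in tests.
* The thickness normal uses a 0.2 mm tangent probe; boundaries with
  curvature radii approaching 0.2 mm would bias the normal, but no
  anatomical bone boundary is that sharp.
* `measure_length` resolution equals the 0.2 mm sampling step; reported
  lengths are accurate to ± one step at coverage transitions.
* The CDI is a sparse-sampling proxy: damage at sites not covered by the
  location table is invisible to it by construction. This is inherent to
  the method, not an implementation limit.
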