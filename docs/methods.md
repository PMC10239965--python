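# Methods

## Section properties

A cross-section is the plane region between two simple closed polygons:
the periosteal border and the endosteal border, in mm, counter-clockwise.
Area, centroid and second moments of the solid lamina bounded by a polygon
are computed with Green's-theorem vertex summations (shoelace forms),
which are exact for the polygon; curved shapes are handled by
polygonization (closed-form checks use 4096 vertices, where the
discretization error of areas and moments is ~n⁻² ≈ 6×10⁻⁸ relative).

For the cortical ring, areas compose by outer-minus-inner; the ring's
centroid is the area-weighted composite centroid; second moments are
evaluated about that centroid directly (points are shifted before
summation, so results are translation-stable to round-off). `Imax`,
`Imin` are the eigenvalues of the 2×2 moment tensor, with

    Imax, Imin = (Ixx+Iyy)/2 ± sqrt(((Ixx−Iyy)/2)² + Ixy²)

and `theta_max = atan2(−Ixy, (Ixx−Iyy)/2) / 2` the direction (in
(−π/2, π/2]) of the axis of maximal moment; an isotropic tensor
(discriminant below 10⁻¹² relative) is reported as `theta_max = 0`,
`Irat = 0`. Moments are taken about the ring's own centroidal axes — the
mechanics convention for section stiffness; image-axis moments would add
a parallel-axis term that depends on an arbitrary origin.

`Irat = ln(Imax/Imin)` uses the natural logarithm throughout.

Contour validation: consecutive duplicates and a repeated closing vertex
are dropped; collinear point sets and zero enclosed area are degenerate;
self-intersection (shapely simplicity test on the ring) is invalid;
orientation is normalized to CCW so input winding never changes results.

### Offsetting

`offset_contour` moves each vertex **by** the offset distance along the
unit bisector of its adjacent outward edge normals. This is the node-wise
convention used when recovering borders from shell-element rings, and it
makes regular-polygon examples exact: a regular n-gon of vertex radius R
dilates to vertex radius R + δ. It is *not* an edge-parallel (true
Minkowski) offset: edges move by δ·cos(ε/2) at exterior angle ε, so the
Minkowski area formula δP + πδ² holds only in the smooth-contour limit
(within 1 % once corners are shallower than ~15°, e.g. 48-vertex convex
contours; a hexagon deviates by 1−cos 30° ≈ 13 %). Erosions that cross
the medial axis can produce an *inverted* polygon that is still simple;
these are detected (an edge reverses direction, or the winding flips)
and rejected as collapse.

### Rasterization oracle

A brute-force cross-check used only in tests: pixel centres on a regular
grid are classified against both polygons; areas, centroid and moments
are pixel sums (including the per-pixel self-moment px⁴/12). At 0.05 mm
pixels it agrees with the exact polygon computation to well under 0.5 %
on rib-sized sections, and is entirely independent of the Green's-theorem
code path.

## Rib model

Stations are percent of total arc length from the vertebral (0 %) to the
sternal (100 %) end. The default grid is 2.5 % steps from 2.5 % to
97.5 % — 39 stations, endpoints excluded; the grid is configurable.
Station points and unit tangents come from linear interpolation along the
midline polyline. Section frames take a superior "up hint", project it
off the tangent to get compass north (rib superior aspect), and complete
a right-handed triad (e_east, e_north, tangent) with east the cutaneous
side; left/right ribs are mirrored explicitly by the caller. Stations
whose contours fail validation are recorded as missing and logged, and
corridors track per-station n accordingly.

## HBM ring meshes

Rib cortical shells are described as ordered circumferential rings of
nodes with per-node (or scalar) thickness, read from a neutral JSON
format validated against a shipped schema (pydantic). Nodes are treated
as the shell **midsurface** and offset by ±t/2 — the standard
shell-element convention; a `node_surface` switch (`mid|outer|inner`)
covers models whose nodes lie on a bone surface instead. Per-element
thickness is converted to per-node values by averaging adjacent
elements. Each ring is projected onto its least-squares plane (rings
need not be exactly planar); ring centroids define the rib midline; each
ring is assigned the arc-length station of its centroid, and property
traces are interpolated linearly in station onto the measurement grid,
clamped at the terminal rings. `Ct.Ar` and `Irat` are re-derived from
the interpolated primary quantities so the identities
`Tt.Ar = Ct.Ar + Es.Ar` and `Irat = ln(Imax/Imin)` hold at every station.

A thin-shell sanity relation ties extraction to first principles:
`Ct.Ar ≈ perimeter × t`, shortened by the polygon chord factor
(exactly cos(π/n) for a regular n-gon ring: ~2 % at 16 nodes, ~3.4 % at
12 nodes).

## Corridors and audits

Corridors store mean, sample SD (n−1 denominator) and n per (sex,
rib 2–11, property, station); single-subject stations have undefined SD.
Whole-population corridors are used (no anthropometric filtering), with
no cross-station smoothing. The `CorridorModel.fit()` →
`CorridorResults` surface carries the estimates with `summary()`,
`band(k)` (mean ± k·SD), `compare()` and `plot()`.

Audits compute per-station z-scores on the stations shared by model and
corridor (undefined or zero SD stations excluded with a warning), then
per rib and property: the signed mean z (`Avg SDs`), and the percentages
of stations with z > 1, |z| ≤ 1, z < −1. The boundary |z| = 1 counts as
"within"; binning applies a 10⁻⁹ relative tie guard so a model
constructed exactly on the boundary is classified deterministically.
Reports print signed averages to one decimal and integer percentages
(which may sum to 99–101 after rounding); a parallel CSV keeps full
precision.

## Synthetic population generator

The generator emulates the study conditions the analysis assumes: 240
subjects (118 male, 122 female), ages approximately uniform per decade
over 18–90, ribs 2–11, 39 stations. Sections are **elliptical annuli**:
the outer border is an ellipse polygon whose shoelace area equals the
sampled Tt.Ar exactly (a constant pre-scale absorbs the polygon/ellipse
area ratio), major axis along compass north; the inner border erodes
both semi-axes by the cortical thickness. The family exercises every
measured property and admits closed-form oracles; real ribs' asymmetric
cross-sections are out of scope.

Mean structure (defaults, all configurable in `PopulationSpec`):

- **Tt.Ar**: female baseline 40 mm² at the rib-2 vertebral end,
  mid-rib enlargement +25·sin(π(rib−2)/9) mm² (largest near ribs 6–7),
  exponential decline exp(−0.011·(s−2.5)) toward the sternal end
  (~65 % drop across the rib). Values chosen to sit in the range of
  adult rib sections (~15–90 mm²).
- **Sex offset**: male mean Tt.Ar = female × (1 + 1.5·CV), i.e. 1.5
  population SDs above female (within the reported 1–2 SD range).
  Cortical thickness is shared between sexes, so the Ct.Ar gap comes out
  smaller (~1–1.5 SD), as observed in adult cohorts.
- **Aspect**: the target *measured* Imax/Imin ratio rises from 2 at the
  vertebral end along a Gaussian bump peaking at the 90 % station —
  15 (M) / 18 (F) on ribs 2–5, 10 (M) / 12 (F) on ribs 6–11. Because the
  eroded inner border lowers the ring's moment ratio below the solid
  ellipse value, the ellipse aspect is *calibrated* per station by
  monotone bisection so the constructed annulus actually measures the
  target ratio (exact at zero noise; `Irat` peaks at ln 15 ≈ 2.71 /
  ln 18 ≈ 2.89).
- **Thickness**: 0.85 mm at the vertebral end declining by 0.003 mm per
  % station (≈0.56 mm sternally), the sub-millimetre range of rib
  cortex. Profiles implying thickness ≥ semi-minor axis raise an error
  naming the sex/rib.

Noise: a per-subject lognormal area scale (σ_ln = 0.18) shared across
that subject's whole rib cage, independent per-station lognormal area
noise (σ_ln = 0.05), and an independent lognormal aspect perturbation
(σ_ln = 0.06); thickness is deterministic. All lognormals are
mean-corrected (E = 1) so corridor means are unbiased estimates of the
profiles, and a zero-noise population reproduces them exactly. Sampled
sections are truncated to validity (semi-minor axis ≥ 1.25×thickness;
~10⁻⁵ probability at the defaults). Station-to-station noise is
uncorrelated beyond the shared subject factor — a deliberate
simplification; real ribs likely have smoother within-rib deviations.
Demographics (height, weight, BMI) mimic adult cohort marginals but are
metadata only.

What passing tests do and do not show: parameter recovery, invariances
and audit correctness are demonstrated on this ellipse family with
similarity-dominated variation; they do not certify behaviour on real,
asymmetric, noise-correlated CT contours, nor do the default profiles
claim anthropometric accuracy beyond the orders of magnitude above.
Because the subject size factor is shared along the rib, per-station
corridor-mean errors are clustered by subject sample: recovery tests
bound the independent station residuals and the subject-mean deviation
separately, each at its 3σ normal-theory rate.

## Synthetic HBM meshes

`simulate_hbm_mesh` builds a ring mesh whose *extracted* properties land
at chosen SD offsets from a fitted corridor: targets are
mean + k·SD for Tt.Ar, Es.Ar (equivalently a fixed uniform thickness)
and Irat. Rings are elliptical midsurface polygons `λ·v(q)`; because
unit vertex normals are scale-invariant, the periosteal/endosteal areas
are exact quadratic forms in (λ, t), solved in closed form, with the
aspect q found by bisection on the extracted Irat. Rings sit on a
straight centerline spanning 0–100 % at 2.5 % steps, so chord-based
station assignment is exact and interior rings coincide with grid
stations — the area offsets are then reproduced to machine precision,
which is what makes the ±1 SD boundary case well defined. `Imax` and
`Imin` follow from the ellipse family and cannot be offset
independently; at k = 0 they sit within ~0.1 SD of the corridor mean
(the moment of the mean shape differs from the mean of moments by
O(CV²)).

## Segmentation-bias demonstration

Threshold-based CT segmentation tends to place periosteal borders
outward by ~0.42 mm on thin bone, inflating Tt.Ar. The demonstration
dilates periosteal contours by a configurable δ (default 0.42 mm),
leaves endosteal borders unchanged, and reports per-station percent
Tt.Ar increase. For convex sections the increase follows the Minkowski
formula (δP + πδ²)/A — e.g. exactly (5.42² − 5²)/5² = 17.5 % for a
circular R = 5 mm section — and across the default synthetic population
averages ≈30 %, larger where sections are small and elongated
(perimeter-to-area ratio high), i.e. toward sternal ends.

## Numerical and interface choices

- Sample SD uses the n−1 denominator.
- Corridor CSV: columns sex, rib, station_pct (one decimal), property,
  mean, sd (empty when undefined), n; floats are written in shortest
  round-trip form and parsed with round-trip precision, so
  write → read is lossless on the default grid.
- Ring-mesh JSON schema is exported as `RING_MESH_SCHEMA`.
- The CLI (`ribgeom`) is a thin layer over the library: simulate,
  measure, corridors, compare, report; figures are optional artifacts
  and never inputs; per-subcommand outputs are deterministic given the
  seed. The contour archive (per-section vertex CSV) is opt-in — a full
  default population archive is ~12 M rows.
- Default problem sizes: 64-vertex generated contours, 240 subjects,
  39 stations; the oracle and recovery test batches (50 random sections;
  20 seeds) were sized to exercise the statistics while keeping the
  whole suite around a minute on one CPU.

## Known limitations

- Elliptical-annulus sections only; no statistical shape model, no
  cortical-thickness asymmetry around the ring (per-node thickness is
  supported on the mesh side but not generated).
- Ribs 1 and 12 are outside scope, as is any age trend in profiles.
- `theta_max` is reported but not pooled into corridors (orientation
  conventions across subjects would need a registration step).
- Mesh extraction assumes rings are ordered along the rib and
  single-branch (no bifurcated shell topology).
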