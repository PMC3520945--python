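# Methods

## Data model and conventions

A terrain surface is a TIN: vertices `V` (n × 3) and triangles `T`
(m × 3 vertex-index triples).  Coordinates are metric and right-handed:
axis 0 = Easting, axis 1 = Northing, axis 2 = vertical **up-positive**.
Bathymetric depth is a negative vertical coordinate; files using
depth-positive conventions must be negated on ingest.  This choice makes
the orientation rule for normals literal: terrain imaged from overhead
has outward face normals with an upward component.

Point clouds are triangulated 2.5D — Delaunay on the E–N projection with
the vertical carried through — matching the overhead-survey setting where
the surface has one height per horizontal position.  True 3D surface
reconstruction (overhangs, caves) is out of scope.

Degenerate (zero-area) triangles are retained with a construction warning
and contribute 0 to every area; feature operations require ≥ 3 vertices
and ≥ 1 triangle.

Face normals are oriented upward; an exactly horizontal normal is
tie-broken to Northing ≥ 0, then Easting ≥ 0, so orientation is a total
order and results are reproducible.

## Virtual chain-tape rugosity

Given transect endpoints `v_s`, `v_e` (distinct in E–N projection), the
slicing plane is the vertical plane through both (equivalently through
`v_s`, `v_e` and a point directly above `v_s`).  Candidate vertices are
those with point–plane distance ≤ γ whose scalar projection on the
horizontal start→end direction lies within the endpoint span (the chain
cannot overshoot the tape).  The endpoints are appended as virtual chain
points when no selected vertex coincides with them.

**Ordering.**  Candidates are sorted by along-transect projection, ties
broken by vertical coordinate then input index — a deterministic total
order.  The alternative greedy walk over the Euclidean distance matrix
(repeatedly link the nearest unvisited candidate) is available as
`ordering="greedy"` for comparison; the two agree on clean transects
(tested) but the greedy walk can stall or jump on noisy ribbons, which is
why the projection order is the default.

**Length convention.**  Segment lengths are full 3D distances between
consecutive chain points, matching how a physical chain lies on terrain;
the in-plane projected length (each point projected into the slicing
plane first) is also exposed as `Chain.in_plane_length` — the two differ
by γ-order terms and can be compared directly.

**Defaults and edge cases.**  γ defaults to 0.5 × the median mesh edge
length: fine enough that the selected ribbon is near-continuous, coarse
enough not to capture parallel vertex rows of a regular grid.  Note the
median edge length is a 3D quantity, so on high-relief meshes it exceeds
the horizontal grid spacing; if the slicing plane falls midway between
two vertex rows of a regular grid and γ reaches both, the ordered chain
zigzags laterally and overestimates R꜀.  This is a genuine pathology of
chain draping on gridded meshes (the discrete analogue of a physical
chain's side-to-side wander); transects should be placed along sampled
terrain, and the largest along-transect gap is reported (with a warning
above 10 γ, where the chain bridges unsampled terrain).

R꜀ = L / D with D the 3D endpoint distance.  R꜀ ≥ 1 up to rounding; a
zero tape distance is an error.  The chain length of a smooth profile
sampled at spacing h is a chord polyline, so R꜀ converges to the true
arc-length ratio at second order (error ∝ h²) — verified against a
numerical-quadrature oracle on sinusoids.

## Windowed area features

**Window membership.**  A query window is a rectangle in the E–N plane
(optionally rotated about its centre).  A triangle is a member iff all
three corners fall inside the *closed* rectangle after rotating
coordinates by −orientation; the vertex set is exactly the union of
member-triangle corners.  Queries go through a KD-tree over triangle
centroids (candidates within the window circumradius plus the largest
centroid-to-corner reach, then the exact test), which returns identical
results to the exhaustive scan (tested) without touching every triangle.

**PCA plane.**  The plane of best fit minimises orthogonal scatter: the
covariance of the centred window vertices is eigen-decomposed, the
eigenvectors ordered by descending eigenvalue form the basis, and the
least-variance eigenvector — oriented upward — is the plane normal.  A
rank-< 2 point set (collinear) is a degeneracy error; an exactly vertical
best-fit plane is oriented to Northing ≥ 0 with a warning.  The default
fit weights every window vertex equally; `pca_weighting="area"` instead
fits the area-weighted triangle centroids.  On meshes with near-uniform
triangle sizes the two agree closely; vertex weighting is the default
because it is the simpler estimator and independent of triangulation
choices inside the window.

**Projected area.**  `A_p = Σ A_i |n̂_i · n̂|` — the foreshortening
cosine taken in absolute value, so back-facing (overhang) triangles add
rather than cancel.  Overlapping projections then double-count, which
inflates rugosity where the surface folds over itself; overhead-imaged
2.5D meshes cannot contain such folds, and the implementation is
validated against a rasterisation oracle on overlap-free meshes (0.5 %).

**Undefined windows.**  Windows with fewer than `min_triangles`
(default 10 — a plane fit on fewer is ill-conditioned at typical mesh
resolutions), a degenerate plane fit, or zero projected area yield
missing values with a reason code rather than exceptions, so exhaustive
feature maps stay total.  Aspect is likewise missing wherever slope is
zero (the normal points straight up; direction is meaningless and
numerically erratic).

**Conventions.**  Slope α ∈ [0°, 90°].  Aspect ψ = atan2(n̂_E, n̂_N) in
(−180°, 180°], compass-style: 0 = facing North, +90 = East.  Northness
and eastness are cos ψ and sin ψ.  Rotating the mesh by β about the
vertical axis leaves R and α unchanged and shifts ψ by −β (tested).

## Synthetic terrains

Generators mesh a regular grid (optionally jittered for irregular TINs)
and attach the analytic height function for oracle checks; identical
spec + seed gives byte-identical meshes.  Families and defaults:

| family | z(E, N) | defaults |
|---|---|---|
| flat | depth | depth 0 m |
| inclined | depth − tan α (E sin ψ + N cos ψ) | α 30°, ψ 0° |
| sinusoid | A sin(2π (E cos θ + N sin θ)/λ) | A 0.2 m, λ 1 m, θ 0° |
| peak_trough | a (N/w) exp(−(E² + N²)/w²) | a 1 m, w 1 m |
| noise_field | smoothed white noise | σ 0.05 m, ℓ 0.2 m |

Default extent 6 m × 6 m at 5 cm spacing.  The peak-and-trough surface
has exactly one peak and one trough (at N = ±w/√2) with a
maximum-slope inflection between them — the canonical shape for
demonstrating slope/rugosity decoupling.  Its amplitude/width/extent are
free parameters of the module; the defaults above are what every bundled
experiment uses.  `add_vertex_noise` perturbs verticals with i.i.d.
Gaussian noise, emulating stereo-reconstruction noise; it does not model
spatially correlated reconstruction artefacts, holes, or pose drift, so
passing tests demonstrate correctness of the geometry pipeline, not
robustness to every real-world failure mode.

## Validation experiments

**Placement translation.**  The endpoints are rigidly displaced by each
radius r ∈ {5, 10, 20, 40} cm at 12 angles (origin East,
counter-clockwise — the origin is arbitrary on isotropic terrain, fixed
for determinism), giving 1 + 4 × 12 = 49 placements that share one
orientation and tape length.  Endpoint verticals are re-sampled from the
mesh (nearest vertex) at each translated location, since a displaced
chain lies on the terrain.  The min/mean/max summary is computed over
placements with defined values, with the undefined count reported.  The
window variant evaluates an oriented rectangle (length and orientation =
the placement separation) through the area pipeline; on rough terrain
its max − min spread is far below the chain's — the area measure mostly
sees the same terrain after a small shift, while the chain may drape
over entirely different features.

**Correlations.**  Pearson over complete-case per-centre records (drop
count reported; zero-variance fields give missing entries), with
ordinary-least-squares fits (r, slope, intercept) on request.  Fits over
placement summaries default to the per-transect means.  On the
peak-and-trough surface the decoupling ordering
corr(slope, R_ne) > corr(R_pca, R_ne) > corr(slope, R_pca) holds at
every resolution tested (2 cm, 1 cm, 5 mm); the individual values depend
on the surface amplitude/width/extent relative to the fixed 1 m window
(dominated by how much near-flat periphery the centre grid includes),
which is why the bundled experiment pins all of them and reports the
matrix rather than single numbers.

## Problem sizes

The bundled correlation experiment runs the 6 m × 6 m peak-and-trough
surface at 5 mm resolution (1.44 M vertices, 2.88 M triangles) with
1 m × 1 m windows on a 25 cm stride grid (441 centres, ≈ 40 k vertices
per window), completing in about 90 s on one CPU.  Exhaustive
every-vertex maps on such meshes are supported but are hours-scale; the
stride grid is statistically equivalent for field-level summaries of a
smooth surface.

## Known limitations

- 2.5D only: overhangs double-count in projected areas (documented
  above) and violate the one-height assumption of the triangulator.
- Chain selection on regular grids is sensitive to transect placement
  relative to vertex rows (lateral zigzag, above); irregular TINs
  degrade gracefully instead.
- ESRI ASCII export rasterises by nearest centre — a presentation
  format, not an analysis-grade resampling.
- No georeferencing: inputs are assumed to be in a local metric frame.
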