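# Methods

## Model

The package treats skeletal shoulder range of motion (ROM) as a constrained
placement problem.  Geometry lives in two anatomical frames: the scapular
frame (origin at the glenoid centroid; x medial–lateral pointing from the
blade toward the glenoid, y cranial–caudal along the medial border,
z anterior–posterior normal to the blade plane) and the humeral frame
(origin at the centre of a sphere fit to the head's articular patch;
y along the proximal shaft, x fixed by the head-centre→lesser-tubercle
azimuth).  A candidate placement maps humerus points h to R h + t in
scapular coordinates.

Rotations R are parameterized sequence-independently: a shortest-arc
(no-twist) rotation carries the humeral long axis (+y) to the spherical
direction given by plane of elevation Φ (longitude about scapular y) and
abduction θ (colatitude from scapular +y), followed by an axial rotation ψ
about the resulting axis.  The map pose ↔ rotation is bijective away from
the poles θ ∈ {0°, 180°}, where all Φ describe the same axis; the simulator
optimizes only Φ = 0 there and copies the result to the redundant
longitudes.  The inclusive grid at increment Δ has
(360/Δ + 1)(180/Δ + 1)(360/Δ + 1) poses — 197,173 at the reference Δ = 5°.

At each rotation the translation t is chosen to bring the *joint proximity*
— the arithmetic mean of unsigned distances from glenoid-face vertices to
the humeral articular surface — to a positive target J\*, subject to
non-interpenetration.  Admissibility requires the converged residual
|J − J\*|/J\* ≤ 5% (threshold configurable; sweeping 2–8% is supported and
cheap because residuals are stored per pose).  Targeting the *mean*
distance penalizes placements that leave part of the glenoid uncovered, so
the criterion approximates "the whole socket keeps facing articular
surface"; it deliberately ignores ligaments and muscle, which is why the
model is a comparative tool rather than an in-vivo predictor.

## Distance fields

All distances are precomputed on regular grids spanning each mesh's
bounding box enlarged by 50% (padding fraction 0.5), 200 points per axis at
reference scale.  Node values are exact point-to-triangle distances: a
KD-tree over triangle centroids proposes k = 8 candidates, and a second
pass widens the candidate set wherever the k-nearest bound cannot certify
the minimum, restricted to a near-surface band of six median triangle radii
(beyond the band the k-candidate error is O(h²/d), far below grid
resolution).  Closed bone meshes get signed values via angle-weighted
pseudonormals (correct sign for face-, edge- and vertex-nearest queries);
open articular patches get unsigned fields.  Queries interpolate
trilinearly, never extrapolate (out-of-prism queries error, and the
simulator classifies such poses infeasible), and expose the analytic
gradient of the interpolant.  A numba kernel accelerates the pairwise
point-triangle computation when available; a pure-numpy implementation of
the same algorithm is the reference and is cross-checked in the tests.

## Translation optimizer

Per pose the solver is a projected Newton iteration on the scalar residual
J(t) − J\*: a Newton step along the interpolant's analytic gradient,
projected to first order onto the boundary of any violated clearance
constraint (each bone's proxy vertices in the other bone's signed field,
enforced symmetrically), with a step cap of 1.5 J\* and at most 30
iterations; convergence tolerance is max(10⁻⁴, 10⁻³ J\*) mm, well inside
the 5% admissibility band.  Initial guesses come from a deterministic
coarse screen — a 5³ translation grid spanning ±1.5 J\* around the
anatomical head-centre placement, evaluated vectorized — which also rejects
poses whose best coarse placement still misses the target by more than
twice J\* (the proximity function is 1-Lipschitz in t, so the screen's grid
error cannot mask an achievable pose).  Within an axial scan the previous
optimum warm-starts the next pose; failed warm starts are retried from the
screen.  The procedure is deterministic: identical inputs give identical
admissible sets.

## ROM metrics

Admissible poses are projected by the equal-area sinusoidal (sine-corrected)
map x = Φ sin θ, y = θ (Jacobian determinant sin θ, so map area equals
solid angle in square degrees).  Mobility is the volume of the alpha shape
of the 3D (x, θ, ψ) cloud; the alpha shape is the union of Delaunay
simplices with circumradius ≤ the alpha radius (5 map degrees at the
reference 5° increment; desk-scale runs at Δ = 15° or 30° scale the radius
with the increment so the shape stays connected).  The circumduction
envelope is the same construction in 2D.  Axial intensity at a (Φ, θ) node
is the count of admissible axial samples × Δ — a total measure, robust to
split axial ranges; at a node with every sample admissible this counts both
±180° endpoints (365° at Δ = 5°), a documented convention.  The functional
centre maximizes the mean intensity of map nodes within a geodesic circle
of radius `radius_coeff` × mobility^⅓; the default coefficient 0.2 map
degrees per cube-root cubic degree (0.3 in the cohort pipeline) makes the
circle large enough to act as a smoother over the saturated plateau that an
unconstrained ball joint produces, so the optimum tracks the plateau's
centroid rather than a tie-break artifact.  The search is exhaustive over
map nodes with deterministic ties (lower abduction, then lower |Φ|),
followed by local sub-grid refinement — equivalent to, but reproducible
unlike, a stochastic global search.

## Scaling law

CT-derived bone meshes lack cartilage, so the anatomical joint proximity of
a specimen scanned in its articulated pose proxies summed cartilage plus
synovial space.  `scaling_law` measures it (identical computation to the
simulator's proximity at the as-scanned placement), fits proximity ~ head
sphere-fit radius by OLS with a slope F-test, and predicts per-specimen
targets with extrapolation warnings and a positivity guard.  The package
ships no fitted anatomical coefficients; `synthetic_default_law`
(0.08 mm/mm slope, 0.2 mm intercept) exists only to give fixtures
plausible millimetre gaps and is labelled non-anatomical.

## Morphometrics

Scapula (22 landmarks) and proximal humerus (21 + 4 semilandmarks, treated
as fixed points — no sliding) are superimposed separately by generalized
Procrustes analysis (centering, unit centroid size, orientation-preserving
rotations only, mean-change convergence 10⁻¹⁰), concatenated column-wise
and decomposed by SVD PCA with a deterministic sign convention.  The 12
discrete measures use documented landmark recipes (see
`morphometrics.discrete_measures`); linear measures are scaled by scapular
centroid size and areas by its square, so uniform scaling leaves every
measure unchanged.  Regressions are independent per predictor, not
multiplicity-corrected by default (a Bonferroni column is provided).

## Synthetic fixtures

Both bones are star-shaped radial surfaces over subdivided icosphere
directions (watertight and consistently oriented by construction, ~5,120
faces at subdivision 4).  The humerus is a head sphere with an optional
planar cut of the superior sector (`head_flattening` f removes up to
0.8 r of radius at f = 1), Gaussian tubercles (σ = 14°, 110° from the
apex), and a capped-cylinder shaft; the articular patch is the angular cap
within 140° of the apex.  The scapula is a blade-like ellipsoid with a
concave spherical cap carved into its lateral end; the cap's centre of
curvature is the anatomical head-centre position, so the constructed
anatomical proximity equals `gap` exactly (default 1.8 mm for the 20 mm
head, matching the synthetic law).  The default socket half-angle is 42°:
deep enough that a glenoid pressed against a flat has mean distance
≈ sagitta/2 ≈ 2.8 mm, comfortably above the 5% admissibility band around
1.8 mm — this is what makes head flattening *remove* poses rather than
merely shift them.  Glenoid cranial tilt rotates the cap axis toward
cranial, translating the whole admissible cone to higher abduction.
Landmarks are placed from the parametrization and optionally jittered by a
seeded digitization noise (`landmark_noise`, 0.1 mm in the cohort) — the
only stochastic element; meshes are deterministic per spec.

Cohorts assign the first planted effect as an ascending gradient and each
subsequent effect through a seeded permutation accepted only when it is
nearly orthogonal to that ascent (|Pearson r| < 0.05) and every tertile of
the ascent spans most of the other effect's range — a crossed design, so
one effect acts as balanced noise in the other's regression; the truth
manifest records every parameter.

### What the fixtures do and do not emulate

They reproduce the *mechanisms* the model is sensitive to — articular
coverage, congruence, protuberance interference, socket orientation — with
idealized smooth geometry.  They do not emulate real bone surface texture,
asymmetric articular curvature gradients, scapular spine/acromion geometry
beyond coarse landmarks, or inter-specimen allometry.  Passing the
planted-effect tests therefore shows the pipeline recovers known
geometry→ROM effects through the full simulation and statistics stack, not
that any particular species comparison would come out as published.

## Problem sizes and numerical choices

Reference configuration: 5° increment, 200³ fields, 5% threshold, alpha
radius 5.  Tests and the acceptance script use desk-scale sizes chosen for
single-CPU tractability: 64³ fields with a 30° increment for the
feasibility/threshold checks, 40–48³ fields with a 15° increment and
alpha radius 15 for the 18-specimen cohort, 100 glenoid vertices and
160–200 clearance proxy vertices per bone.  At these sizes the constructed
gap is still resolved to ~0.01 mm (node distances are exact; trilinear
error scales with spacing²/curvature radius).  Degenerate inputs error
loudly: non-watertight meshes for signed fields, coplanar sphere fits,
constant regressors, empty ROMs, out-of-prism queries.  Alpha-shape
circumradii of degenerate simplices are set to +∞ (excluded at any alpha);
pole map points are deduplicated before Delaunay construction.

## Known limitations

* The admissibility criterion is permissive for congruent joints: pressing
  the head deeper can compensate partial articular coverage until
  interpenetration stops it, so unconstrained ball joints keep large ROMs
  and near-total axial freedom.  This mirrors the model's design (soft
  tissue is out of scope) but means intensity maps of idealized fixtures
  saturate; the functional-centre search copes via the large-circle
  smoothing described above.
* The coarse screen bounds its search to ±1.5 J\* around the anatomical
  placement; poses whose only feasible placements lie far outside that box
  are classified infeasible.  For articulating geometry the optimum lies
  well inside the box.
* Semilandmarks do not slide; scapulothoracic posture is out of scope; ROM
  is skeletal, not in-vivo.
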