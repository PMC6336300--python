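# Methods

`stemscan` reconstructs plot-level forest inventory attributes — stem
positions, diameter at breast height (DBH) and total tree height — from a
*single* terrestrial laser scan, and ships a simulator of the scanning
instrument so the whole pipeline can be validated against exact ground
truth.  This note records the models, the parameters that matter, and the
design choices made where the procedure left room.

## Instrument model and coordinates

The emulated instrument is a 2-D laser profiler (0.7–80 m measurement
window, ±12 mm range accuracy, 4.7 mrad beam divergence, selectable
vertical step width down to 0.1667°) rotated about the vertical axis by a
stepper motor.  Every return is a tuple (R, I, θ, φ): slant range,
intensity, vertical angle, horizontal angle.

Conventions: right-handed axes with z up and x toward φ = 0, scanner at
the origin, degrees at API boundaries and radians internally.  θ is the
signed *elevation*; the default lattice spans (−90°, 90°), which with the
full 360° rotation covers the sphere.  This represents the sensor's
190° fan mounted symmetric about the horizon — the mounting that lets the
instrument see the ground beneath nearby trees, which the per-tree ground
fitting requires.  Cartesian conversion is the signed-trigonometric
x = R cosθ cosφ, y = R cosθ sinφ, z = R sinθ, valid in all quadrants;
‖p‖ = R exactly and the inverse recovers (R, θ, φ) to 1e−9.

Returns outside the measurement window or the field of view are dropped,
never clamped.  Range/intensity maps place each return in its (θ, φ)
lattice cell; when two returns land in one cell the nearer wins, and empty
cells hold NaN.

## Scan simulator

The simulator is built to be an *analytic oracle*: every recorded range is
an exact geometric intersection, so any discrepancy downstream is
attributable to the reconstruction, not the scene.

* **Stand.**  Stems occupy the nodes of a rectangular planting grid
  (defaults 1.6 m north–south × 2.8 m west–east on a 10 m square, i.e.
  ⌊10/1.6⌋·⌊10/2.8⌋ = 18 nodes ≈ 1800 stems/ha).  Each node is vacant with
  probability 0.05 (dead trees removed from the plantation); attribute
  draws are made per node regardless of vacancy so a fixed seed yields
  nested stem sets as vacancy grows.  DBH ~ N(12.11, 2.37²) cm and height
  ~ N(8.43, 0.78²) m, truncated at zero — the distributions of the
  leaf-off ginkgo plantation the instrument was validated in.  Plan
  positions get Gaussian jitter (σ = 0.15 m), matching the scatter of the
  surveyed stem maps; a perfectly regular lattice would also create
  artificial radial occlusion alignments no real plot has.
* **Stems** are vertical tapered frustums.  `dbh` is defined at breast
  height (1.3 m above local ground); the radius decays linearly so the tip
  radius is (1 − taper) times the base (default taper 0.7).  Ray–frustum
  intersection is a quadratic.  Leaning stems are not simulated (the
  validation stand grew straight).
* **Crowns** are sparse small spheres (2–4 cm radius, 60 per tree) in the
  top 15 % of stem height, thinning toward the tip, centres never above
  the tip so the crown cannot raise the true top.  Spheres stand in for
  short branch segments: an exact ray never hits a zero-thickness segment,
  and a sphere is the zero-length capsule.  There are no leaves (leaf-off
  conditions), and intensity is a simple cosine-incidence model.
* **Ground** is flat, a tilted plane, or a sinusoidal undulation (closed
  form for planes; coarse march plus bisection for undulation).  Ground
  hits outside the plot square (+1 m margin) are discarded, emulating the
  plot extraction applied to field scans.
* **First-return occlusion** arises by construction: each lattice ray
  records its nearest intersection.  Gaussian range noise (σ = 12 mm by
  default — the instrument's ±12 mm accuracy read as one standard
  deviation; the error law is not otherwise specified) is added afterwards
  and the measurement window re-applied.
* Beam divergence is *reported* (footprint = divergence × distance) but not
  simulated: rays are infinitely thin.  Real grazing returns at stem
  silhouettes are mixed-pixel dropouts; the simulator instead produces
  clean edge hits whose range noise smears them tangentially, a slightly
  pessimistic model for circle fitting.

## Trunk detection

The cloud is sliced at breast height (±5 cm).  Within the slice, the
expected spacing of angularly adjacent returns follows from the law of
cosines, d = √(R_a² + R_b² − 2 R_a R_b cos Δ), evaluated at both the
horizontal and vertical step widths.  Two points link when their planar
distance is below k · max(d_horizontal, d_vertical) with k = 1.5, the
spacings evaluated at the pair's mean range (the adjacent-spacing formula
is defined for lattice neighbours; the mean-range evaluation extends it
symmetrically to arbitrary pairs).  Clusters are the connected components
of that relation — single linkage, computed with a KD-tree radius search
at the largest in-slice threshold followed by exact per-pair filtering;
an O(n²) union–find oracle is kept in the tests.  Components smaller than
10 points are discarded (too few for a stable circle fit).

Each cluster is fitted with a circle and *validated by diameter*: accepted
only if the fitted diameter lies within the stand's plausible limits
(library default 5–30 cm; the simulated-campaign evaluation uses 5–20 cm,
the rough thickest/thinnest-stem limits appropriate for a 12 ± 2.4 cm
stand).  Fits on short occluded arcs typically explode to implausible
diameters and are thereby rejected with an auditable status.  An optional
RMS-residual gate exists but is off by default — diameter limits are the
procedure's own validation.  Accepted candidates whose centres fall within
0.3 m of a larger accepted cluster are treated as fragments of the same
trunk and merged.

## Circle fitting

A circle is A(x² + y²) + Bx + Cy + D = 0.  Under the normalization
B² + C² − 4AD = 1 the centre is (−B/2A, −C/2A) and the radius 1/(2|A|).
With z_i = x_i² + y_i², both algebraic fits minimize Σ(A z_i + B x_i +
C y_i + D)² subject to

* Pratt: B² + C² − 4AD = 1,
* Taubin: 4A²z̄ + 4ABx̄ + 4ACȳ + B² + C² = 1,

each a 4×4 generalized eigenproblem M a = η N a solved in
centroid-centred coordinates; among eigenvectors normalizable to
aᵀN a = 1 the one with the smallest non-negative objective is taken, and
the result is re-expressed in the Pratt convention.  Collinearity is
detected beforehand (relative singular value < 1e−12).  Both are exact on
noiseless circular data.  Gauss–Newton minimizes the geometric objective
Σ(‖p_i − c‖ − r)² from a Pratt start with step halving, so the objective
is monotonically non-increasing; non-convergence within `max_iter` is
flagged on the result rather than raised.  The pipeline uses Pratt
throughout — the non-iterative fit is accurate to within a millimetre of
the geometric one on realistic arcs.

A caveat the closed-loop tests make visible: at σ = 12 mm on 6 cm-radius
stems (σ/r ≈ 0.2) *every* fitter carries a small negative radius bias on
front-facing arcs, giving a DBH bias near −1.3 cm under the default noise
model.  This is a property of circle fitting at that noise level, not of
one algorithm.

## Per-tree ground plane and p_zero

No plot-wide terrain model is built.  For each accepted trunk, the points
in a 0.6 m-diameter vertical cylinder around the centre are extracted and
reduced to the lowest 10 cm slab — ground returns plus some trunk bottom.
RANSAC (200 iterations, 2 cm inlier tolerance, minimum consensus 0.5,
seeded and deterministic) fits the local plane from random 3-point
hypotheses, refined by an SVD plane fit on the inliers.  Planes steeper
than 45° are rejected as non-ground; inclinations above 10° flag the tree
for breast-height tilt correction, which is *not* applied (at the ~3°
inclinations of the validation terrain the induced breast-height error is
about 0.2 m · tan 3° ≈ 1 cm across a 20 cm stem).  The trunk-circle centre
is projected vertically (not along the normal — the difference is <0.2 %
below 3°) onto the plane: that point, p_zero, is the tree's position and
local zero height.

## DBH, height, position

DBH is re-estimated at the *confirmed* breast height: the cloud inside the
tree's 0.8 m cylinder is re-sliced at z(p_zero) + 1.3 m ± 5 cm and fitted
with the Pratt method; the diameter (reported in cm) is the DBH and the
new centre refines the tree position and p_zero.  The re-slice fit passes
the same plausible-diameter gate as detection; if it fails (a shadowed
arc), the detection-stage fit is kept and the tree flagged.

Height uses the cylinder's candidate top set V_top = points within 0.5 m
of the cylinder's highest return.  For each of the M candidates the mean
distance md_i to its 10 nearest neighbours is computed (k falls back to
M − 1 for tiny sets); points with md_i ≤ md, the grand mean of the md_i,
are tree points, the rest are outliers or low-confidence returns (isolated
twig hits, noise).  Because min md_i ≤ md the tree set is never empty.
p_top is the highest tree point (z-ties broken by input order, for
deterministic output), and height = z(p_top) − z(p_zero), clamped at zero
with a flag if negative.  Points of neighbouring crowns inside the
cylinder are not specially handled — a known limitation shared with the
field procedure.

Heights are systematically *underestimated*: tree tops are sparsely
sampled (the vertical point spacing is ~3 cm at 10 m and the top twigs are
thin), and the KNN filter deliberately discards isolated top returns.  The
closed-loop campaign shows a height bias around −0.05 m under the default
crown model.

## Evaluation

Estimated stem maps are scored against reference tables by greedy
globally-nearest one-to-one matching within 0.5 m (about a third of the
minimum planting spacing; the field campaign matched stems by hand, so the
tolerance is this package's choice and is exposed as a parameter).
Matched = correct detection, unmatched estimate = false detection,
unmatched reference = omission; detection rate = correct / reference
count.  Paired quantities are summarized as bias = mean(est − ref) and
RMSE, with percentages relative to the reference mean; rmse² = bias² +
var(errors) holds identically.

## Problem sizes and determinism

The closed-loop campaign (`stemscan.campaign.run_campaign`, also what
`scripts/acceptance.py` runs) simulates four 10 m × 10 m plots at the
instrument's native lattice (0.1667° × 0.1°, ≈ 3.9 M rays per scan,
≈ 1.8 M returns) with σ = 12 mm noise and processes each in a few seconds;
unit tests use coarser lattices (0.25–1°).  Every stochastic stage — plot
generation, range noise, RANSAC — draws from a seeded generator, and
seeded CLI runs are byte-reproducible.

## What passing tests do and do not show

The simulator reproduces the geometry of single-scan plantation scanning —
angular sampling, range noise, occlusion, terrain tilt, sparse tree tops —
but not mixed pixels at silhouettes, multi-echo returns, wind motion,
understory, bent stems or leaf-on canopies.  Closed-loop agreement
therefore validates the *reconstruction logic* under the stated instrument
model; accuracy on real forests additionally depends on those unmodelled
effects, and the field campaign's own tables (packaged in
`stemscan.fielddata`) are the evidence on that side.
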