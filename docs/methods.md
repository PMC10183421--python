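# Methods

`fibsafe` simulates syndesmotic stabilization drill tunnels on 2-D axial
cross-sections of the distal fibula and aggregates per-subject results
into cohort *safe corridors*.  This note describes the geometric model,
its assumptions, the synthetic cohort that drives it, and the numerical
choices.

## Coordinate frame and landmarks

All analysis happens in a canonical right-sided frame: +x anterior,
+y lateral, millimetres.  Left-sided inputs are mirrored about the
y-axis at ingest, so side never appears in the geometry.  Landmarks
follow the drill-planning numbering convention:

| point | meaning |
|---|---|
| 1 | anteromedial tibial anchor (landing zone, anteriorly angulated device) |
| 4 | posteromedial tibial anchor |
| 7 / 8 / 9 | anterior / posterior / lateral cortical apex of the fibula |
| 10 | midpoint of anchors 1 and 4 (derived) |
| 11 | midpoint of apexes 7 and 8 (derived) |
| M | midpoint of the 7–8 chord, the fibular-width bisector |

The lateral cortex splits at the apexes into an anterior edge (9→7) and a
posterior edge (9→8).  Positions on it are reported as **signed
normalized locations**: percent of the edge's arc length from the
lateral apex, positive anterior, negative posterior, 0 at the apex.
Arc length is the primary normalization; the straight apex-to-apex chord
is available via `normalization="chord"` (the two coincide on straight
edges and differ on bulged or wavy cortexes).

Annotated apexes are snapped onto the contour at construction.  The snap
tolerance defaults to 1.5 mm, about five standard deviations of the
default 0.3 mm manual-marking jitter, so realistic annotations are
accepted while grossly misplaced landmarks are rejected.  Geometry uses
the snapped copies; registration uses the annotated coordinates, as
marked points would be used in practice.

## Drill-tunnel model

A tunnel is an anchor point plus a diameter *d* (default 3.5 mm, the
usual suture-button drill).  The guide-wire axis is a line through the
anchor; rotation about the anchor is the single degree of freedom.  The
drill hole is the strip of width *d* centred on the axis.  An axis is
**feasible** when

1. the bone crossing nearest the anchor lies on the medial 7–8 arc — the
   drill must pass through the fibula toward the tibial landing zone, not
   clip a lateral corner;
2. the axis exits through the lateral cortex (if it crosses it more than
   once, the crossing farthest from the anchor is the starting point —
   the drill enters at the far cortex); and
3. neither cortical apex lies strictly inside the open strip — otherwise
   part of the hole emerges from bone anterior to apex 7 or posterior to
   apex 8, i.e. the anterior or posterior cortex is perforated.
   Tangency (apex exactly on the strip boundary) counts as safe.

For convex sections the feasible angles form an interval whose endpoints
are exactly the inner tangents from the anchor to the circles of radius
*d*/2 around the apexes; the **extreme borders** are solved in closed
form (angle = direction to apex ± asin(r/L)) and their lateral-cortex
exits reported as signed locations.  Non-convex (irregular) sections use
an angular sweep: 0.25° walking from a feasible seed plus bisection of
the feasibility boundary to 10⁻⁴ degrees.  At *d* = 0 the limiting axes
pass exactly through the apexes; these candidates are built directly from
the two points to avoid a trigonometric round-trip that can put a
grazing line on the wrong side of the vertex.

The **central (ideal)** tunnel runs from the anchor through M.  M is the
midpoint of the 7–8 chord by default; a one-step refinement to the
midpoint of the bone chord cut by the axis is available
(`midpoint="axis_chord"`), since "bisector of the fibular width" admits
both readings.  An infeasible central axis is flagged, not fatal.  The
**center-center** orientation is the single axis through points 10
and 11; it has no angular freedom, so only its exit location (and a
strip-feasibility flag for the recorded diameter) is reported.

A consequence of the farthest-crossing rule worth knowing: when an
anchor lies near the extension of a lateral edge beyond its apex (the
anatomically realistic position, see below), the axis through that apex
exits on the *far* cortex, so even the most anteriorly rotated feasible
drill from the anteromedial anchor starts posterior of the lateral apex.
This is what confines the anteriorly angulated corridor to negative
(posterior) locations.  Only for anchors in the medial wedge — from
which each apex is the far crossing — do the *d* = 0 borders reach
±100 % exactly.

## Registration

Subjects are superimposed by the direct (non-reflecting) 2-D similarity
transform minimizing the sum of squared distances between the three apex
landmarks, computed in closed form via the complex-regression estimator
a = Σ w·conj(z) / Σ|z|².  Scaling is included by default (percent-based
pooling is size-free); a rigid fit is available.  Reflection is excluded
because sides are canonicalized at ingest.  The registration error is
the mean distance of the transformed apexes to the reference apexes.

Reference policies: `first`, `id:<subject>` (single reference image), or
`mean` (default): generalized Procrustes iteration of the mean shape,
rescaled each round to the cohort's mean centroid size so errors stay in
millimetres, iterated until the mean moves by less than 10⁻⁸ relative.

Registration serves overlay and quality control only.  Corridor numbers
are computed from raw per-subject percent locations, which are invariant
under similarity transforms — a property the test suite asserts to
1e-9 relative.

## Cohort statistics

Per-subject angulated solutions give feasible exit intervals
[posterior border, anterior border].  The cohort **angulated corridor**
is their intersection (anterior bound = minimum of anterior borders,
posterior bound = maximum of posterior borders); an empty intersection is
representable and flagged.  The **center-center corridor** is the range
(min/max) of the single exits.  Infeasible subjects are excluded and
counted.  Descriptives are mean ± sd (n−1) with range; the paired t-test
and Pearson correlation (scipy) compare operated vs simulated tunnel
heights and correlate them with patient height.  Degenerate inputs
(constant differences, zero variance) are flagged with t = 0 / r = NaN
and p = 1 instead of raising, matching descriptive-cohort usage.

## Synthetic cohort

No public cross-section data exist for this anatomy, so a generator
emulates the statistical structure the analysis consumes:

* **Shape mixture** — triangular convex 81 %, quadrilateral 8 %,
  irregular 10 %, truly triangular the residual 1 %.
* **Triangular convex** — apexes 7/8 on a horizontal chord (AP width
  ~ N(25, 2²) mm), lateral apex at depth ~ N(15, 1.5²) mm, medial edge a
  circular arc bulging medially with sagitta 0.15 × chord (the convex
  counterpart of the tibial incisura).  The lateral apex position is
  solved so the anterolateral/posterolateral edge-length ratio equals a
  truncated-normal draw, 1.0 ± 0.2 within [0.7, 1.5].
* **Quadrilateral** — the lateral apex replaced by two pushed-out
  corners; **irregular** — a mixture of pentagons, smooth wobbled blobs,
  and low-frequency radially perturbed triangles (amplitudes 9–14 %),
  regenerated until simple.
* **Anchors** — placed on the extension of the respective lateral edge
  beyond its apex (anchor 1 along 9→7, anchor 4 along 9→8), 10–25 mm out
  with ~1.5 mm jitter.  This abstracts "just medial to the anterior
  tibial tendon" and "just anterior to the posterior tibial tendon
  groove": from those soft-tissue landmarks the line of sight to the
  fibula runs roughly along the corresponding lateral surface, and it is
  the regime that reproduces the reported sign structure of the
  corridors (anteriorly angulated entirely posterior, posteriorly
  angulated anterior, center-center straddling the apex).
* **Annotation noise** — isotropic Gaussian jitter (sd 0.3 mm) on the
  landmark annotations only; contours are exact.
* **Heights** — simulated-side tunnel heights Y ~ 19 ± 3 mm (plafond) and
  X ~ 44 ± 4 mm (fibular tip), operated-side 23 ± 6 / 48 ± 7 mm, each
  truncated to its observed range and tied to a latent patient-height
  covariate (172 ± 9 cm) with correlation 0.42 (simulated) and 0.15
  (operated) via a Gaussian copula.
* Sides are ~54 % left; generation is bit-reproducible given the seed.

What the generator does **not** emulate: real cortical texture and
thickness, the tibial incisura's true shape (the tibial outline is
cosmetic), 3-D obliquity of the tunnel relative to the axial plane, and
the between-patient covariance of shape with size.  Passing tests
therefore certify the geometry and statistics of the pipeline, not
clinical corridor values.  In particular the registration error on the
default cohort (~1.0 ± 0.5 mm) exceeds what a homogeneous patient sample
shows, because the generator's aspect-ratio spread (sd 0.2) leaves true
shape differences in the 3-landmark residual; with shape variation
switched off the error matches the isotropic-noise Monte-Carlo
expectation within 20 %, which the suite verifies.

## Shape classification

A corner is a contour vertex whose signed turning angle, integrated over
a 2 mm arc window, exceeds 35°; super-threshold vertices within one
window merge into a single corner.  Rules: 3 corners with straight
lateral edges and a straight medial edge (max deviation < 4 % of the
chord) → triangular; with a one-signed medial bulge ≥ 4 % → triangular
convex; 4 corners with straight edges → quadrilateral; anything else →
irregular.  Straightness is judged after trimming 2 mm at the path ends,
where annotation jitter can fold a stub of the neighbouring edge into a
path; the medial-convexity test tolerates inflections up to 2.5 % of the
chord for the same reason.  These thresholds are declared
operationalizations of an otherwise visual classification and are
configurable.  Automatic apex detection (maximal lateral point plus the
extreme-x corners) exists for unlandmarked inputs and refuses contours
with fewer than three corners, such as circles.

## Numerical choices

* Geometric epsilon for tangency/intersection: 10⁻⁹ mm, configurable.
* Exit locations snap to exact 0 / ±100 within 10⁻⁷ relative arc length,
  so the apex identities are bit-exact.
* Extreme-tunnel candidates tolerate 10⁻⁷ mm clearance slack at exact
  tangency; the tangency certificate (feasible at the extreme, infeasible
  0.1° beyond) is asserted in tests.
* Report JSON rounds floats to 10 decimals and sorts keys, making runs
  with identical configuration and seed byte-identical.
* Problem sizes in the test suite: 200 random convex sections for the
  analytic-vs-sweep equivalence, 100 subjects for diameter monotonicity,
  1000 draws for distributional recovery, 96 subjects (the study scale)
  for cohort-pattern checks.

## Known limitations

* Feasibility is fibula-only: tibial cortex passage, neurovascular
  structures, and implant mechanics are out of scope.
* The breach model is apex containment; a drill may graze a concave
  stretch of the lateral cortex *between* the apexes without being
  flagged, consistent with the drill starting on that surface.
* For non-convex sections with a disconnected feasible angle set, the
  sweep reports the boundary of the component containing the seed
  (toward the lateral apex).
* Corridor magnitudes on synthetic cohorts depend on the anchor-placement
  abstraction; only their sign structure and the interval semantics are
  asserted.
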