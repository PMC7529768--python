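# Methods

## The agent-based model

Each colony is a set of point cells (default 6, half T+, half T−) on a
continuous 2-D plane, confined to a micropattern centred at the origin: a
disc of radius 97.5 µm or an ellipse with semi-axes 195.5 × 49 µm.  Time
advances in 15-minute steps for 192 steps (48 h).  Cells carry a heading
(degrees counter-clockwise from +x, modulo 360), a type, and a
persistence counter.  There is no division, death, differentiation or
cell shape: the model isolates the contribution of motility alone.

Per step, cells update in randomised order:

1. **Heading.**  When the persistence counter expires the cell re-polls
   its heading: with the neighbour rule (iii) active, the heading is the
   direction of the summed inverse-square forces from neighbours within
   the sensing radius *R* (each neighbour at distance D ≤ R contributes a
   unit vector scaled by 1/D², pointing away from the neighbour for T+,
   toward it for T−), perturbed by Normal(0, σ) noise in degrees; a zero
   net force carries no information and yields a uniform heading.
   Without rule iii the new heading is uniform.  The persistence interval
   is the per-type persistence time (T+ 105 min = 7 steps, T− 15 min = 1
   step) when rule ii is active, otherwise one step.
2. **Speed.**  Per-type mean speed (T+ 100, T− 40 µm/h) with rule i,
   otherwise both types move at the T− speed.  With the velocity-ratio
   refinement the speed is additionally multiplied by `|ΣF| / Σ|F|` over
   the sensed forces (1 when no neighbour is in range), so cells in
   force balance slow down instead of jittering.
3. **Movement.**  The step displacement `v·Δt` is executed in 1 µm
   sub-steps.  A sub-step that would leave the pattern triggers the
   border response: with rule iv the heading rotates by α away from the
   direction of the nearest exterior point (sign re-evaluated each
   retry, so a head-on approach walks around to an inward heading);
   without rule iv the cell re-polls a uniform random heading and
   retries.  A sub-step that would bring the cell within 2 µm of another
   (the projected 3-D contact distance) truncates the move at the last
   admissible position.  Cells are therefore inside the pattern and
   mutually separated after every step, by construction.

The border response without rule iv deserves a note, because it is the
single most consequential unstated detail.  Truncating blocked moves
("stop at the wall") permanently pins any cell whose re-polled force
direction keeps pointing outward; the random model then accumulates
density along the border, and neighbour-force models score *worst*
because pinned T+ cells drag T− outward.  Re-polling the heading — the
standard confinement idiom in lattice ABM frameworks — makes cells bounce
off the border, gives the random model its expected broad interior
density, and lets edge/tip preference emerge from the force rules rather
than from wall artefacts.  We measured both and kept re-polling.

Defaults for parameters that a study must fix: sensing radius R = 50 µm
(the smallest neighbourhood radius at which the two cell types show
distinct localisation, and the second point of the calibration grid),
σ = 3° (the calibration grid's midpoint), α = 20°, T+ seeding
fraction 0.5.  All are exposed in `SimParams` / the CLI.

## SCAPD

Pooled per-type positions are summarised on a fixed 256 × 256 grid
spanning the pattern's bounding box inflated by 10 % per side (the same
grid for reference and model, which is what makes grid-sum comparisons
meaningful).  The kernel is Gaussian with per-axis bandwidths selected by
the diffusion ("improved Sheather–Jones") fixed point on the pooled
coordinates; for tiny samples where the fixed point cannot be bracketed
the estimator falls back to Silverman's rule with a warning.  Grid values
are renormalised to sum to one.

High-density-area (HDA) borders come from thresholding at the midpoint of
the map's extreme values and extracting iso-contours by marching squares
(contours under 6 points dropped as noise).  Topology per pattern/type:

* disc T−: largest contour → least-squares (Kåsa) circle → centre reset
  to the origin; density counted inside.
* disc T+: the innermost contour that winds around the origin (the hole
  of the rim ridge) → circle → centre reset; density counted in the
  annulus between the circle and the pattern border.
* ellipse T−: largest contour → direct least-squares (Halir–Flusser)
  ellipse → centred, axis-aligned; counted inside.
* ellipse T+: two largest contours → ellipses → mirrored tip pair with
  shared semi-axes (maxima of the two fits) at (±mean|x|, 0); counted
  inside.  If thresholding yields a single contour a central ellipse is
  used instead, with a warning.

The chosen side is auto-checked: if the mean density on it does not
exceed the threshold, the orientation flips with a warning.  Membership
of a grid cell in a region is decided at the cell's centre.

Reference total densities T_e are the per-type grid sums inside these
borders.  A model is scored by pooling all its runs per type, estimating
densities **with the reference bandwidths** on the same grid, integrating
over the *reference* borders, and summing the absolute per-type
differences.  Self-comparison is exactly zero because every operation is
deterministic given the inputs.

## Baseline metrics

EMD is the exact optimal-transport cost between two maps with Euclidean
ground distance in µm, solved as a sparse transportation LP (HiGHS).
Full 256² maps are far beyond exact-solver reach, so maps are
block-summed to 32 × 32 by default (mass-conserving; the error on
KDE-smooth maps is a few percent, checked in the tests).  KL divergence
uses additive 1e−12 smoothing and renormalisation so exact zeros in KDE
tails stay finite.  CRPS treats, per grid point, the per-run density
values as an ensemble against the reference value, with the standard
`E|X−y| − ½E|X−X′|` estimator in its O(m log m) sorted form, averaged
over grid points.

## Calibration

`grid_search` exhaustively scores every combination of
R ∈ {25, 50, 75, 100} µm and σ ∈ {1, 3, 5}° (12 combinations shared
between types, 144 per-type) with the same base seed per combination
(common random numbers), breaking ties toward smaller R then smaller σ.
`angle_sweep` applies the same protocol to α.  A ground truth generated
by the model itself at (R = 50, σ = 3) is recovered by the shared search
to within one grid step at 20 runs per combination (σ is nearly inert,
consistently with the angle/noise insensitivity of the model family).

## The synthetic reference generator

Real reference images (186 disc, 152 ellipse colonies) are not publicly
deposited, so tests and examples use a generator that emulates the
*qualitative* pooled organisation:

* **T−**: per colony, a compact cluster — centre uniform over the pattern
  scaled to 0.7 of its dimensions, cells scattered with 10–15 µm SD.
  Pooling colonies gives a flat-topped central density.  A single pooled
  Gaussian cannot play this role: the mass of any 2-D Gaussian inside its
  half-maximum contour is ≈ 0.5 regardless of scale, while flat-topped
  profiles place 0.6–0.8 of their mass inside the fitted border, which is
  the regime reported for real aggregated colonies.
* **T+ disc**: radius drawn as (R − margin)·Beta(6, 2) — a rim-shifted
  ring — with uniform angle.
* **T+ ellipse**: equal mixture of two isotropic 20 µm Gaussians at
  (±(a − 30), 0), truncated to the pattern.

All laws respect the 2 µm interior margin and the 2 µm minimum
separation.  What the generator does **not** emulate: cell division and
colony growth over 48 h (real imaged colonies hold more than the 6 seeded
cells), per-colony cell-count variation, anisotropic cluster shapes,
segmentation noise, and the exact empirical density magnitudes.  Passing
tests therefore demonstrate that the pipeline and the model family behave
correctly and that the reported ranking structure is reproducible on
data with the stated organisation — not that any model fits the original
cultures.

## Numerical choices and degenerate inputs

* Containment boundaries are inclusive; the ellipse margin shrinks each
  semi-axis (193.5/47 µm at the 2 µm selection margin) rather than
  offsetting the curve.
* The nearest-boundary direction on the ellipse solves the stationarity
  condition by 60-step bisection in the first quadrant (closed forms on
  the axes); at the exact disc centre the escape direction is a uniform
  random draw.
* Closed contours drop their duplicated closing vertex before fitting so
  the fit is unbiased and mirror-symmetric.
* The conic-to-geometric conversion goes through the 2 × 2 quadratic-form
  eigensystem, which handles both overall conic signs.
* `border_turn` ties (heading exactly equals the escape direction) break
  counter-clockwise; the signed difference wraps to (−180°, 180°].
* Coincident cells (D = 0) raise rather than produce infinite forces;
  the separation invariant makes them unreachable in simulation.

## Problem sizes

Default experiment sizes: 50 colonies per model for ranking (with 3
seeded replicates where means are compared), 100 for the angle sweep, 20
per combination for grid searches, and the full 186/152-colony references
for ground truths.  These reproduce the ranking structure stably; larger
sizes shrink the replicate spread (~0.02–0.08 SCAPD at 50 runs) roughly
as 1/√n.

## Known limitations

* The basic model 14 on the ellipse is measurably sensitive to α
  (SCAPD spread ~0.06–0.12 across 10–40° at 100 runs): larger turn
  angles bounce cells farther off the border and reduce border-hugging.
  An α-insensitive border response would require a different (unknown)
  confinement mechanism.
* Reference total densities from the generator vary by a few hundredths
  across seeds because the midpoint threshold depends on the single
  highest KDE lump; this is intrinsic to the threshold rule at ~500
  pooled points.
* SCAPD is evaluated on pooled aggregates only; per-colony variants are
  out of scope.
* The rule set omits division, apoptosis, differentiation, cell shape
  and substrate mechanics by design.
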