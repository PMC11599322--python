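# Methods

## Coordinate frame and apparatus model

The arena is modelled top-down in centimetres: the flower wall is the line
y = 0 with x running along it (0 ≤ x ≤ 15.2), the feeding area occupies
0 ≤ y ≤ 2.8, the transparent screen sits at y = 2.8, and the observation
chamber spans 2.8 < y ≤ 12.8. Four flowers of width 2.4 cm, depth 0.8 cm
and gap 1.6 cm are centred on the wall (centres at x = 1.6, 5.6, 9.6,
13.6). The frame was chosen so that the ray–wall intersection is a
one-line solve; the apparatus itself only fixes physical dimensions.
Pixel coordinates map to cm through a linear calibration
(`cm = (px − origin)/px_per_cm`) carried in the arena YAML.

## Facing classification

The facing ray originates at the **thorax** and points along the
thorax → head angle; bee positions are thorax positions throughout. The
visual target of a flower is its 2.4-cm x-interval on the wall (the
frontal face); the 0.8-cm protrusion is ignored for ray intersection and
only enters occupancy dilation. Intervals are closed: a ray landing
exactly on an endpoint is a hit — an arbitrary but documented and tested
tie-break on a measure-zero set. Rays with non-negative y-component of
heading (pointing away from the wall) always miss. A valid observer frame
at or behind the screen line raises an error rather than yielding a label:
during observation the screen confines the observer, so such frames signal
a tracking or calibration fault.

**Occupancy.** A flower counts as demonstrator-occupied when the
demonstrator thorax lies in the flower footprint dilated by 1.0 cm
(≈ one body length; the radius is configurable because "occupied" is not
quantified by any physical dimension). At these defaults adjacent
dilations overlap mid-gap (1.6 < 2 × 1.0); since a bee can only feed at
one flower, containment ties resolve to the nearest flower centre,
preserving the at-most-one-occupied invariant.

**Filtering.** A frame is invalid if (precedence order) it is
wall/ceiling-flagged, head or thorax keypoints are missing, head or thorax
likelihood < 0.99, or the head–thorax distance is below 0.05 cm (no
defined body axis). The abdomen never gates validity because headings need
only head and thorax. The wall/ceiling exclusion, manual in the original
protocol, is an explicit input here (flag column or frame-range mask
file) for reproducibility. Missing frames are never interpolated.
Demonstrator-invalid frames default to "all flowers unoccupied" — facing
geometry is still defined for the observer — with a toggle to mark them
invalid instead.

## Summaries

Facing seconds are frame counts divided by fps, so the six categories
partition the session exactly in frames. Bouts are maximal runs of one
non-INVALID label; INVALID gaps of ≤ 5 frames (50 ms) between identical
labels are bridged, since sub-100-ms tracking dropouts should not split a
fixation. "Immediately preceding" an unoccupied-rewarding bout is
operationalised as the predecessor bout's label (equivalently, the last
valid pre-bout frame); session-initial bouts have no predecessor and drop
out of denominators. Transition tests use bout events, not frames, as
units.

## Statistical models

All choice models are binomial with a logit link, per-bee choice
proportion as response and the choice count as weight. Colony enters as a
random intercept by default; a per-bee intercept is not identifiable when
each bee contributes a single binomial row (it is confounded with
residual binomial variation) and is therefore not fitted. Tests are
two-sided at α = 0.05.

The random-intercept fit maximises the exact marginal likelihood by
adaptive Gauss–Hermite quadrature (21 nodes centred and scaled at each
group's posterior mode), with an analytic gradient obtained as the
posterior quadrature expectation of the complete-data score. Standard
errors come from the numerical Hessian at the optimum. When the
random-effect variance estimates at the boundary (≤ 1e-8) the model is
refitted as a plain weighted GLM (statsmodels) and the fallback recorded
in the result. The fitter agrees with `lme4::glmer` (nAGQ = 25) to ~1e-3
on coefficients, standard errors and the variance component in the test
suite's cross-check.

**Separation.** With small groups, complete separation (every bee choosing
the same colour) collapses the Wald test (Hauck–Donner: SE → ∞, p → 1
despite overwhelming evidence). Intercept-vs-chance tests therefore always
also compute a likelihood-ratio test against the fixed null p = 0.5, and
report it (with the signed root of the LRT statistic as Z) whenever the
Wald statistic is degenerate; the method used is recorded in the result.

**Group comparisons** use an LRT on nested fits (group factor in/out,
df = groups − 1) and single-step Wald z contrasts on the logit scale,
unadjusted by default with an optional Tukey-style (studentized-range)
adjustment — the default is unadjusted because no particular multiplicity
correction is canonical for this three-group design.

**Facing-effect models** are fitted per group (Blue and Yellow separately,
keeping innate colour preference out of the slopes), with the four facing
times in seconds as predictors, drop-one LRTs for factor retention, and
average marginal effects: AME = 100 · β̂ · mean(p̂ᵢ(1 − p̂ᵢ)) percentage
points per second, switchable to an effect-at-the-mean. AME is the default
because it is the standard summary when the per-second effect is reported
as a single number. A condition-number check on the standardized predictor
matrix warns on near-collinearity.

**Freeman–Halton exact test.** Exact conditional p for r × c tables
(≤ 4 × 4): all tables on the fixed-margin lattice are enumerated
recursively; the p-value sums hypergeometric probabilities of tables no
more probable than the observed one, with ties admitted within a 1e-10
relative log-probability tolerance (distinct probabilities of small-count
tables are rationals whose relative gaps are orders of magnitude larger).
The implementation reduces to the classical two-sided Fisher exact test on
2 × 2 tables and is validated against an exact-rational brute-force
enumerator.

## Synthetic session generator

The generator produces what the analysis consumes — two pose tracks plus
ground truth — while matching the paradigm's printed descriptive
statistics: session durations uniform on 94–288 s at 100 fps (empirical
mean ≈ 191 s under the uniform; the published mean of 159 s would imply a
left-skewed duration distribution that is not specified, so the uniform is
used and documented), demonstrator visit counts from a rounded normal
(11.333, 2.270) truncated at 1, and wall/ceiling episodes
(exponential alternating renewal, 2-s mean episode) covering ≈ 15% of
observer frames.

**Demonstrator.** Feeding is dwell at the flower face (thorax ≈ 0.4 cm
from the wall, small jitter) covering 75% of the session split across
visits; travel between flowers runs deeper in the feeding area
(y ≈ 2.2 cm), outside the occupancy dilation, so occupancy epochs are
clean. Each visit lands on a rewarding flower except with error
probability 0.005 (the observed demonstrator error rate is ~2 errors in
~476 visits ≈ 0.004).

**Observer attention** is an alternating-renewal schedule over the four
facing categories plus off-target, with gamma dwell times (mean 0.8 s,
shape 2). Scheduling is *category-based and occupancy-conditioned*: at
each bout start the category is drawn with weights equal to the bee's
target fractions, inflated by the inverse of the time share in which the
category is realisable (occupied-rewarding attention can only happen while
the demonstrator sits on a rewarding flower), and bouts are truncated at
occupancy changes. This makes the scheduled fractions the expected
realised fractions and makes ground-truth labels exact by construction
even under heading noise. Default attention fractions (0.10, 0.08, 0.01,
0.05 for occupied-rewarding, unoccupied-rewarding, occupied-non-rewarding,
unoccupied-non-rewarding) echo bees facing flowers for roughly a quarter
of the session, mostly the rewarding ones; per-bee fractions are Dirichlet
draws around these (precision 8), which is what makes facing times vary
across bees.

**Trajectory and heading.** The observer's position is a discrete
Ornstein–Uhlenbeck walk (pull 0.06/frame, step SD 0.05 cm/frame, folded at
the walls) toward the attended flower's x and a preferred depth 0.5 cm
behind the screen — bees in this paradigm sit pressed against the
screen — or toward a random wander anchor during off-target bouts. The
per-frame heading is the direction from the thorax to the attended
flower's wall-face centre plus von Mises noise (κ = 50 by default,
angular SD ≈ 8°); off-target headings point into the away-from-wall
half-plane. The OU pull is a deliberate linearisation (transient speeds
are not biomechanically constrained); its time constant (~0.17 s) was
chosen so that an attending bee is settled near its target for most of a
bout, which is what makes the flower's angular half-width (~17–19° at
3.3–4 cm range) comfortably exceed the heading-noise SD — the geometric
condition under which scheduled dwell is recoverable by the classifier.

**Artefacts.** Keypoint likelihoods are Beta(2000, 1) with dropout
probability 0.001 (dropouts are uniform on [0, 0.9]), reproducing the
observation that the 0.99 threshold removes well under 1% of frames beyond
the wall/ceiling exclusion.

**Choices.** Per bee, the yellow-choice logit is α + s·Σ β_c t_c with
innate bias α = −1.2, sign s = +1 for the Yellow group, −1 for Blue, 0 for
Control, and default slopes (+0.06, +0.03, −0.04, −0.04) per second for
the four categories; choice counts are Poisson(10) truncated at 1 (or
fixed). A summary-level fast path samples facing times from the same
distributions without trajectory synthesis, for recovery studies that
need thousands of replicates.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: biomechanically realistic flight or walking
kinematics, visual saliency or occlusion by the demonstrator's body,
learning dynamics within the observation (attention is stationary within a
session), head movement independent of body axis, and tracking errors that
correlate with behaviour (wall flags and dropouts are independent
processes here; in real video they co-occur with wall-climbing).

## Validation studies

`beegaze.validation` pairs each pipeline stage with an independent oracle
or a calibration study: a dense ray-sampling classifier oracle (10,000
poses; disagreements only within numerical distance of interval edges),
exact frame conservation, recovery of scheduled dwell fractions (20 × 30-s
sessions at κ = 50, pooled over valid time, tolerance ±0.05 — the slack
covers classifier-vs-schedule boundary frames), Wald-CI coverage and power
for the choice slope (200 replicates of 22 bees × 10 choices), type-I
error of the drop-one LRT (1,000 null replicates), exact-rational
validation of the Freeman–Halton enumeration, and a 100-replicate
qualitative study checking the group-preference ordering, the positive
facing-time difference, and the signs of the occupied-rewarding and
unoccupied-non-rewarding slopes in both trained groups. Problem sizes are
the package's validation defaults and complete in a few minutes on one
CPU.

## Numerical choices and degenerate inputs

Angles are normalised to (−π, π]; headings shorter than 0.05 cm of
head–thorax separation are undefined and invalidate the frame. The
vectorised wall intersection uses `searchsorted` over interval edges with
closed-interval semantics identical to the scalar path. Optimiser
restarts use three variance starting points; non-convergence raises rather
than returning silently. Separated fits warn (`SeparationWarning`) and are
reported via the LRT path described above. Empty choice tables, single
colonies, and bees without qualifying transition predecessors degrade to
the documented fallbacks (fixed-effects fits; dropped rows) rather than
erroring.

## Known limitations

Heading is body-axis direction; head direction relative to the body is not
modelled, nor is the width of the binocular field — a frame "facing" a
flower is a geometric statement about the body axis ray. The exact test is
limited to 4 × 4 tables by enumeration cost. The GLMM supports one random
intercept factor (colony); crossed or nested structures are out of scope.
Occupancy is thorax-in-dilated-footprint; a demonstrator hovering between
flowers is unoccupied by fiat.
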