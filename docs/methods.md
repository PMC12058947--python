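# Methods

This note documents the models, conventions, parameters and design
choices behind `trajsplit`, and what the synthetic-data tests do and do
not establish about real data.

## Coordinate conventions and geometry

All analysis runs in a *canonical* frame: origin at the start-area
centre, y increasing upward. Raw logs may be in screen coordinates
(origin top-left, y down); the geometry config's `frame` tag drives the
conversion `x' = x − x_start`, `y' = y_start − y` at canonicalization.
Trials whose correct target is on the left are mirrored about the
vertical line through the start-area centre (not the screen midline —
the two coincide for the symmetric layouts the validator enforces, and
the start-centred choice stays meaningful for slightly asymmetric
configs admitted via `symmetry_tol`). After mirroring, the correct
target always sits at positive x and the wrong target at negative x,
which fixes the sign conventions below.

Regions are axis-aligned rectangles with **boundary-inclusive**
membership. Rectangles make the vertical cutoff well defined and match
the square areas typical of these displays. Shapes other than
rectangles, native formats of specific mouse-tracking packages, and
DPI/multi-monitor handling are out of scope.

## Preprocessing

* **Truncation.** The analyzed movement runs from the *first sample*
  outside the start area to the first subsequent sample inside the
  correct target area. No sub-sample boundary interpolation is done:
  sample-level anchoring is deterministic and matches common practice.
  Re-entries into the start area after the first exit do not reset the
  anchor. `IT` is the exit-sample time (stimulus-onset clock), `MT` the
  exit→entry difference; `IT + MT` equals the entry time exactly.
  Trials that never leave the start area or never reach the correct
  target are flagged unusable (distinct from response errors).
* **Time normalization.** N = 101 points, linearly interpolated at
  equally spaced times between exit and entry. 101 is the long-standing
  convention (each step = 1% of movement time) and the operation is
  idempotent at fixed N. Endpoints are reproduced exactly.
* **Downward movements.** A trial is "downward" iff any post-exit
  sample's y falls strictly below the start area's bottom edge. This is
  an operationalization choice (no standard formula exists): it catches
  movements that leave the task space downward without flagging
  ordinary lateral starts.
* **Outliers.** For each participant × condition cell and each of
  IT/MT/AUC/MAD, the cell mean and *sample* SD (n−1) are computed once,
  on trials surviving the error/downward/unusable filters, **before**
  any multi-step classification; a trial is an outlier as soon as any
  measure deviates by more than k = 2.5 SD. Single pass — thresholds are
  not recomputed after removal — so the same trials are flagged whether
  or not the cutoff is later applied. Cells with fewer than 3 trials
  are skipped with a warning. Response-error trials are excluded before
  any measure-based analysis.

## Measures

Both curvature measures are taken relative to the *ideal line* through
the movement's first and last point. Each normalized point gets an arc
coordinate `s_i` (projection on the unit chord vector) and a signed
orthogonal deviation `d_i`, positive to the left of the travel
direction, i.e. toward the wrong target in the flipped frame.

* `MAD` is the signed deviation at the step with maximal |d|; ties break
  to the earliest step (deterministic, and it biases the velocity split
  toward placing a full correction in the post-MAD segment).
* `AUC` is the **net** signed area, the trapezoid sum
  `Σ (d_i + d_{i+1})/2 · (s_{i+1} − s_i)`. Opposite-side lobes cancel
  and backtracking (decreasing s) contributes negatively. A net measure
  is required for the slightly negative condition means that nearly
  straight movement sets produce; the trapezoid-in-projection form is
  validated against a shoelace polygon-area oracle (identical up to
  floating-point accumulation). Units are px² / px; no screen-size
  normalization.

## The vertical-cutoff classifier

The cutoff is parametrized by the fraction `f` of the horizontal
distance from the start-area centre to the wrong-target centre;
`x_cut = −f · |x_wrong|`. The default cutoff touches the start area on
its left edge, i.e. `f = (start width/2)/|x_wrong|` (≈ 0.083 for the
default layout). A trial is multi-step iff any **truncated raw** sample
(not the 101-point resampled path, which could miss brief excursions
between knots) satisfies `x < x_cut` strictly — a movement that only
touches the line survives. Classified trials are flagged, never
deleted, so with/without-cutoff analyses run from one table. The sweep
relaxes `f` from the default to 1.0 in steps of 0.025 (a grid fine
enough for a smooth effect-size curve at negligible cost) and recomputes
the paired effect at each step, dropping participants who lose a
condition cell at that step.

## Velocity profiles

Speeds are computed on the time-normalized path with physical time
restored from MT — `v_i = ‖p_{i+1} − p_i‖·(N−1)/MT`, in px/ms — so the
MAD index is shared between measures and velocity. Each trial's speed
curve is split at its MAD step; the pre- and post-segments are
separately resampled to M = 101 points over their own 0–100% time
fraction (per-movement temporal alignment: the MAD occurs at different
times in different trials). Trials whose MAD lands on an endpoint
(essentially straight paths) are excluded from profile averages only —
they remain in every other analysis. Group averages are pointwise
means. The y-axis unit, px/ms, is stated explicitly on plots.

## Paired statistics

Per-participant condition means feed a classical paired *t*-test with
`dz = mean(d)/SD(d)` (sample SD, `d = incompatible − compatible`),
two-sided p. Multifactorial designs are reduced to the compatibility
main effect by collapsing over the other within-subject factors (cell
means first, then their unweighted mean when balanced; trial-weighted
with a warning otherwise); for a two-level factor the repeated-measures
F equals t², which is reported alongside. The %CC comparison applies the
same machinery to per-participant multi-step percentages. Zero-variance
differences yield NA with a reason rather than a number. No
multiple-testing correction is applied across measures.

## The synthetic-data generator

The generator emulates the statistical structure of the re-analyzed
experiments: a two-level within-subject compatibility factor,
per-participant blocks with randomly interleaved conditions, left/right
targets at random, smooth single-step movements, and a minority of
multi-step movements that start toward the wrong target — more often in
the incompatible condition — with slower initiation under incompatible
mappings.

Kinematics use minimum-jerk timing, s(τ) = 10τ³ − 15τ⁴ + 6τ⁵, whose
bell-shaped speed 30·L/T·τ²(1−τ)² provides a closed-form oracle.
Single-step paths follow a quadratic Bézier whose control point carries
a Gaussian lateral offset (positive = toward the wrong target);
multi-step trials are two minimum-jerk submovements — start → turn point
at a Uniform fraction of the distance toward the wrong-target centre,
then turn → correct target — joined by a short dwell. Because each
submovement starts and ends at zero speed, the near-stop at the turn is
intrinsic and the dwell can be brief. Gaussian positional noise is added
to every 10 ms (100 Hz) sample.

Key defaults (the reference study conditions):

| parameter | default | rationale |
|---|---|---|
| participants × trials/condition | 40 × 200 | reference experiment size |
| p(multi-step) | 0.098 / 0.175 (comp/incomp) | target %CC rates |
| IT dwell mean | 639 / 693 ms, lognormal, sd 110 ms | reported condition means; right-skewed RTs |
| participant IT intercept | sd 60 ms | realistic between-subject spread; cancels in paired diffs |
| movement-time draw | 440 ms, lognormal, sd 150 ms | plausible reach times with realistic trial-level spread |
| single-step curvature | sd 140 px (≈ 50 px trial-level MAD sd) | matches the per-trial spread implied by reported effect sizes |
| wrong-ward excursion | U(0.13, 0.28) of wrong-target distance | deep enough to be always classifiable (floor > cutoff fraction + noise margin), shallow enough that multi-step trials largely survive the 2.5 SD pass, as they evidently do in real data |
| turn dwell | U(20, 80) ms | brief pause; the deceleration itself comes from the submovement endpoints |
| submovement durations | 0.35 / 0.45 of a movement-time draw | corrections are brisk; keeps multi-step MTs inside the outlier envelope |
| positional noise | sd 2 px | cursor quantization/jitter scale |

By default the single-step path distribution is **identical across
conditions** — the generator encodes, as its null, the hypothesis that
spatial compatibility effects enter only through initial decision
errors. That construction is what makes the cutoff's effect-removal
testable: any with-cutoff spatial effect on default data is a false
positive of the pipeline (up to sampling noise, see below). An optional
`execution_bias_px` shifts the mean single-step curvature in the
incompatible condition, injecting a genuine execution-level effect for
power studies; tests verify such an effect *survives* the cutoff.

The measured IT exceeds the IT dwell parameter by the ~100 ms the cursor
needs to travel from its jittered start point to the start-area edge
(equally in both conditions, so the contrast is preserved); measured MT
is likewise a fixed fraction of the movement-time draw. The generator
reproduces level *differences* and rates faithfully, not absolute
reported means.

What the generator does **not** emulate: response errors reaching the
wrong target (the flag is honored by the pipeline but not generated by
default), downward excursions, pauses unrelated to changes of mind,
participant-level variation in multi-step propensity or curvature
style, heavy-tailed or autocorrelated motor noise, and mouse
gain/acceleration nonlinearities. Passing tests therefore show the
pipeline's operations are correct and the classification logic is sound
under realistic smooth kinematics — not that the cutoff is optimal for
any particular real dataset.

## Numerical and statistical notes

* Floating point: AUC equals the shoelace oracle to ~1e−12 relative;
  canonicalization is an exact isometry up to rounding; CSV round trips
  use `%.17g` and round-trip float parsing.
* Degenerate inputs: coincident movement endpoints (no ideal line),
  fewer than 2 samples, zero-variance paired differences, empty groups
  and sub-3-trial cells all produce explicit errors, NAs or logged
  skips — never silent numbers.
* Sampling behaviour of dz: with per-participant differences that are
  pure noise (the generator's with-cutoff null), `dz ≈ t(n−1)/√n`
  regardless of trials per participant — SD ≈ 0.16 at n = 40. A
  with-cutoff |dz| of ~0.2 on a single synthetic experiment is
  therefore ordinary; only the *absence of systematic* effects is a
  meaningful null check. Across seeds the mean with-cutoff dz is ≈ 0.06,
  a small positive residue traceable to condition-asymmetric outlier
  clipping: cells with more multi-step trials have inflated means/SDs,
  so their single-step positive tail is clipped less. This is a genuine
  property of the single-pass preprocessing order, worth remembering
  when interpreting near-zero with-cutoff effects in real data.
* All randomness flows through one `numpy` Generator seeded from a
  single integer recorded in the output metadata; identical seeds give
  byte-identical datasets.

## Problem sizes

Tests and the acceptance script use the 40 × 200 reference experiment
(16,000 trials, a few seconds end-to-end) plus smaller configurations
for unit-level checks; oracle comparisons use 1,000 random paths and
fine (N = 1001) discretizations where closed forms are checked.

## Known limitations

* The "downward movement" rule and the sample-level truncation anchors
  are documented operationalizations; datasets logged at low rates may
  warrant sub-sample interpolation.
* Exact reproduction of published per-experiment statistics requires the
  original archived datasets and their display geometries; the CLI
  accepts such data in the documented CSV/YAML schema.
* The main-effect collapse reproduces factorial F values exactly only
  for balanced two-level designs; full factorial ANOVA is out of scope.
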