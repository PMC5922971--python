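# Methods

This note records the scientific model, the parameter choices, the realism
decisions in the synthetic trial generator, the numerical conventions, and
the known limitations of `edgecode`. Values described as *published
endpoints* are behavioral/neurophysiological figures from the human
fingertip literature that the model aims to emulate; they are calibration
targets, not facts this package can derive.

## 1. Virtual fingertip model

A fingertip is a 20 × 20 mm skin patch innervated by first-order tactile
neurons ("units").

**Placement.** Unit receptive-field (RF) centers are drawn uniformly at
random, one at a time, until the mean distance from each center to its six
nearest neighbours falls to 1 mm (tolerance 0.02 mm). This reproduces the
~1 mm innervation spacing of the human fingertip and yields ≈ 390–420
units per patch. Placement is intentionally random rather than jittered-grid:
the coincidence code's hyperacuity depends on heterogeneous sampling.

**RF sizes.** Each unit's RF is a disk whose size is log-normal:
log10(size) ~ Normal(1, 0.45). Under the default **area** interpretation the
sampled quantity is the RF area in mm² (median 10 mm², median radius
√(10/π) ≈ 1.78 mm), matching the microneurography convention of reporting
field areas. A **diameter** interpretation (sampled quantity = diameter in
mm, median radius 5 mm) is selectable via
`PopulationConfig(size_interpretation="diameter")`; see §3 for why it is not
the default.

**Subfield variant.** Each unit innervates n ~ DiscreteUniform{2..64}
circular receptor elements of 250 µm diameter inside its RF disk. The first
two are placed antipodally on the RF boundary (a random diameter), which
guarantees every unit expresses its field's full spatial extent; the rest
are uniform over the disk. A unit fires when the edge passes strictly
within 125 µm of any element center.

**Uniform twin.** The control variant replaces each unit's elements with a
single element coincident with the RF disk, so activation reduces to "the
edge enters the RF". A twin shares RF centers and radii unit-for-unit with
its subfield source; paired comparisons therefore isolate the receptor
layout.

## 2. Coincidence-code discrimination

The population message is *which* units are active (binary), not firing
rates. For an edge (line segment) centered at a pivot:

* the **contactable pool** N_c is the number of units that some orientation
  of the edge about that pivot could activate. Analytically, a unit is in
  the pool iff any of its elements lies strictly within L/2 + element
  radius of the pivot (the rotating segment sweeps that disk); the dense
  rotational sweep (`contactable_pool_sweep`, 0.1° steps) reproduces this
  exactly and serves as an independent oracle in the tests.
* the **discrimination threshold** is the smallest rotation Δ (0.5° steps,
  up to the 180° symmetry of a segment) at which the Hamming distance
  between the activation vectors at 0° and Δ reaches 5 % of N_c.

The experiment (`run_paired_experiment`) builds 100 subfield/uniform pairs,
applies identical stimuli to both members of a pair, and averages
thresholds per variant and edge length. The "infinite" edge is the 44 mm
physical edge, which exceeds the patch diagonal (28 mm) and so behaves as
unbounded. Two documented alternatives are exposed:
`nc_convention="rf_reach"` normalizes the 5 % criterion by the units whose
*nominal RF disk* the edge can reach (shared between paired variants), and
`stimulus_location="random"` draws the pivot per repetition from the
central half of the patch instead of the patch center.

## 3. Model endpoint calibration and sensitivity

The published endpoints are: subfield mean threshold ≈ **1.3°** (infinite
edge) and ≈ **13.1°** (1 mm edge); uniform-minus-subfield gaps ≈ **6.4°**
and ≈ **28.4°**. The defaults here follow the stated construction
literally (area interpretation, centered edge, activation-based N_c). That
construction does **not** reproduce the endpoints, and no single reading we
evaluated reproduces all four at once:

| Configuration | t1 (inf, subfield) | t2 (1 mm, subfield) | t3 (inf, gap) | t4 (1 mm, gap) |
|---|---|---|---|---|
| target | 1.3 | 13.1 | 6.4 | 28.4 |
| A. default (area, centered, activation N_c) | 2.4 | 7.6 | 3.6 | 17.4 |
| B. as A, N_c = RF-reach pool | 2.4 | 11.6–13.7 | 3.6 | ~26 |
| C. as A, randomized pivot | ~2.4 | ~8 | ~3.6 | larger (uniform 1 mm → ~40°) |
| D. as A, log10 area mean 1.3 | 1.4 | ~6 | ~4.7 | ~15 |
| E. diameter interpretation | 0.67 | — | 7.9 | undefined* |

\* under E the uniform model fails to discriminate the 1 mm edge in ~2/3 of
runs (median RF radius 5 mm means only a handful of units can ever change
state, fewer than 5 % of the pool), so the gap is not measurable; this is
why the diameter reading is rejected despite its better t3.

Observations: (a) thresholds are nearly invariant to innervation *density*
(both the flip count and the 5 % normalizer scale with it); (b) RF *size*
is the main lever — larger fields lower the infinite-edge threshold and
raise the 1 mm threshold; (c) the 1 mm endpoint is also sensitive to the
N_c convention (B) and the uniform 1 mm endpoint to the pivot location (C).
A related consequence of A: the subfield mean threshold is slightly
*higher* for the infinite edge (2.34° ± 0.07 SEM) than for the 8 mm edge
(1.83° ± 0.07), i.e. the length series is not monotone at the long end;
under D monotonicity is restored (1.35 vs 1.59). The acceptance tests
assert the published endpoints and the monotone property against the
default configuration and currently fail there; the defaults are kept
because they are the stated construction, and the alternatives remain
available as explicit options.

## 4. Trial event-detection pipeline

Trials are 1 kHz normal-force (N) and dial-orientation (deg) traces.

* **Touch** — locate the first post-go sample above 0.2 N, then walk
  backwards to the first sample exceeding the pre-go baseline median by
  0.01 N. The two-stage rule is robust to sub-0.2 N blips before contact.
* **Force plateau** — smooth the force with the 8.7 Hz triangular filter,
  differentiate, take the maximum rate in the 50–350 ms post-touch window
  (the lower bound skips the impact transient; taking the window max rather
  than an interior local peak keeps fast ramps analyzable, whose true rate
  peak can precede 50 ms), and mark the first subsequent drop below 10 % of
  that peak. Windows whose max rate is under 0.05 N/s are rejected.
* **Rotation velocity** — 17 Hz triangular low-pass of orientation, then a
  ±1-sample central difference.
* **Speed peaks** — negative-slope zero crossings of the 8.7 Hz-low-passed
  derivative of speed; ripples below 5°/s are ignored.
* **Segmentation** — minima of the 2.1 Hz high-pass-filtered speed. All
  velocity peaks and minima later than 200 ms before the shutter opening
  are excluded first (they belong to the visually guided correction). The
  onset is the last remaining minimum at or before the first peak; the end
  is the last remaining minimum; interior minima are sub-movement
  boundaries. Minima must clear a noise gate of 8× a robust SD
  (1.4826 × MAD of the high-passed pre-go baseline) — inert on clean data,
  it prevents sensor-noise ripples from capturing the backward onset
  search.

**Filter conventions.** "Triangular filter with cutoff f" maps to a kernel
half-width in one of two ways, chosen per role. The smoothing low-passes
(17, 8.7 Hz) use the −3 dB half-power convention (half-widths 18 and 36
samples at 1 kHz): the reciprocal reading (58/114) smears speed onsets by
~40 ms and merges sub-movements 0.22 s apart. The 2.1 Hz segmentation
high-pass uses the first-null (reciprocal) convention (half-width 475): its
low-pass branch is a local-baseline estimate and must be wider than one
movement, otherwise the onset/end minima are displaced ~17 ms into the
movement on clean bell-shaped profiles. With this mixed convention the
onset/end bias on clean minimum-jerk rotations is zero.

**Summaries.** Per participant and edge length, the median |alignment
error| is computed first and then averaged across participants (the order
matters and is asserted in tests); direction-correct proportions are
averaged per participant likewise, and the 75 %-correct edge-length
threshold is linearly interpolated over the finite lengths. Aborted
(onset latency > 350 ms) and unanalyzable trials are excluded but stay
visible in the per-trial table.

## 5. Synthetic trial generator

The generator emits traces *with ground truth* so the pipeline can be
validated by parameter recovery, and its outcome statistics are themselves
calibration targets (criterion: closure, §6).

* **Design**: 10 participants × 6 edge lengths (0, 1, 2, 4, 8 mm, ∞) ×
  6 initial orientations (±10°, ±20°, ±30°) × 18 repeats, blocked by
  length (3 blocks of 36), orientations shuffled within blocks: 648 trials
  per participant.
* **Outcome model** per length: direction correct with probability
  p ∈ {∞: .995, 8: .98, 4: .92, 2: .75, 1: .58, 0: .5} (crossing 75 % at
  2 mm by construction); correct trials land Normal(0, sd) about the target
  with sd ∈ {∞: 4.30, 8: 5.93, 4: 8.70, 2: 11.47, 1: 13.50}°, resampled so
  the movement is ≥ 3° and actually heads toward the target; wrong-direction
  and dot movements are ~N(15°, 5°) away; everything clips to the ±38°
  pointer range.
* **Kinematics**: minimum-jerk rotations with duration
  0.30 + 0.003·|amplitude| s. 44 % of movements ≥ 10° split into two
  overlapping minimum-jerk sub-movements; the second starts
  max(N(220, 20) ms, half the first's duration + 60 ms) after onset — the
  floor guarantees the second component begins after the first's velocity
  peak, otherwise the speed profile would be single-peaked and the
  two-sub-movement ground-truth label would be wrong.
* **Force**: smoothstep ramp to a plateau ~N(1.64, 0.83) N (clipped to
  0.3–4 N) over ~N(0.31, 0.09) s, plus a fast contact-compliance component
  (τ = 3 ms, 5 % of plateau) and a brief 0.1 N impact transient at touch.
* **Timing**: touch ~350 ms after the go signal; rotation onset latency
  N(0.20, 0.02) s between participants with within-participant SD
  0.046–0.055 s, clipped at the apparatus' 340 ms bound.
* **Online shutter rule**: the apparatus' speed signal is a causal
  first-order low-pass (τ = 10 ms) of |dθ/dt|; the shutter opens once it
  stays below 10°/s for 200 ms, plus a 100 ms command/opening latency. The
  latency must exceed the longest sub-threshold tail before the true end:
  a minimum-jerk tail stays under 10°/s for at most ≈ 0.245 × duration
  ≈ 76 ms at the smallest amplitude (3°, ~0.31 s), so 100 ms leaves ≥ 24 ms
  margin — with less, the offline "≥ 200 ms before shutter" rule can
  discard the true end-of-rotation minimum.
* **Corrections**: trials ending outside the ±2° target zone receive a
  visually guided minimum-jerk correction ~250 ms after the shutter opens.
* **Noise**: additive Gaussian sensor noise (force 0.002 N, orientation
  0.005°), scaled by `noise_scale` (0 disables it).

**Recovery** (noiseless, 648 trials, two seeds): all trials analyzable;
touch max |error| 1.3 ms, onset 7.1 ms, end 9.2 ms, plateau force 0.15 %.
With the configured noise: onset RMSE 3.6 ms, end RMSE 3.8 ms.

## 6. Calibration closure

`expected_summary` Monte-Carlo-samples the outcome model alone (no traces,
no detection; n = 20 000 per length) to produce the per-length median
|error| and p(correct) that an end-to-end analysis of generated traces
should recover. The closure test compares the analyzed 10-participant
dataset against these targets using a combined uncertainty
√(participant-SEM² + binomial-SEM²); because 12 two-SEM comparisons
false-fail ~half the time even for a perfect generator, the test requires
|z| ≤ 2 for at least 10 of 12 quantities and |z| ≤ 3 for all, plus a 75 %
threshold in [1.5, 2.5] mm.

## 7. Numerical conventions

* Strict inequalities everywhere an activation or reachability disk is
  tested, so the analytic pool and the sweep agree exactly.
* Rotations sweep 0.5° steps to 180° (segment symmetry); the Hamming
  profile is recorded up to the threshold step.
* Filtering uses reflection padding; derivatives are central differences
  (one-sided at trace ends).
* All randomness flows from `numpy.random.SeedSequence` spawning: each
  repetition/participant gets an independent child stream, so results are
  reproducible and order-independent.
* Time is an integer 1 ms grid; event times are reported at sample
  resolution.

## 8. Limitations

* The coincidence-code endpoints are not reproduced under the stated
  default construction (§3); the sensitivity analysis brackets the causes
  (RF-size reading, N_c convention, pivot placement) but no configuration
  matches all four published values simultaneously.
* The model is binary and static: no spike timing, adaptation (FA/SA
  distinction), skin mechanics, or edge indentation depth.
* The generator's kinematic and outcome parameters beyond the published
  summary statistics are plausible inventions (documented above), not fits
  to raw data; its purpose is pipeline validation and calibration closure,
  not human-data emulation.
* The pipeline assumes one rotation episode per trial with the apparatus'
  online rules in force; free-form movement streams are out of scope.
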