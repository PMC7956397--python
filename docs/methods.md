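# Methods

## Signal model and features

The input is a thigh-worn tri-axial accelerometer trace in units of g,
nominally 25 Hz, hardware range ±8 g, with a configurable mapping of device
axes onto anatomical roles (longitudinal along the thigh, anterior-
posterior, medio-lateral) including sign flips, so the longitudinal axis
reads +1 g in quiet standing regardless of mounting. Recordings are
segmented into non-overlapping windows anchored at sample 0; a trailing
partial window is discarded so algorithm and reference label series always
share one grid. Window sizes are restricted to values that land on whole
samples at the configured rate (the 0.4 s lattice at 25 Hz does, up to
float drift, which is absorbed by a 1e-6 relative tolerance).

**Orientation** is the window mean of the *raw* longitudinal acceleration.
For a motionless sensor this equals the cosine of the thigh-to-gravity
angle, so the 0.8 g default threshold corresponds to ≈ 37° — comfortably
on the upright side of the 60° sitting/standing boundary used in
observational annotation. Low-pass filtering before the mean was
considered and rejected: the mean over a multi-second window is already an
adequate low-pass, and keeping the raw signal makes the feature exactly
interpretable as a gravity projection.

**Activity counts** quantify dynamic acceleration. The upstream device's
proprietary counts definition is not public, so the package fixes its own,
documented and configurable definition: per axis, a Butterworth band-pass
(defaults 0.25–11 Hz, scipy design order 4) applied forward-backward
(zero-phase, `scipy.signal.filtfilt` with its default odd-extension
padding) over the *whole recording*, then rectification, summation per
window, division by the window duration. One count is therefore 1 g·sample
of rectified band-limited signal, and counts-per-second values are
comparable across window sizes. Filtering the full recording once — rather
than per window — keeps short windows free of filter transients and makes
the counts of a window independent of the segmentation chosen around it.
The 0.25 Hz high-pass edge removes gravity (DC) while passing slow
postural adjustments; 11 Hz keeps the band below the 12.5 Hz Nyquist
frequency. Consequences that the test suite pins down: counts are
1-homogeneous in the dynamic signal, invariant to constant per-axis
offsets up to the sensor range, and a 2 Hz sinusoid of amplitude A yields
≈ A·(2/π)·25 ≈ 15.9·A cps.

Tri-axial mode (baseline) sums the three per-axis rectified traces before
window summation; single-axis mode (optimized variant) uses only the
anterior-posterior axis, where the gait signal of slow and walking-aid-
assisted patients is most pronounced.

Because the counts unit is defined by this filter, *thresholds expressed in
counts per second are meaningful only relative to this definition*. The
preset thresholds are retained as named presets, but any quantitative use
on a new signal source should re-run the optimizer (see below) rather than
assume threshold transferability across counts definitions.

## Classification and transitions

Both decision trees label each window independently; no bout smoothing is
applied (an intentionally simple, window-wise design — the reference
annotation granularity, not the classifier, handles minimum durations).
Threshold ties are fixed conventions: orientation ≥ SO Th counts as
upright, counts ≥ PA Th counts as dynamic. The baseline tree
(activity-first) and optimized tree (posture-first) are both provided
behind a `variant` switch; their behavioural difference is exactly the
horizontal-but-moving window (in-bed movement): dynamic under the
baseline, sedentary under the posture-first tree.

Postural transitions are flagged on window boundaries: flag 1 where a
sedentary window precedes a standing or dynamic window. Sub-window
transitions are invisible by construction. Series with fewer than two
windows have no boundaries and count zero — a documented degenerate case,
not an error.

## Validation metrics

The reference event table (contiguous, non-overlapping, covering the
analysis span) is windowized by majority duration; exact ties break toward
the label covering the later part of the window — deterministic and of
measure zero on continuous-valued data. Per activity, one-vs-rest
confusion matrices yield sensitivity TP/(TP+FN), specificity TN/(TN+FP)
and accuracy (TP+TN)/N in percent; the *total* row uses the element-wise
sum of the three matrices. Transition metrics compare the two boundary
flag arrays position-wise.

Percentage error on per-activity total time (and on transition counts) is
(reference − algorithm)/reference × 100, negative meaning algorithm
overestimation; APE is its absolute value. The pooled total error is
time-weighted: Σ|ref_a − algo_a| / Σ ref_a × 100. Its signed version
telescopes to exactly zero whenever both series live on the same grid — a
structural identity the tests assert — and the unsigned version equals
2 × m × WS / T × 100 where m is the minimum number of windows that must be
relabelled to equalize the per-activity marginals (note m is *not* the raw
disagreement count: opposing misclassification flows cancel in the
marginals; the raw count gives only an upper bound).

Ratios with zero denominators (no reference time for an activity, zero
reference transitions) are reported as not-available and excluded from
cohort aggregation instead of being imputed. Cohort summaries report
median and Q1–Q3 using linear interpolation between order statistics, with
acceptability flags at the conventional limits (sensitivity, specificity,
accuracy ≥ 80%; PE within ±10%; APE < 10%) evaluated on the median.

## Threshold optimization

The optimizer sweeps the standard lattice — WS 0.4–10 s in 0.4 s steps
(25 values) and PA Th 2–6 cps in 0.025 steps (161 values), 4025
combinations, SO Th held at 0.8 g — minimizing the cohort aggregate
(median by default; mean available) of per-subject total-activity APE.
Lattice values are generated as index × step so they are bit-reproducible.
Ties resolve to the first point in row-major (WS, then PA Th) order.
Subjects shorter than one window at a given WS are excluded from that grid
point with a warning.

The implementation factorizes the sweep — filter once per recording,
window once per WS, threshold-sweep over cached features — and the test
suite asserts bit-identical objectives against re-running the complete
pipeline at sampled grid points, so the speedup is an implementation
detail, not an approximation.

## Synthetic data generator

The simulator reduces thigh kinematics to one inclination angle θ (90°
sedentary, 0° upright) with linear-in-angle ramps (default 2 s) at posture
changes, placed at the start of the new posture's segment. Signal model:
longitudinal = cos θ + vertical gait component + noise; anterior-posterior
= sin θ + gait or sway oscillation + noise; medio-lateral = noise. Gait is
a sinusoid at the step frequency on the anterior-posterior axis (the
dominant axis for slow hospital gait) with a half-amplitude component at
twice the frequency on the longitudinal axis. Standing bouts may carry a
small sway/fidget oscillation (default 0.6 Hz): hospitalized patients
rarely stand perfectly still, and without it standing windows could never
interact with any threshold on the optimization lattice, making
standing-degradation experiments vacuous. Sensor noise is white Gaussian
(default sd 0.02 g). All randomness flows from one seed through numpy's
splittable `SeedSequence`.

Scenario presets stipulate per-bout distributions:

* `orthopedic` — gait amplitude 0.25–0.50 g, cadence 1.4–2.0 Hz, sway
  0.02–0.06 g, sessions 8–15 min of sit → walk → stand → walk cycles
  (upright bouts start dynamic, so every session contains all three
  activities and at least one sedentary-to-upright transition);
* `elderly_shuffling` — gait 0.08–0.22 g, cadence 1.1–1.7 Hz, sway
  0.03–0.08 g, longer sedentary bouts: the shuffling regime whose counts
  overlap standing activity;
* `well_separated` — a verification scenario: bout durations aligned to
  the 4 s analysis grid, fixed 0.45 g gait, quiet standing, 0.005 g noise,
  shorter sessions. Its purpose is falsifiability: any correct
  implementation must classify it perfectly, so every metric has a known
  exact value.

These amplitude regimes are package-documented stipulations chosen for
plausibility in this package's counts units; true amplitude statistics of
shuffling hospital gait are not publicly available. What passing tests on
synthetic cohorts show is that the pipeline, metrics and optimizer are
correct and that the standing-vs-shuffling confusion mechanism behaves as
in real populations; they do not certify numeric performance on any real
sensor, whose counts scale, gait harmonics, non-sagittal movements and
annotation jitter the generator does not emulate.

`scale_gait_amplitudes` rescales only the gait amplitudes of a script,
reusing the identical noise realization — the instrument for amplitude-
ladder experiments. Re-optimizing PA Th at each rung and measuring median
standing sensitivity reproduces the degradation direction: as gait
approaches standing amplitudes the APE-optimal threshold descends into the
standing count range and standing sensitivity falls monotonically.

## Numerical and interface choices

* Window-size × sample-rate products must be integers within 1e-6
  relative; event-table contiguity uses a 1e-9 s tolerance.
* `filtfilt` padding is the scipy default (odd extension, 3 × filter
  length), capped at N−1 for very short recordings.
* CSV artifacts carry `#`-prefixed provenance headers (package version and
  the exact parameter set); readers skip comments, so round trips are
  lossless. JSON reports embed the same stamp.
* Problem sizes in tests and the acceptance script (cohorts of 5–10
  subjects, sessions of 2.5–15 min) were chosen as the smallest scales at
  which every cohort-level property is exercised with stable medians.

## Known limitations

* Counts are not numerically comparable to any proprietary device counts;
  thresholds must be re-optimized per counts definition.
* The simulator's single-angle kinematics cannot produce lying-vs-sitting
  differences, stair-specific signatures, sensor drift or clipping.
* Transition detection is grid-quantized; transitions shorter than one
  window boundary apart are merged.
* The optimizer's objective surface is piecewise constant in PA Th, so
  ties are common and the row-major tie-break (favoring small WS and low
  PA Th) is part of the contract.
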