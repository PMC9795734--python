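# Methods

## The assay and its measurements

A single fish swims in a cylindrical arena (10 cm diameter) with a glass rod
vibrating near 40 Hz at the center; attraction to the rod is a foraging
behavior mediated by the lateral line. A markerless pose estimator provides
per-frame pixel coordinates and a confidence ("likelihood") for five
markers: head-left, head-center, head-right, caudal fin and rod center. One
video may hold two dishes; each dish's marker set is processed
independently.

From a calibrated, QC'd track the pipeline computes, per session:

- **NOA** (number of approaches): maximal runs of frames with
  `dist(head_center, rod) <= radius` (default 1.3 cm). The boundary is
  closed — a frame exactly at the radius is inside — and a session that
  begins inside the radius counts as one approach classified at frame 0.
  These are fixed, documented conventions; no debouncing is applied by
  default (`min_gap_frames = 0` exists for sensitivity analysis only).
- **Approach side**: left iff the head-left marker is strictly closer to
  the rod than the head-right marker at the entry frame, right iff
  strictly farther. An exact tie inherits the previous frame's side, and a
  tie with no prior frame is "left" — a deterministic tie-break that
  matters only on degenerate synthetic inputs.
- **DIR / DOR**: seconds inside / outside the radius. Both are attributed
  per-frame to a facing side by the same marker-proximity rule (rather than
  per-event), so `DIR_left + DIR_right = DIR_total` and
  `DIR_total + DOR = session duration` hold exactly up to frame
  quantization. Facing outside the radius uses marker proximity as well,
  not heading angle.
- **Swim distance**: summed frame-to-frame displacement of the head-center
  marker (the head-center is the single marker tracked most reliably and
  defines the approach events; using it for distance keeps one reference
  point throughout).

## Track QC

A frame is flagged when *any* of the five markers falls below the
confidence threshold (default 0.92, the empirical operating point of the
pose model this dialect comes from). For every maximal flagged run, the x
and y of **all** markers are linearly interpolated between the frame
immediately before and immediately after the run — whole-frame replacement,
which is more destructive than per-marker repair but matches how such
tracks are conventionally cleaned and keeps all five markers mutually
consistent. Runs touching the session boundary have a single anchor and are
filled with that anchor's values (constant extrapolation), logged with the
run length. Repaired frames get likelihood equal to the threshold so their
provenance survives a round-trip through track files. A session with every
frame flagged is an error: there is nothing to anchor the interpolation.

## Radius selection

`scan_radius` recomputes per-fish NOA for each candidate radius (default
0.5–2.5 cm in 0.1-cm steps) in two groups and scores each radius by the
rank-based two-sample AUC — the probability that a randomly drawn fish from
the second group out-approaches one from the first (ties count half),
computed from the Mann–Whitney U statistic. AUC was chosen because it is
threshold-free, invariant to monotone transformations of NOA, and directly
operationalizes "best discriminates"; the full per-radius table is returned
so alternative scores can be compared. Ties go to the smallest radius.
Groups need at least 2 members each (no dispersion otherwise).

## Laterality statistics

- **Left–right ratio** `r = right / (left + right)`, on NOA counts or DIR
  seconds. `r` is *undefined* (NaN) when both sides are zero — fish with no
  approaches are excluded from histograms, never coerced to 0.5. Preference
  bins: `r < 0.33` left, `0.33 <= r <= 0.67` balanced (closed interval),
  `r > 0.67` right.
- **Bias index** `max(left, right)/(left + right)` ∈ [0.5, 1], identically
  `max(r, 1 − r)`; property-tested as an algebraic invariant.
- **Repeatability ICC**: from a complete subjects × repeats matrix, the
  two-way mean-squares decomposition gives MSR (between subjects), MSC
  (between repeats) and MSE (residual). The consistency ICC is
  `(MSR − MSE)/(MSR + (k−1) MSE) = (F − 1)/(F + k − 1)` with
  `F = MSR/MSE`, df1 = n−1, df2 = (n−1)(k−1); the absolute-agreement
  (two-way random raters) variant adds `k (MSC − MSE)/n` to the
  denominator. Both are reported. Published repeatability kappas for this
  assay follow the consistency identity; one printed row (F = 3.0 → 0.39
  rather than 0.40) is consistent with F having been rounded for print, so
  the identity is checked at the printed precision of F. Negative kappas
  are clipped to 0 for reporting. Interpretation bins: < 0.2 none,
  0.2–0.4 fair, 0.4–0.6 moderate, 0.6–0.8 substantial, ≥ 0.8 almost
  perfect — anchored to the labels conventionally printed with these
  values. Missing cells are rejected rather than imputed.
- **Kendall's τ-b** (tie-corrected) with exact permutation p-values for
  small untied samples and the tie-corrected normal approximation
  otherwise (scipy's implementation; verified in the tests against an
  O(n²) pair-counting oracle and a Mahonian-recursion enumeration of the
  exact null).
- **Fasting deltas**: per-fish after − before differences, requiring an
  exact id match between conditions (unmatched ids are an error listing
  the ids).
- **Paired Wilcoxon signed-rank** with Holm step-down correction over an
  explicitly declared family — families are never inferred from whatever
  happens to be in a table. All-zero difference vectors make the test
  undefined; they are reported as such and excluded from the Holm family.

## The synthetic generator

`simulate_session` emulates the assay, not fish biomechanics. The
head-center trajectory is smoothed random-waypoint motion in the annulus
between the approach radius (+0.8 cm margin) and the arena wall, with
`n_events` scripted approach excursions inserted at random times: a
straight leg aimed at a point `approach_depth_cm` from the rod and offset
to the scripted side, an orbital dwell at that depth (exponential dwell
draw, mean `dwell_mean_s`, capped at 3× the mean), and a radial exit.
Because the lateral head markers are placed at a fixed half-width
perpendicular to the instantaneous heading (computed from frame-to-frame
displacement), the marker-proximity side rule reproduces the scripted side
by construction, with a ~0.5-cm geometric margin against ties. Scripted
legs take a fractional first step on exit so no frame lands exactly on the
radius boundary, keeping ground truth and detector free of knife-edge
disagreements. Ground-truth entry/exit frames are read off the clean
geometry, so on noise-free sessions the detector must agree exactly.

Likelihoods of good frames are uniform in [0.95, 1.0]; `corrupt_confidence`
corrupts each frame independently with probability `dropout_rate`, dropping
one random marker's likelihood into [0, 0.92) and kicking its coordinates
by a ~25-px jump — so the 0.92 threshold separates good from corrupted
frames exactly. All randomness flows from a single seed; identical
parameters and seed give byte-identical track files.

Defaults (units, rationale): arena 10 cm, session 180 s, radius 1.3 cm and
threshold 0.92 — the assay's standard conditions; fps 20 (the video frame
rate is not fixed by the assay; 20 fps is typical of the webcam hardware
used for it and is exposed as a parameter); pixels_per_cm 50 (a 10-cm dish
spanning ~500 px); swim speed 4 cm/s and n_events 12 with 1.5-s mean
dwell — a realistic activity level for a VAB-positive fish, giving ~20 s
DIR per 3-min session; head half-width 0.25 cm and body length 1.5 cm,
matching adult *Astyanax* head proportions at this scale.

What the generator does **not** emulate: pose-network error structure
(errors are iid dropouts/jumps, not the correlated failures of a real
network), wall-following and burst-glide kinematics, rod vibration
dynamics, or two-fish interactions. Passing tests therefore validate the
*analysis* — event detection, repair, statistics — on tracks with known
truth; they say nothing about pose-estimation accuracy on real video.

## Numerical choices and problem sizes

- Distances are always computed in cm after calibration; calibration
  conflicts > 5 % between an explicit scale and one derived from arena
  geometry warn and keep the explicit value.
- Interpolation uses `np.interp`, whose constant end-extrapolation
  implements the boundary-run rule directly.
- The test suite exercises 100 noise-free + 100 dropout sessions for event
  recovery, cohorts of 15 fish × 10 events per side-bias level for
  parameter recovery, and 1000 short (20–45 s) random-parameter sessions
  for the accounting invariants — sizes chosen to give tight binomial CIs
  while keeping the default run fast.
- MSE = 0 in the ICC (identical repeats with subject spread) is treated as
  F = ∞, kappa = 1, p = 0.

## Known limitations

- Whole-frame repair discards good markers in flagged frames by design
  (fidelity to the standard cleaning rule over cleverness).
- The AUC radius score is directional (group B over group A); swap the
  groups or reflect the score for the opposite contrast.
- `derive_calibration`'s track-based arena span underestimates the true
  diameter because fish avoid the wall; prefer an explicit span or scale.
- GLM/ANOVA model selection on NOA/DIR is out of scope; the tidy output
  tables are designed to feed external model-fitting directly.
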