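# vabtrack

Behavioral quantification for **vibration attraction behavior (VAB)** assays:
a fish in a 10-cm circular arena is presented with a rod vibrating at
~40 Hz, and markerless pose tracks (DeepLabCut-style exports with head-left,
head-center, head-right, caudal-fin and rod markers) are turned into the
assay's standard measurements and laterality statistics. The package is
aimed at behavioral biologists analyzing lateral-line–driven foraging
behavior in *Astyanax mexicanus* cavefish and surface fish, or any similar
zone-entry assay.

## What it computes

For each session (default: 3 min of video, 1.3-cm cutoff radius around the
rod, confidence threshold 0.92):

- **Track QC** — frames where any marker's likelihood falls below the
  confidence threshold are repaired by linear interpolation of *all*
  markers between the nearest reliable frames.
- **NOA** — number of approaches: maximal runs of frames with the
  head-center marker within the cutoff radius, each classified *left* or
  *right* by whichever lateral head marker is closer to the rod at entry.
- **DIR / DOR** — time in and out of the radius, split per-frame into
  left- and right-facing components; plus total swim distance.
- **Radius scan** — recomputes NOA over radii 0.5–2.5 cm (0.1-cm steps) and
  selects the radius that best discriminates two groups by the rank-based
  two-sample AUC.
- **Laterality statistics** — the left–right ratio
  `r = right / (left + right)` (`r < 0.33` left preference, `0.33–0.67`
  balanced, `> 0.67` right preference), the bias index
  `max(left, right) / (left + right)`, single-rater intraclass correlation
  repeatability `κ = (F − 1)/(F + k − 1)` for k repeated assays (both
  consistency and absolute-agreement variants), Kendall's τ-b rank
  correlations against superficial-neuromast counts, fasting deltas
  (after − before), and paired Wilcoxon signed-rank tests with Holm
  correction.
- **Synthetic sessions** — a trajectory simulator that scripts approach
  events with known sides, dwell times and likelihood dropouts, providing
  exact ground truth for every downstream stage.

## Worked example

```python
from vabtrack import (SimParams, simulate_session, clean_tracks,
                      detect_approaches, summarize, laterality_record)

params = SimParams(seed=7, n_events=10, p_right=0.8, dropout_rate=0.02)
tracks, truth = simulate_session(params)

clean, report = clean_tracks(tracks, threshold=0.92)
# report: repaired 61 of 3600 frames in 60 runs

events = detect_approaches(clean, radius_cm=1.3)
# [(261, 'right', 1.35 s), (557, 'left', 1.05 s), (868, 'right', 1.9 s), ...]

summary = summarize(clean, radius_cm=1.3)
# noa_left=3, noa_right=7, noa_total=10,
# dir_total_s=20.5, dor_s=159.5, swim_distance_cm=644.8

rec = laterality_record(summary.noa_left, summary.noa_right,
                        summary.dir_left_s, summary.dir_right_s)
# lr_noa_ratio=0.7, bias_index_noa=0.7, preference_noa='right'
```

The session was scripted with 10 approaches biased 80% to the right; the
detector recovers all 10 events after repairing the 2% likelihood dropout,
and the fish's NOA ratio of 0.7 lands in the right-preference bin.

The same pipeline is available from the shell:

```sh
vabtrack simulate --n 20 --seed 7 --out sims/
vabtrack analyze sims/session_*.csv --pixels-per-cm 50 --out analysis/
vabtrack stats analysis/behavior_summary.csv --out stats/
```

Each command writes tidy CSV tables plus a JSON manifest (config snapshot,
input checksums, seed, version, row counts) for reproducibility.

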