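# Methods

## Problem and pipeline

`casatrack` estimates sperm vitality — the fraction of sperm heads moving
fast enough to be considered viable — from microscopy video, and turns it
into a clinical suitability verdict for artificial insemination. The
pipeline has four stages:

1. **Detection.** Any provider of per-frame bounding boxes with confidence
   scores can feed the pipeline: a trained CNN whose output is loaded from a
   detection table, or the shipped classical blob detector. Detections with
   score strictly greater than 0.8 are kept (configurable to an inclusive
   comparison), capped at 100 per frame.
2. **Tracking.** Boxes are reduced to centroids (the midpoint of the box's
   start and end coordinates). Centroids are associated to existing tracks
   by greedy minimum-Euclidean-distance matching under an 80 px gate: the
   globally smallest still-available (track, centroid) distance is assigned
   first, ties broken by lower track id then lower centroid index, and no
   pair farther apart than the gate is ever linked. Unmatched centroids
   start new tracks; tracks unmatched for more than `max_missed_frames`
   consecutive frames (default 5, i.e. 0.1 s at 50 fps) are retired with
   their history intact. There is no motion model: association uses the last
   recorded position only. An optimal-assignment mode (Hungarian algorithm
   on the gated cost matrix) is config-selectable; greedy is the default.
3. **Speed and viability.** A track's speed is its mean path speed: the
   cumulative centroid path length divided by the track's lifetime
   ((last − first frame)/fps). The physical criterion — a viable sperm swims
   at ≥ 34.5 µm/s — is converted to pixels with the 0.66 µm/px calibration
   and floored to 52 px/s; a track at or above the cut is viable
   (the boundary is inclusive; configurable).
4. **Vitality and verdict.** `n_found` counts all tracks; `n_live` those
   spanning ≥ 2 frames (a defined speed); `n_viable` those above the cut.
   Count-mode vitality (the default) is `100 · n_viable / n_live`; a
   distance-weighted mode (viable tracks' share of total path length) is
   also exposed because the vitality ratio can be read either way. A sample
   with vitality strictly greater than 58% is judged suitable.

## Parameters that matter

| parameter | default | unit | role |
|---|---|---|---|
| `score_threshold` | 0.8 | – | detection confidence gate (strict >) |
| `gate_px` | 80 | px | maximum association distance |
| `max_missed_frames` | 5 | frames | occlusion tolerance before retirement |
| `um_per_px` | 0.66 | µm/px | pixel calibration at 400× magnification |
| `fps` | 50 | 1/s | video frame rate |
| `viable_speed_um_s` | 34.5 | µm/s | viability speed criterion (→ 52 px/s) |
| `suitability_threshold_pct` | 58 | % | insemination suitability cut (strict >) |

The 80 px value is implemented as a hard association gate — the only
reading under which "match the least distant point in the neighborhood"
is coherent. The 52 px/s cut is the floor of 34.5/0.66 = 52.27; flooring
rather than rounding reproduces the operative printed value. The stated
µm-per-pixel derivation from sensor pitch and magnification is not
arithmetically self-consistent, so 0.66 µm/px is taken as the operative
constant and left user-configurable.

## Synthetic scenes

The simulator generates scenes whose geometry and statistics emulate the
clinical videos: 640×480 px at 50 fps, 41 heads per frame by default (the
dataset mean; the observed range is roughly 2–175), and two speed regimes.
Motile heads follow a constant-speed persistent-heading random walk
(per-frame step = speed/fps; heading diffusion sd 0.15 rad/frame); their
speeds are drawn from a truncated normal, 107 ± 25 µm/s on [45, 250] µm/s,
which corresponds to a mean of ≈162 px/s. Non-motile heads take
uncorrelated small steps with speeds 22 ± 5 µm/s on [2, 30] µm/s
(≈33 px/s mean). Sub-pixel positional jitter (sd 0.2 px) is added to every
step. The truncation bounds keep each class's realized path speed strictly
on its side of the 52 px/s cut, so class-based ground-truth vitality and
trajectory-derived vitality coincide — a deliberate design choice: a
"non-motile" head swimming above the viability criterion would contradict
the class definition. The default motile fraction is 0.85, in the range of
experimental viability of analyzable clinical samples.

Boundaries are reflective by default (billiard reflection with heading
flip), which keeps the head count constant and preserves step lengths up to
the small overshoot on the reflection frame; an unbounded mode exists for
closed-form trajectory tests. Heads render as filled rotated ellipses
(semi-axes 3.5 × 2.3 px, ≈ a 4.6 × 3 µm head at 0.66 µm/px) at intensity
200 over a background of 30 with additive Gaussian noise (sd 4), clipped at
the frame border — reproducing the partial-blob appearance of heads touching
the field edge.

The detection-noise model (`perturb_detections`) emulates an imperfect
detector rather than re-running one: each ground-truth box is translated by
N(0, 0.3² px) per axis (sub-pixel localization error of the order a
centroid detector delivers), 2% of detections are dropped (misses and
transient occlusion), and spurious boxes appear at 0.2 per frame with
score 0.9.

What the simulator does **not** model: tails and their beat, photometric
variation between samples, defocus and depth, debris and non-sperm
artifacts, scene cuts, and head-count drift as cells cross the field
boundary. Passing the simulation-based tests therefore demonstrates the
correctness of the gating/tracking/assessment logic under known motion and
noise, not detector robustness on real semen video.

## Numerical and degenerate-input choices

- Coordinates are continuous; sub-pixel centroids are allowed throughout.
  Integer quantization happens only at rendering and VOC-XML export (boxes
  rounded to integers, with a 1 px guard against degenerate boxes).
- Greedy matching sorts candidate pairs once by (distance, track id,
  centroid index); exact ties are therefore deterministic.
- A single-point track has undefined speed and is treated as non-motile
  ("found" but not "live"), not as an error, in batch assessment.
- Empty inputs are valid everywhere downstream of I/O: zero detections give
  a zero report marked not suitable; an empty frame gives no blobs.
- The bootstrap is a seeded percentile bootstrap, 2000 resamples by
  default. Motile/non-motile speed groups are compared with Welch's
  unpaired t-test by default; a paired variant exists for comparability
  with analyses that paired these groups, but pairing unrelated tracks has
  no statistical justification and is flagged as such.
- Detection evaluation uses greedy score-ordered IoU matching at a 0.5
  threshold (community convention; no rule is prescribed by the source
  analysis), and "accuracy" is tp/(tp+fp+fn) because detection has no true
  negatives; precision and recall are always reported alongside.

## Known limitations

- **Identity swaps at crossings.** Nearest-neighbor association without a
  motion model can swap two tracks when heads cross inside the gate. Swaps
  between same-class heads are harmless for vitality; a motile/non-motile
  crossing can splice a fast and a slow trajectory and occasionally shifts
  the viable count by one (≈0.3–0.4 points of vitality MAE on clean
  default-density scenes, measured by `scripts/acceptance.py`). The
  optimal-assignment mode reduces but does not eliminate this.
- Count-mode vitality reproduces most, but not all, rows of the clinical
  comparison table from their Found/Live/Viable counts; the published
  estimate for a few rows follows no recoverable formula, and no attempt is
  made to force agreement.
- Path-length speed is biased upward by localization noise (each jittered
  step adds length). Under the default noise model the bias is small
  relative to the 52 px/s margin between the speed regimes; heavier noise
  would require trajectory smoothing, which is deliberately not applied
  because the reference procedure defines speed on raw centroids.
- The blob detector is a baseline for self-contained runs, not a substitute
  for a trained detector on real video; overlapping heads merge into one
  blob.

## Problem sizes used in the test and acceptance runs

Simulation-based checks use 1 s scenes (50 frames) at the default 41 heads:
20 scenes for the clean-identity and noisy-recovery checks, 1000 random
instances (≤ 5×5) for the matching-oracle comparison, and 500 replications
(n = 100, 1000 resamples) for bootstrap coverage. The full suite and the
acceptance script each complete in well under a minute on one CPU.
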