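# Methods

This document records what the toolkit computes, the assumptions behind each
stage, every tunable parameter with its default and rationale, what the
simulator does and does not emulate, and the numerical choices that make runs
reproducible. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` compute.

## 1. Problem statement and overall model

A transplanter plants seedlings into a line of planting holes; some holes end
up empty ("missed"). A UAV flies a nadir pass along the rows recording video.
The estimation pipeline is:

1. a per-frame detector labels each visible hole *tobacco* (class 0, planted)
   or *missing* (class 1, empty);
2. a multi-object tracker links detections of the same hole across frames;
3. a virtual counting line tallies each confirmed track exactly once as its
   marker crosses the line, giving counts `T1` (planted) and `T2` (missed);
4. the missed-planting rate is `Mv = 100 · T2 / (T1 + T2)` percent.

Counting tracks at a line, rather than summing per-frame detections,
de-duplicates the many sightings of each hole and is robust to isolated
per-frame detector errors: a hole misdetected in a few frames is still carried
by its track and crosses the line once.

The detector itself is out of scope as a trained network; the package provides
(a) the two inference-time backbone operators that distinguish the detector
variant this pipeline assumes, and (b) a seeded simulator that plays the role
of the detector with controllable imperfections, so the downstream pipeline
can be evaluated against exact ground truth.

## 2. Feature blocks (`feature_blocks.py`)

Pure functions on `(C, H, W)` float arrays; parameters are inputs (no
training, no autograd).

**SOCA — second-order channel attention.** For feature map `X`:

- center: `X̂ᵢ = Xᵢ − mean(Xᵢ)` over the spatial grid;
- covariance: `S = (1/HW) · X̂ X̂ᵀ` (C × C, symmetrized to kill roundoff
  asymmetry; `channel_covariance` refuses input that is not mean-centered);
- attention: `Z = σ(W₂ · relu(S) · W₁)` with `W₁ ∈ ℝ^{C×1}`,
  `W₂ ∈ ℝ^{C×C}`, `relu` elementwise on `S`;
- output: `X′ᵢ = Zᵢ · Xᵢ`.

A constant feature map has zero covariance, so every weight is σ(0) = 0.5 and
the block halves its input — a useful analytic fixed point used in the tests.
The contract says `Z` lies strictly in (0, 1); because the float64 sigmoid
rounds to exactly 0 or 1 for |pre-activation| ≳ 37, the implementation clamps
its output to the nearest representable values inside the open interval.

**SimSPPF — simplified spatial pyramid pooling (fast).** ConvBNReLU (1×1
convolution, inference-statistics batch norm, ReLU) → three *iterated*
stride-1 max-pools with kernel `k = 5` and `-inf` padding → channel
concatenation of the input and all three pool outputs (4 · C_hidden channels)
→ a second ConvBNReLU. Iterating a k×k stride-1 max-pool is equivalent to a
single pool with window `2k−1` then `3k−2` (9×9 and 13×13 for k = 5); the
tests verify this against a direct sliding-window oracle. The output conv
must accept exactly 4× the hidden channels; the parameter bundle validates
this at construction.

## 3. Tracking (`kalman.py`, `tracking.py`)

**State model.** Per track, an 8-dimensional constant-velocity state
`(cx, cy, a, h, ẋ, ẏ, ȧ, ḣ)` where `a = w/h` is the box aspect ratio;
the measurement is `(cx, cy, a, h)`. Noise is parameterized relative to the
box height `h` with the standard weights:

| quantity | std |
| --- | --- |
| position / height (process, measurement) | `h/20` |
| velocity (process) | `h/160` |
| aspect ratio: initiate / process / measurement | `1e-2` / `1e-5` / `1e-1` |
| initial position / velocity stds | `2·h/20`, `10·h/160` |

The aspect-ratio components use small absolute stds because aspect is
dimensionless and nearly constant for a planting hole. Updates use Cholesky
factorization (`cho_factor`/`cho_solve`); the Mahalanobis gating distance uses
a triangular solve rather than an explicit inverse.

**Association.** Per frame and *per class* (a planted hole is never matched
to a missing-hole track):

1. *Appearance cascade* over confirmed tracks with usable appearance vectors,
   in tiers of increasing `time_since_update` (fresher tracks match first).
   Cost is the minimum cosine distance `1 − g·f` over the track's gallery
   (budget 100 vectors); a pair is infeasible if its Mahalanobis distance
   exceeds the gate **or** its cosine distance exceeds `max_cosine_distance`.
2. *IoU stage* (cost `1 − IoU`, infeasible above `max_iou_distance`) for the
   remaining detections against tentative tracks and confirmed tracks seen
   last frame (`time_since_update == 1` after predict), plus any track or
   detection lacking an appearance vector — missing appearance degrades
   gracefully to motion-only matching rather than erroring.
3. Assignment by `scipy.optimize.linear_sum_assignment` on the cost matrix
   with infeasible cells set to a large finite constant (1e5) and such pairs
   dropped from the result.

**Lifecycle.** New tracks are *tentative*; they confirm after `n_init = 3`
consecutive hits and are deleted if tentative when first missed, or after
`max_age = 30` frames without an update. Track ids increase monotonically and
are never reused, which the counting ledger relies on.

**Defaults** (`TrackerConfig`): gating threshold 9.4877 (χ² 0.95 quantile at
4 dof — a 95 % gate on the 4-d measurement), `max_cosine_distance = 0.2`,
`max_iou_distance = 0.7`, `n_init = 3`, `max_age = 30`, gallery budget 100.
These are the standard published DeepSORT settings; nothing here was tuned on
simulator outcomes.

## 4. Counting (`counting.py`)

- Marker: the **bottom-edge midpoint** of the track's box — the point where
  the hole meets the ground, which is least sensitive to box-height jitter.
- Side test: sign of the 2-D cross product of (line direction) × (line start →
  marker). Exactly on the line (side 0) the previous stored side is kept, so
  a marker sitting on the line cannot double-count.
- A crossing fires when the stored side and the new side are strictly
  opposite, the track is **confirmed**, and its id has not been counted
  before. Both crossing directions count (a hole is a hole regardless of the
  camera's travel direction).
- `missed_rate(t1, t2)` raises when `t1 + t2 = 0` rather than returning a
  number; the pipeline converts this to a `null` rate plus a diagnostic, and
  the CLI exits with status 2.

The default counting line is horizontal at half the frame height, spanning
the frame width — every object swept by the camera crosses it near the image
center where tracks are most stable.

## 5. Metrics (`metrics.py`)

All percentages are on the 0–100 scale.

- `P = 100·TP/(TP+FP)`, `R = 100·TP/(TP+FN)`; miss rate `Mm =
  100·FN/(FN+TP)`; false rate `Mf = 100·FP/(FP+TN)`. In the two-class
  tracking evaluation, the TN of one class is taken as the TP of the other
  class (the only sensible "true negative" in a detection setting). Empty
  denominators raise `ZeroDivisionError` rather than returning 0.
- Detection matching: detections sorted by descending confidence (ties broken
  by input order, then area), each greedily matched one-to-one to the
  unmatched ground-truth box of the same class with highest IoU ≥ 0.5
  (threshold configurable).
- AP: all-point interpolation by default — sort the PR curve by recall, take
  the monotone non-increasing precision envelope, integrate. The optional
  `11point` mode averages the envelope at recalls 0, 0.1, …, 1.0. The
  two-point curve (0.5, 1.0), (1.0, 0.5) integrates to 0.75, a hand-checkable
  oracle in the tests. `mAP` is the mean over classes, × 100.
- MOTA `= 1 − Σ(FN + FP + IDS) / ΣGT`, with per-frame Hungarian matching of
  hypotheses to ground truth on `1 − IoU` at threshold 0.5 and an identity
  switch counted whenever a ground-truth object's matched hypothesis id
  changes. Tracking hypotheses are confirmed tracks **updated in that frame**
  (coasting predictions are not claims of detection).
- Detection accuracy `Dt = 100 · Mv_model / Mv_truth`, returned with an
  `overestimate` flag (`Mv_model > Mv_truth`), since `Dt` alone cannot
  distinguish over- from under-counting. Undefined when the true rate is 0.

## 6. Scene simulator (`simulate.py`)

**Geometry.** Orthographic nadir camera over a planar field. Rows run
parallel to the direction of travel (the image y-axis). The camera starts
with the field just below the frame (`cam_y = −H`) and advances
`camera_speed_px_per_frame` per frame, so objects enter at the bottom and
sweep upward; image y is `world_y − cam_y`. A hole is emitted in a frame only
when its whole box lies inside the frame (partial boxes at the frame edge are
not half-detections the downstream stages must guess about). The default
frame count is exactly enough for the full field to sweep through:
`ceil((field_length + 2H) / speed) + 1`.

**Field.** `n_rows` rows centered across the frame width, `holes_per_row`
holes per row at fixed spacing; each hole is independently missed with
probability `p_miss` (Bernoulli). The true missed rate of a scene is a
binomial draw around `p_miss`, not `p_miss` itself — tests verify the mean
over many seeds recovers `p_miss` within 3 binomial standard errors.

**Seeding.** `np.random.SeedSequence(seed).spawn(3)` yields independent
streams for field layout, detector noise, and clutter, so changing the
detector model does not perturb the field. Each hole's reference appearance
vector comes from `SeedSequence((scene_seed, hole_id))` — stable per hole,
independent of frame order.

**Detector corruption** (`DetectorModel`): each visible hole is detected with
probability `p_detect`; detected boxes get i.i.d. Gaussian corner jitter
(`jitter_sigma_px`); the class flips with probability `p_confuse`; clutter
detections arrive as a Poisson process (`clutter_rate` per frame) at random
positions with random classes; appearance vectors are the hole's reference
vector plus Gaussian noise and re-normalized. `appearance_noise` is the
**expected norm** of the perturbation (per-component σ =
`appearance_noise / √appearance_dim`), so its scale is comparable to the
unit-norm signal regardless of dimension; a per-component interpretation at
dim 128 would produce noise of norm ≈ 1.13 and destroy all appearance
matching, which is a statement about the parameterization, not the tracker.

**Defaults — the study conditions.** These defaults define the headline
experiment and were fixed before outcomes were inspected:

| parameter | default | rationale |
| --- | --- | --- |
| `n_rows` × `holes_per_row` | 6 × 20 | 120 holes: large enough for stable rates, small enough for second-scale runs |
| `p_miss` | 0.10 | typical missed-planting magnitude for a transplanter |
| `hole_spacing_px` / `row_spacing_px` | 64 / 90 | holes well separated relative to box size |
| `hole_box_size_px` | 32 | small-target regime at 640 px frames |
| `frame_size` | 640 × 640 | standard detector input size |
| `camera_speed_px_per_frame` | 8 | each hole visible for ~75 frames; ample association evidence |
| `p_detect` / `p_confuse` | 0.95 / 0.02 | a good-but-imperfect detector |
| `jitter_sigma_px` | 1.0 | sub-pixel-accurate localization is unrealistic |
| `clutter_rate` | 0.5/frame | occasional false alarms |
| `appearance_noise` / `appearance_dim` | 0.1 / 128 | 10 % perturbation norm on a unit-norm embedding |

**Not emulated:** perspective and lens distortion, camera attitude changes or
vibration, motion blur and rolling shutter, illumination and shadow,
occlusion between plants, plant-size variation over growth stages, terrain
relief, row curvature, and any correlation structure in detector errors
(all corruptions are independent across frames and holes). Consequently the
simulator validates the *tracking-and-counting logic* under controllable
noise; it does not predict field-trial accuracy of any real detector.

## 7. File formats and the pipeline (`io.py`, `pipeline.py`, `cli.py`)

Detections and ground truth use a MOT-style CSV:
`frame,id,bb_left,bb_top,bb_width,bb_height,conf,class,vis` — frames 1-based
in files, 0-based in memory. Track snapshots append `status` and `updated`
columns. Appearance vectors live in a plain-text sidecar (`frame index
v1…vd`). Parse errors name the file and line number.

`run_pipeline` either simulates a scene or reads detection files, tracks,
counts at the line, and (when ground truth exists) evaluates detection and
tracking quality, returning a single `RunReport`. The CLI (`seedtrack`)
exposes each stage (`simulate`, `track`, `count`, `eval-detect`,
`eval-track`) and the whole pipeline (`report`).

## 8. Numerical and reproducibility choices

- All arithmetic in float64; no global RNG state is touched — every random
  draw comes from explicitly seeded `numpy` generators.
- Floats are serialized with `repr()` (shortest round-trip representation),
  JSON keys are sorted, and the wall-clock timing field is excluded from
  persisted reports, so identical seeds yield **byte-identical** artifacts
  (asserted by the tests).
- Infeasible assignment costs use a large finite constant (1e5) instead of
  `inf`, which `linear_sum_assignment` rejects; such pairs are removed from
  the returned assignment.
- `scripts/acceptance.py` derives child seeds via
  `SeedSequence([seed, k])`, reduced mod 2³¹ to stay in the safe integer
  range for downstream consumers.

## 9. Limitations

- The simulator's independence assumptions (Section 6) make it a logic
  validator, not a field-accuracy predictor.
- `Dt` is undefined for fields with zero true misses, and unstable when the
  true rate is very small; the replicate-mean protocol in the acceptance
  script is the intended usage.
- The feature blocks are inference-time operators only; there is no training
  loop, and their effect on a real detector's mAP is outside this package's
  claims.
- Appearance vectors in the simulation are abstract unit vectors; real
  embedding failure modes (e.g. all holes looking alike) are explored only
  through the `appearance_noise` knob.
- The tracker assumes near-constant velocity in image space, which holds for
  a steady nadir pass but not for aggressive UAV maneuvers.
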