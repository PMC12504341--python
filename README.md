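# seedtrack

Simulation and evaluation toolkit for estimating the **missed-planting rate**
of a mechanized seedling transplanter from nadir UAV video.

When a transplanter works a field, some planting holes end up empty. The
standard way to measure this is to walk the rows and count by hand. This
package implements — and lets you stress-test end to end — the video
alternative: a per-frame detector classifies each planting hole as *tobacco*
(planted) or *missing* (empty), a multi-object tracker ties detections of the
same hole together across frames, and a virtual counting line tallies each
hole exactly once as the camera sweeps over it.

Everything is framework-free (`numpy`/`scipy`): the detector-side building
blocks are pure inference-time operators, and the detector itself is replaced
by a seeded, corruptible simulation so every number the toolkit reports can be
checked against known ground truth.

## The model

**Missed-planting rate.** With `T1` holes counted as planted and `T2` counted
as missed,

```
Mv = 100 · T2 / (T1 + T2)        (percent)
```

Detection accuracy compares the model's rate to the reference (manual) rate:
`Dt = 100 · Mv_model / Mv_truth`, with an explicit flag when the model
overestimates.

**Backbone blocks** (`seedtrack.feature_blocks`). Two small-target feature
operators for a YOLOv5s-class backbone, as pure functions on `(C, H, W)`
arrays:

- *SOCA*, second-order channel attention: center each channel
  (`X̂ᵢ = Xᵢ − mean(Xᵢ)`), form the inter-channel covariance
  `S = (1/HW) X̂ X̂ᵀ`, compute weights `Z = σ(W₂ · relu(S) · W₁)` and scale
  each channel by its weight.
- *SimSPPF*: ConvBNReLU → three iterated stride-1 max-pools (kernel 5,
  equivalent to 9×9 and 13×13 windows) → channel concatenation → ConvBNReLU.

**Tracking** (`seedtrack.tracking`, `seedtrack.kalman`). A DeepSORT-style
tracker: an 8-state constant-velocity Kalman filter on `(cx, cy, aspect,
height)`, Mahalanobis-gated appearance matching run as a cascade over track
staleness, an IoU stage for fresh and tentative tracks, Hungarian assignment,
and a tentative → confirmed → deleted lifecycle. Track ids are never reused.

**Counting** (`seedtrack.counting`). A track's marker is the bottom-edge
midpoint of its box. A confirmed track is counted, once, when its marker's
signed side of the counting line strictly changes sign; both crossing
directions count.

**Evaluation** (`seedtrack.metrics`). Precision, recall, all-point-interpolated
AP and mAP for the detector; MOTA, identity switches, and per-class miss/false
rates for the tracker; `Dt` for the end-to-end count.

**Simulation** (`seedtrack.simulate`). A seeded orthographic scene generator:
rows of planting holes, each independently missed with probability `p_miss`,
swept by a constant-velocity camera. A `DetectorModel` corrupts the perfect
detections with missed detections, coordinate jitter, class confusion,
Poisson clutter, and appearance noise. The simulator's defaults *are* the
study conditions; see `docs/methods.md` for every parameter and its rationale.

## Worked example

```python
from seedtrack.pipeline import RunConfig, run_pipeline
from seedtrack.simulate import SceneConfig

scene = SceneConfig(n_rows=4, holes_per_row=12, p_miss=0.15, seed=42)
report = run_pipeline(RunConfig(scene=scene))
print(report.t1, report.t2, report.missed_rate_percent)
```

With the default (noisy) detector model this run prints, deterministically:

```
planted counted (T1): 39
missed counted  (T2): 9
missed rate Mv:       18.75%
true missed rate:     18.75%
detection accuracy:   100.00%
mAP:                  88.36%
MOTA:                 0.897
ID switches:          2
```

The per-frame detector is imperfect (mAP 88.36 %, two identity switches), yet
the line-crossing count still recovers the true missed rate exactly — which is
the point of counting tracks at a line instead of counting detections.

The same run from the command line:

```bash
cat > scene.yaml <<'EOF'
n_rows: 4
holes_per_row: 12
p_miss: 0.15
seed: 42
EOF
seedtrack report --config scene.yaml --out run1
```

This writes `det.csv`, `gt.csv`, `features.txt`, `tracks.csv`, `truth.json`
and `report.json` into `run1/` and prints the report (same numbers as above:
`t1 = 39`, `t2 = 9`, `Mv = 18.75 %`). The other subcommands — `simulate`,
`track`, `count`, `eval-detect`, `eval-track` — expose each pipeline stage
separately on the same CSV formats; run `seedtrack --help`.

## Layout

| Module | Contents |
| --- | --- |
| `seedtrack.feature_blocks` | SOCA attention, SimSPPF pooling block |
| `seedtrack.boxes` | bounding boxes, IoU |
| `seedtrack.kalman` | constant-velocity Kalman filter |
| `seedtrack.tracking` | detections, tracks, association cascade, tracker |
| `seedtrack.counting` | counting line, crossing ledger, missed rate |
| `seedtrack.metrics` | P/R/AP/mAP, MOTA, miss/false rates, Dt |
| `seedtrack.simulate` | scene generator and detector corruption model |
| `seedtrack.io` | MOT-style CSV, appearance sidecar, YOLO annotations |
| `seedtrack.pipeline` | orchestration, reports, track snapshot I/O |
| `seedtrack.cli` | `seedtrack` command-line interface |

Methodological details, parameter defaults, and known limitations are in
[`docs/methods.md`](docs/methods.md).
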