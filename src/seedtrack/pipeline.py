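"""End-to-end orchestration: simulate/read -> track -> count -> evaluate.

The evaluation protocol mirrors a field trial of a seedling transplanter:
the tracker and line-crossing counter produce the model's seedling-planted
and missed-planting hole counts, the scene truth (or a manual count)
supplies the reference, and the report compares the two missed
transplanting rates through the detection accuracy Dt = R_model / R_truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .boxes import BoundingBox
from .counting import (
    MISSED,
    PLANTED,
    CountingLine,
    CountLedger,
    UndefinedRateError,
    ledger_step,
    marker_point,
    missed_rate,
)
from .metrics import (
    ConfusionCounts,
    average_precision,
    detection_accuracy,
    match_detections,
    mean_ap,
    miss_rate,
    false_rate,
    mota,
    pr_curve,
    precision,
    recall,
    tracking_events_from_gt,
)
from .simulate import SceneConfig, simulate_scene, write_scene
from .tracking import Detection, Track, Tracker, TrackerConfig, TrackStatus

logger = logging.getLogger("seedtrack")

__all__ = [
    "RunConfig",
    "RunReport",
    "TrackSnapshot",
    "track_stream",
    "count_crossings",
    "evaluate_static",
    "evaluate_tracking",
    "run_pipeline",
    "write_track_snapshots",
    "read_track_snapshots",
    "report_json",
]

_CLASS_NAMES = {PLANTED: "tobacco", MISSED: "missing"}


@dataclass(frozen=True)
class TrackSnapshot:
    """State of one track at the end of one frame."""

    frame: int
    track_id: int
    class_id: int
    box: BoundingBox
    status: str
    updated: bool  # matched to a detection this frame


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``scene`` (simulate in-process) or ``det_path`` (read a MOT
    detection CSV, optionally with an appearance sidecar) must be given.
    """

    scene: SceneConfig | None = None
    det_path: str | Path | None = None
    features_path: str | Path | None = None
    gt_path: str | Path | None = None
    truth_rate: float | None = None
    line: CountingLine | None = None
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    frame_size: tuple[int, int] = (640, 640)
    iou_threshold: float = 0.5
    ap_mode: str = "allpoint"
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scene is None and self.det_path is None:
            raise ValueError("RunConfig needs a scene config or a detection file")


@dataclass
class RunReport:
    """Computed results of one run; ``None`` means inputs were absent."""

    t1: int = 0
    t2: int = 0
    missed_rate_percent: float | None = None
    true_missed_rate_percent: float | None = None
    detection_accuracy_percent: float | None = None
    overestimate: bool | None = None
    detection_eval: dict | None = None
    tracking_eval: dict | None = None
    counted_ids: list[int] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)
    version: str = ""
    timing_seconds: float | None = None
    diagnostic: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def track_stream(
    det_frames: dict[int, list[Detection]],
    config: TrackerConfig | None = None,
    n_frames: int | None = None,
) -> dict[int, list[TrackSnapshot]]:
    """Run the tracker over a frame-indexed detection stream.

    Frames with no detections are still stepped so lifecycle ageing and
    deletion behave as they would on real video.
    """
    tracker = Tracker(config)
    last = max(det_frames) if det_frames else -1
    if n_frames is not None:
        last = max(last, n_frames - 1)
    out: dict[int, list[TrackSnapshot]] = {}
    for frame in range(last + 1):
        live = tracker.step(det_frames.get(frame, []))
        out[frame] = [
            TrackSnapshot(
                frame, t.track_id, t.class_id, t.to_box(), t.status.value,
                t.time_since_update == 0,
            )
            for t in live
        ]
    return out


def count_crossings(
    track_frames: dict[int, list[TrackSnapshot]], line: CountingLine
) -> CountLedger:
    """Apply the once-per-identity line-crossing rule over tracker output."""
    ledger = CountLedger()
    for frame in sorted(track_frames):
        for snap in track_frames[frame]:
            ledger_step(
                ledger,
                snap.track_id,
                snap.class_id,
                marker_point(snap.box),
                line,
                confirmed=snap.status == TrackStatus.CONFIRMED.value,
            )
    return ledger


def evaluate_static(
    det_frames: dict[int, list[Detection]],
    gt_frames: dict[int, list[tuple[int, BoundingBox]]],
    iou_threshold: float = 0.5,
    ap_mode: str = "allpoint",
) -> dict:
    """Per-class detection metrics pooled over frames, Table-style.

    ``gt_frames`` maps frame -> list of (class_id, box). Returns per-class
    ground-truth/detected/TP/FP/FN counts, precision, recall and AP, plus
    the class-mean AP (mAP) in percent.
    """
    per_class: dict[int, dict] = {}
    aps = []
    for cls in (PLANTED, MISSED):
        counts = ConfusionCounts()
        scored: list[tuple[float, bool]] = []
        n_gt = 0
        for frame in sorted(set(det_frames) | set(gt_frames)):
            dets = [d for d in det_frames.get(frame, []) if d.class_id == cls]
            gts = [b for c, b in gt_frames.get(frame, []) if c == cls]
            n_gt += len(gts)
            c, is_tp = match_detections(
                [(d.box, d.confidence) for d in dets], gts, iou_threshold
            )
            counts = counts + c
            scored.extend((d.confidence, tp) for d, tp in zip(dets, is_tp))
        ap = average_precision(pr_curve(scored, n_gt), ap_mode) if n_gt else 0.0
        aps.append(ap)
        per_class[cls] = {
            "class_name": _CLASS_NAMES[cls],
            "ground_truth": n_gt,
            "detected": counts.tp + counts.fp,
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
            "precision_percent": precision(counts) if counts.tp + counts.fp else None,
            "recall_percent": recall(counts) if counts.tp + counts.fn else None,
            "ap_fraction": ap,
        }
    return {
        "per_class": {_CLASS_NAMES[c]: v for c, v in per_class.items()},
        "map_percent": mean_ap(aps),
    }


def evaluate_tracking(
    track_frames: dict[int, list[TrackSnapshot]],
    gt_frames: dict[int, list[tuple[int, BoundingBox, int]]],
    iou_threshold: float = 0.5,
) -> dict:
    """MOTA plus per-class and pooled miss/false rates from tracker output.

    Hypotheses are confirmed tracks that matched a detection in the frame.
    ``gt_frames`` maps frame -> list of (object id, box, class_id).
    """
    hyps = {
        f: [
            (s.track_id, s.box)
            for s in snaps
            if s.status == TrackStatus.CONFIRMED.value and s.updated
        ]
        for f, snaps in track_frames.items()
    }
    gts = {f: [(i, b) for i, b, _ in recs] for f, recs in gt_frames.items()}
    events = tracking_events_from_gt(hyps, gts, iou_threshold)

    # per-class confusion across frames; TN of one class = TP of the other
    class_counts = {}
    for cls in (PLANTED, MISSED):
        counts = ConfusionCounts()
        for f in sorted(set(track_frames) | set(gt_frames)):
            h_boxes = [
                (s.box, 1.0)
                for s in track_frames.get(f, [])
                if s.class_id == cls and s.status == TrackStatus.CONFIRMED.value and s.updated
            ]
            g_boxes = [b for _, b, c in gt_frames.get(f, []) if c == cls]
            c, _ = match_detections(h_boxes, g_boxes, iou_threshold)
            counts = counts + c
        class_counts[cls] = counts
    class_counts[PLANTED].tn = class_counts[MISSED].tp
    class_counts[MISSED].tn = class_counts[PLANTED].tp
    pooled = ConfusionCounts(
        tp=sum(c.tp for c in class_counts.values()),
        fp=sum(c.fp for c in class_counts.values()),
        fn=sum(c.fn for c in class_counts.values()),
        tn=sum(c.tp for c in class_counts.values()),
    )

    def _rates(c: ConfusionCounts) -> dict:
        return {
            "miss_rate_percent": miss_rate(c) if c.fn + c.tp else None,
            "false_rate_percent": false_rate(c) if c.fp + c.tn else None,
            "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
        }

    return {
        "mota": mota(events) if sum(events.gt_counts) else None,
        "id_switches": sum(events.id_switches),
        "misses": sum(events.misses),
        "false_positives": sum(events.false_positives),
        "gt_total": sum(events.gt_counts),
        "per_class": {_CLASS_NAMES[c]: _rates(cc) for c, cc in class_counts.items()},
        "pooled": _rates(pooled),
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Simulate or load detections, track, count, evaluate, report."""
    import time

    from . import __version__, io as stio

    t_start = time.perf_counter()
    report = RunReport(version=__version__)
    frame_size = config.frame_size
    gt_frames_eval: dict[int, list[tuple[int, BoundingBox, int]]] | None = None
    truth_rate = config.truth_rate
    n_frames = None

    if config.scene is not None:
        truth, gt_raw, det_frames = simulate_scene(config.scene)
        frame_size = config.scene.frame_size
        n_frames = config.scene.resolved_n_frames()
        gt_frames_eval = {
            f: [(h.hole_id, b, h.class_id) for h, b in recs] for f, recs in gt_raw.items()
        }
        truth_rate = truth.true_missed_rate if truth_rate is None else truth_rate
        if config.out_dir is not None:
            write_scene(truth, gt_raw, det_frames, config.scene, config.out_dir)
    else:
        det_frames = stio.read_mot_detections(config.det_path, config.features_path)
        if config.gt_path is not None:
            gt_frames_eval = stio.read_mot_ground_truth(config.gt_path)

    line = config.line or CountingLine.horizontal(frame_size[1] / 2.0, float(frame_size[0]))
    logger.info("tracking %d frames", len(det_frames))
    track_frames = track_stream(det_frames, config.tracker, n_frames)
    ledger = count_crossings(track_frames, line)
    report.t1, report.t2 = ledger.t1_count, ledger.t2_count
    report.counted_ids = sorted(ledger.counted_ids)
    try:
        report.missed_rate_percent = missed_rate(ledger)
    except UndefinedRateError as exc:
        report.diagnostic = str(exc)

    if gt_frames_eval is not None:
        gt_static = {
            f: [(cls, b) for _, b, cls in recs] for f, recs in gt_frames_eval.items()
        }
        report.detection_eval = evaluate_static(
            det_frames, gt_static, config.iou_threshold, config.ap_mode
        )
        report.tracking_eval = evaluate_tracking(
            track_frames, gt_frames_eval, config.iou_threshold
        )
    if truth_rate is not None:
        report.true_missed_rate_percent = truth_rate
        if report.missed_rate_percent is not None and truth_rate > 0:
            dt, over = detection_accuracy(report.missed_rate_percent, truth_rate)
            report.detection_accuracy_percent = dt
            report.overestimate = over

    report.config_echo = _config_echo(config)
    report.timing_seconds = time.perf_counter() - t_start
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_track_snapshots(out / "tracks.csv", track_frames)
        # timing is excluded from the persisted report so identical runs
        # produce byte-identical files
        (out / "report.json").write_text(report_json(report, include_timing=False) + "\n")
    return report


def report_json(report: RunReport, include_timing: bool = True) -> str:
    d = report.to_dict()
    if not include_timing:
        d.pop("timing_seconds", None)
    return json.dumps(d, indent=2, sort_keys=True)


def write_track_snapshots(
    path: str | Path, track_frames: dict[int, list[TrackSnapshot]]
) -> None:
    """Tracker output in the MOT dialect plus status and updated columns."""
    lines = []
    for frame in sorted(track_frames):
        for s in track_frames[frame]:
            left, top, w, h = s.box.as_ltwh()
            lines.append(
                f"{frame + 1},{s.track_id},{left!r},{top!r},{w!r},{h!r},1.0,"
                f"{s.class_id},1,{s.status},{int(s.updated)}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_track_snapshots(path: str | Path) -> dict[int, list[TrackSnapshot]]:
    """Inverse of :func:`write_track_snapshots` (frames back to 0-based)."""
    frames: dict[int, list[TrackSnapshot]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.strip().split(",")
            if not line.strip():
                continue
            if len(parts) != 11:
                raise ValueError(f"{path}:{lineno}: expected 11 fields, got {len(parts)}")
            frame = int(parts[0]) - 1
            left, top, w, h = (float(p) for p in parts[2:6])
            frames.setdefault(frame, []).append(
                TrackSnapshot(
                    frame,
                    int(parts[1]),
                    int(parts[7]),
                    BoundingBox(left, top, left + w, top + h),
                    parts[9],
                    bool(int(parts[10])),
                )
            )
    return dict(sorted(frames.items()))


def _config_echo(config: RunConfig) -> dict:
    echo = {
        "tracker": dataclasses.asdict(config.tracker),
        "iou_threshold": config.iou_threshold,
        "ap_mode": config.ap_mode,
        "seed": config.seed,
    }
    if config.scene is not None:
        echo["scene"] = config.scene.to_dict()
    if config.line is not None:
        echo["line"] = [list(config.line.p0), list(config.line.p1)]
    for name in ("det_path", "features_path", "gt_path"):
        v = getattr(config, name)
        if v is not None:
            echo[name] = str(v)
    return echo
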