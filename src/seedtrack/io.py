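"""Readers and writers for the plain-text interchange formats.

* MOT-style CSV, one line per box:
  ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,class,vis``.
  Frames are 1-based in files and 0-based in memory; these functions are
  the only crossing point between the two conventions. Detections carry
  ``id = -1``; ground truth and tracker output carry real identities, and
  tracker output appends a ``status`` column.
* Appearance sidecar: one line per detection,
  ``frame index v1 v2 ... vd`` (whitespace-separated, frame 1-based,
  index = position of the detection within its frame in the CSV).
* YOLO-txt annotations: ``class cx cy w h [conf]`` with coordinates
  normalized to the frame size.

All writers emit full-precision floats (``repr``) so a write/read cycle is
bit-exact and identical inputs give byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .boxes import BoundingBox
from .simulate import Hole
from .tracking import Detection

__all__ = [
    "read_mot_detections",
    "write_mot_detections",
    "write_mot_ground_truth",
    "read_mot_ground_truth",
    "write_appearance_sidecar",
    "read_appearance_sidecar",
    "read_yolo_annotations",
]


class ParseError(ValueError):
    pass


def _parse_line(line: str, lineno: int, path) -> tuple[int, int, BoundingBox, float, int, float]:
    parts = line.strip().split(",")
    if len(parts) < 9:
        raise ParseError(f"{path}:{lineno}: expected 9 comma-separated fields, got {len(parts)}")
    try:
        frame = int(parts[0])
        obj_id = int(parts[1])
        left, top, w, h = (float(p) for p in parts[2:6])
        conf = float(parts[6])
        cls = int(parts[7])
        vis = float(parts[8])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if frame < 1:
        raise ParseError(f"{path}:{lineno}: frame must be >= 1, got {frame}")
    if w <= 0 or h <= 0:
        raise ParseError(f"{path}:{lineno}: non-positive box size {w}x{h}")
    return frame, obj_id, BoundingBox(left, top, left + w, top + h), conf, cls, vis


def read_mot_detections(
    path: str | Path, features_path: str | Path | None = None
) -> dict[int, list[Detection]]:
    """Detection stream from a MOT CSV, optionally with appearance vectors.

    Returns 0-based frame index -> detections, frames sorted ascending.
    """
    features = read_appearance_sidecar(features_path) if features_path else {}
    frames: dict[int, list[Detection]] = {}
    per_frame_index: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            frame1, _, box, conf, cls, _ = _parse_line(line, lineno, path)
            idx = per_frame_index.get(frame1, 0)
            per_frame_index[frame1] = idx + 1
            vec = features.get((frame1, idx))
            frames.setdefault(frame1 - 1, []).append(
                Detection(frame1 - 1, box, min(max(conf, 0.0), 1.0), cls, vec)
            )
    return dict(sorted(frames.items()))


def write_mot_detections(path: str | Path, det_frames: dict[int, list[Detection]]) -> None:
    lines = []
    for frame in sorted(det_frames):
        for d in det_frames[frame]:
            left, top, w, h = d.box.as_ltwh()
            lines.append(
                f"{frame + 1},-1,{left!r},{top!r},{w!r},{h!r},{d.confidence!r},{d.class_id},1"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_mot_ground_truth(
    path: str | Path, gt_frames: dict[int, list[tuple[Hole, BoundingBox]]]
) -> None:
    lines = []
    for frame in sorted(gt_frames):
        for hole, box in gt_frames[frame]:
            left, top, w, h = box.as_ltwh()
            lines.append(
                f"{frame + 1},{hole.hole_id},{left!r},{top!r},{w!r},{h!r},1.0,{hole.class_id},1"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_mot_ground_truth(
    path: str | Path,
) -> dict[int, list[tuple[int, BoundingBox, int]]]:
    """Ground truth as 0-based frame -> list of (object id, box, class)."""
    frames: dict[int, list[tuple[int, BoundingBox, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            frame1, obj_id, box, _, cls, _ = _parse_line(line, lineno, path)
            frames.setdefault(frame1 - 1, []).append((obj_id, box, cls))
    return dict(sorted(frames.items()))


def write_appearance_sidecar(path: str | Path, det_frames: dict[int, list[Detection]]) -> None:
    lines = []
    for frame in sorted(det_frames):
        for idx, d in enumerate(det_frames[frame]):
            if d.appearance is None:
                continue
            vec = " ".join(repr(float(v)) for v in d.appearance)
            lines.append(f"{frame + 1} {idx} {vec}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_appearance_sidecar(path: str | Path) -> dict[tuple[int, int], np.ndarray]:
    """(1-based frame, within-frame index) -> unit appearance vector."""
    out: dict[tuple[int, int], np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 'frame index v1 ...'")
            out[(int(parts[0]), int(parts[1]))] = np.array([float(v) for v in parts[2:]])
    return out


def read_yolo_annotations(
    path: str | Path, frame_size: tuple[int, int]
) -> list[tuple[int, BoundingBox, float]]:
    """YOLO-txt boxes for one image: (class, box, confidence).

    Lines are ``class cx cy w h`` with optional trailing confidence
    (defaults to 1.0); coordinates are fractions of the frame size.
    """
    fw, fh = frame_size
    out: list[tuple[int, BoundingBox, float]] = []
    with open(path) as fh_:
        for lineno, line in enumerate(fh_, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (5, 6):
                raise ParseError(f"{path}:{lineno}: expected 5 or 6 fields")
            try:
                cls = int(parts[0])
                cx, cy, w, h = (float(p) for p in parts[1:5])
                conf = float(parts[5]) if len(parts) == 6 else 1.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if cls not in (0, 1):
                raise ParseError(f"{path}:{lineno}: class id {cls} outside {{0, 1}}")
            box = BoundingBox(
                (cx - w / 2) * fw, (cy - h / 2) * fh, (cx + w / 2) * fw, (cy + h / 2) * fh
            )
            out.append((cls, box, conf))
    return out
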