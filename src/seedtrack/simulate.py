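"""Synthetic overhead row-crop scenes with a corruptible detector.

Emulates nadir UAV footage of mulched ridges: parallel planting rows run
along the camera's travel direction, each row a regular sequence of
planting holes that are independently either seedling-planted or
missed-planting. An orthographic camera of fixed frame size advances at
constant velocity along the rows; a hole is visible in a frame only when
its whole box lies inside the frame, mirroring the cropping of distorted
image edges in real footage.

On top of the exact ground truth sits a parameterized detector-noise
model: per-frame Bernoulli dropouts, Gaussian box-centre jitter, class
confusion, Poisson clutter, and noisy unit-norm appearance vectors tied to
the underlying hole identity. Everything is deterministic given (config,
seed): the master seed is split into independent streams for the field
layout, the detector, and the clutter, so toggling one noise source never
perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boxes import BoundingBox
from .counting import MISSED, PLANTED
from .tracking import Detection

__all__ = [
    "DetectorModel",
    "SceneConfig",
    "Hole",
    "SceneTruth",
    "generate_field",
    "project_frame",
    "corrupt_detections",
    "simulate_scene",
    "write_scene",
]


@dataclass(frozen=True)
class DetectorModel:
    """Noise model standing between the true scene and the detection stream."""

    p_detect: float = 0.95  # per-object per-frame detection probability
    p_confuse: float = 0.02  # class-flip probability
    jitter_sigma_px: float = 1.0  # Gaussian box-centre noise, pixels
    clutter_rate: float = 0.5  # expected false positives per frame (Poisson)
    appearance_noise: float = 0.1
    appearance_dim: int = 128

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_detect <= 1.0 and 0.0 <= self.p_confuse <= 1.0):
            raise ValueError("probabilities must be in [0, 1]")
        if min(self.jitter_sigma_px, self.clutter_rate, self.appearance_noise) < 0:
            raise ValueError("noise rates must be non-negative")

    @classmethod
    def perfect(cls, appearance_dim: int = 16) -> "DetectorModel":
        return cls(1.0, 0.0, 0.0, 0.0, 0.0, appearance_dim)


@dataclass(frozen=True)
class SceneConfig:
    """Field layout, camera, and detector configuration.

    Rows are parallel to the travel (image-y) axis and spaced across
    image x; each row holds ``holes_per_row`` holes at ``hole_spacing_px``.
    Defaults emulate a 6-row swath of well-cellar planting holes at the
    scale they appear from 10-15 m altitude.
    """

    n_rows: int = 6
    holes_per_row: int = 20
    hole_spacing_px: float = 64.0
    row_spacing_px: float = 90.0
    hole_box_size_px: float = 32.0
    p_miss: float = 0.1
    frame_size: tuple[int, int] = (640, 640)  # (width, height)
    camera_speed_px_per_frame: float = 8.0
    n_frames: int | None = None  # None: enough for one full pass
    detector: DetectorModel = field(default_factory=DetectorModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.holes_per_row < 1:
            raise ValueError("the field must contain at least one hole")
        if min(self.hole_spacing_px, self.row_spacing_px, self.hole_box_size_px) <= 0:
            raise ValueError("spacings and sizes must be positive")
        if not 0.0 <= self.p_miss <= 1.0:
            raise ValueError("p_miss must be in [0, 1]")
        if self.camera_speed_px_per_frame < 0:
            raise ValueError("camera speed must be >= 0")

    @property
    def field_length_px(self) -> float:
        return (self.holes_per_row - 1) * self.hole_spacing_px

    def resolved_n_frames(self) -> int:
        if self.n_frames is not None:
            return self.n_frames
        if self.camera_speed_px_per_frame == 0:
            return 1
        travel = self.field_length_px + 2 * self.frame_size[1]
        return int(np.ceil(travel / self.camera_speed_px_per_frame)) + 1

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "detector" in d and isinstance(d["detector"], dict):
            d["detector"] = DetectorModel(**d["detector"])
        if "frame_size" in d:
            d["frame_size"] = tuple(d["frame_size"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_size"] = list(self.frame_size)
        return d


@dataclass(frozen=True)
class Hole:
    """One planting hole: world position, true class, stable identity."""

    hole_id: int
    world_x: float
    world_y: float
    class_id: int  # PLANTED or MISSED


@dataclass
class SceneTruth:
    """Ground truth of a simulated scene."""

    holes: list[Hole]
    n_planted: int
    n_missed: int

    @property
    def true_missed_rate(self) -> float:
        return 100.0 * self.n_missed / (self.n_planted + self.n_missed)


def _rng_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    """Independent (field, detector, clutter) generators from one seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3)
    return tuple(np.random.default_rng(c) for c in children)  # type: ignore[return-value]


def generate_field(config: SceneConfig) -> SceneTruth:
    """Lay holes on the row grid and draw each one's true class."""
    rng, _, _ = _rng_streams(config.seed)
    width = config.frame_size[0]
    x0 = (width - (config.n_rows - 1) * config.row_spacing_px) / 2.0
    holes: list[Hole] = []
    hole_id = 1
    for r in range(config.n_rows):
        for j in range(config.holes_per_row):
            cls = MISSED if rng.random() < config.p_miss else PLANTED
            holes.append(
                Hole(hole_id, x0 + r * config.row_spacing_px, j * config.hole_spacing_px, cls)
            )
            hole_id += 1
    n_missed = sum(1 for h in holes if h.class_id == MISSED)
    return SceneTruth(holes, len(holes) - n_missed, n_missed)


def project_frame(
    truth: SceneTruth, frame_index: int, config: SceneConfig
) -> list[tuple[Hole, BoundingBox]]:
    """Visible (hole, box) pairs for one frame of the camera pass.

    The camera starts one frame-height before the field so every hole
    enters at the bottom edge and exits at the top. Image y = world y
    minus the camera offset; a hole is visible only when its whole box
    fits inside the frame.
    """
    w, h = config.frame_size
    cam_y = -float(h) + config.camera_speed_px_per_frame * frame_index
    half = config.hole_box_size_px / 2.0
    out: list[tuple[Hole, BoundingBox]] = []
    for hole in truth.holes:
        iy = hole.world_y - cam_y
        ix = hole.world_x
        box = BoundingBox(ix - half, iy - half, ix + half, iy + half)
        if box.x_min >= 0 and box.y_min >= 0 and box.x_max <= w and box.y_max <= h:
            out.append((hole, box))
    return out


def _hole_appearance(hole_id: int, dim: int, scene_seed: int) -> np.ndarray:
    """Deterministic unit appearance vector for one physical hole."""
    rng = np.random.default_rng(np.random.SeedSequence((scene_seed, hole_id)))
    v = rng.normal(size=dim)
    return v / np.linalg.norm(v)


def corrupt_detections(
    gt: list[tuple[Hole, BoundingBox]],
    detector: DetectorModel,
    frame_index: int,
    config: SceneConfig,
    det_rng: np.random.Generator,
    clutter_rng: np.random.Generator,
) -> list[Detection]:
    """Push one frame's ground truth through the detector-noise model."""
    w, h = config.frame_size
    half = config.hole_box_size_px / 2.0
    dets: list[Detection] = []
    for hole, box in gt:
        if det_rng.random() > detector.p_detect:
            continue
        dx, dy = (
            det_rng.normal(scale=detector.jitter_sigma_px, size=2)
            if detector.jitter_sigma_px > 0
            else (0.0, 0.0)
        )
        cls = hole.class_id
        if detector.p_confuse > 0 and det_rng.random() < detector.p_confuse:
            cls = MISSED if cls == PLANTED else PLANTED
        vec = _hole_appearance(hole.hole_id, detector.appearance_dim, config.seed)
        if detector.appearance_noise > 0:
            # appearance_noise is the expected *norm* of the perturbation
            # relative to the unit signal, independent of the embedding dim
            scale = detector.appearance_noise / np.sqrt(detector.appearance_dim)
            vec = vec + det_rng.normal(scale=scale, size=vec.shape)
            vec = vec / np.linalg.norm(vec)
        conf = float(np.clip(det_rng.uniform(0.6, 1.0), 0.0, 1.0))
        dets.append(
            Detection(frame_index, box.translated(float(dx), float(dy)), conf, cls, vec)
        )
    n_clutter = clutter_rng.poisson(detector.clutter_rate) if detector.clutter_rate > 0 else 0
    for _ in range(n_clutter):
        cx = clutter_rng.uniform(half, w - half)
        cy = clutter_rng.uniform(half, h - half)
        cls = int(clutter_rng.integers(0, 2))
        vec = clutter_rng.normal(size=detector.appearance_dim)
        vec = vec / np.linalg.norm(vec)
        conf = float(np.clip(clutter_rng.uniform(0.3, 0.7), 0.0, 1.0))
        dets.append(
            Detection(
                frame_index,
                BoundingBox(cx - half, cy - half, cx + half, cy + half),
                conf, cls, vec,
            )
        )
    return dets


def simulate_scene(
    config: SceneConfig,
) -> tuple[SceneTruth, dict[int, list[tuple[Hole, BoundingBox]]], dict[int, list[Detection]]]:
    """Full scene: truth, per-frame ground-truth boxes, corrupted detections."""
    truth = generate_field(config)
    _, det_rng, clutter_rng = _rng_streams(config.seed)
    gt_frames: dict[int, list[tuple[Hole, BoundingBox]]] = {}
    det_frames: dict[int, list[Detection]] = {}
    for t in range(config.resolved_n_frames()):
        gt = project_frame(truth, t, config)
        gt_frames[t] = gt
        det_frames[t] = corrupt_detections(
            gt, config.detector, t, config, det_rng, clutter_rng
        )
    return truth, gt_frames, det_frames


def write_scene(
    truth: SceneTruth,
    gt_frames: dict[int, list[tuple[Hole, BoundingBox]]],
    det_frames: dict[int, list[Detection]],
    config: SceneConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write det.csv / gt.csv (MOT dialect), features.txt, truth.json, config.json.

    Frames are 1-based in the files (MOT convention); detections carry
    id -1. The emitted files round-trip bit-exactly through the readers in
    :mod:`seedtrack.io`.
    """
    from . import io as stio  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "det": out / "det.csv",
        "gt": out / "gt.csv",
        "features": out / "features.txt",
        "truth": out / "truth.json",
        "config": out / "config.json",
    }
    stio.write_mot_detections(paths["det"], det_frames)
    stio.write_mot_ground_truth(paths["gt"], gt_frames)
    stio.write_appearance_sidecar(paths["features"], det_frames)
    total = truth.n_planted + truth.n_missed
    paths["truth"].write_text(
        json.dumps(
            {
                "n_planted": truth.n_planted,
                "n_missed": truth.n_missed,
                "n_holes": total,
                "true_missed_rate_percent": truth.true_missed_rate,
            },
            indent=2, sort_keys=True,
        )
        + "\n"
    )
    paths["config"].write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
    return paths
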