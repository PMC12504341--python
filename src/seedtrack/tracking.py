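"""DeepSORT-style multi-object tracker for per-frame detection streams.

Tracking-by-detection with the classic ingredients: a constant-velocity
Kalman filter per track, Mahalanobis gating, appearance-cosine cascade
matching for confirmed tracks (fresher tracks get priority), IoU matching
for the leftovers and for newborn tracks, Hungarian assignment, and a
tentative/confirmed/deleted lifecycle.

Appearance (re-identification) vectors are *inputs* — read from a sidecar
file or produced by the scene simulator — never computed here. When they
are absent, association degrades gracefully to motion + IoU matching.

Association is strictly per class: a track only ever matches detections of
its own class, because downstream counting pre-classifies targets by track
identity and a class flip mid-track would corrupt the count ledger.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .boxes import BoundingBox, box_to_measurement, iou, measurement_to_box
from .kalman import KalmanFilter

__all__ = [
    "Detection",
    "Track",
    "TrackStatus",
    "TrackerConfig",
    "Tracker",
    "hungarian_assign",
    "appearance_cost",
    "matching_cascade",
    "iou_match",
]

_APPEARANCE_NORM_TOL = 1e-6
_INFEASIBLE = 1e5


@dataclass(frozen=True)
class Detection:
    """One frame-stamped detector output."""

    frame: int
    box: BoundingBox
    confidence: float
    class_id: int
    appearance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame index must be non-negative")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        if self.appearance is not None:
            vec = np.asarray(self.appearance, dtype=float)
            norm = np.linalg.norm(vec)
            if abs(norm - 1.0) > _APPEARANCE_NORM_TOL:
                raise ValueError(f"appearance vector must be unit-norm, |v|={norm}")
            object.__setattr__(self, "appearance", vec)


class TrackStatus(enum.Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


@dataclass
class TrackerConfig:
    """Association thresholds and lifecycle parameters.

    Defaults are the standard published DeepSORT configuration: the gating
    threshold is the chi-square 0.95 quantile at 4 degrees of freedom.
    """

    gating_threshold: float = 9.4877
    max_cosine_distance: float = 0.2
    max_iou_distance: float = 0.7
    n_init: int = 3
    max_age: int = 30
    gallery_budget: int = 100
    std_weight_position: float = 1.0 / 20
    std_weight_velocity: float = 1.0 / 160

    def __post_init__(self) -> None:
        for name in ("gating_threshold", "max_cosine_distance", "max_iou_distance",
                     "max_age", "gallery_budget"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


class Track:
    """One tracked object: Kalman state, identity, lifecycle, gallery."""

    def __init__(
        self,
        mean: np.ndarray,
        covariance: np.ndarray,
        track_id: int,
        class_id: int,
        n_init: int,
        gallery_budget: int,
        appearance: np.ndarray | None = None,
    ) -> None:
        self.mean = mean
        self.covariance = covariance
        self.track_id = track_id
        self.class_id = class_id
        self.hits = 1
        self.time_since_update = 0
        self._n_init = n_init
        self.status = TrackStatus.CONFIRMED if self.hits >= n_init else TrackStatus.TENTATIVE
        self.gallery: deque[np.ndarray] = deque(maxlen=gallery_budget)
        if appearance is not None:
            self.gallery.append(appearance)

    @property
    def is_confirmed(self) -> bool:
        return self.status is TrackStatus.CONFIRMED

    @property
    def is_deleted(self) -> bool:
        return self.status is TrackStatus.DELETED

    def to_box(self) -> BoundingBox:
        return measurement_to_box(self.mean[:4])

    def predict(self, kf: KalmanFilter) -> None:
        self.mean, self.covariance = kf.predict(self.mean, self.covariance)
        self.time_since_update += 1

    def update(self, kf: KalmanFilter, det: Detection) -> None:
        self.mean, self.covariance = kf.update(
            self.mean, self.covariance, box_to_measurement(det.box)
        )
        self.hits += 1
        self.time_since_update = 0
        if det.appearance is not None:
            self.gallery.append(det.appearance)
        if self.status is TrackStatus.TENTATIVE and self.hits >= self._n_init:
            self.status = TrackStatus.CONFIRMED

    def mark_missed(self, max_age: int) -> None:
        if self.status is TrackStatus.TENTATIVE:
            self.status = TrackStatus.DELETED
        elif self.time_since_update > max_age:
            self.status = TrackStatus.DELETED


def hungarian_assign(
    cost: np.ndarray, infeasible: np.ndarray | None = None
) -> list[tuple[int, int]]:
    """Minimum-cost one-to-one assignment, skipping infeasible cells.

    Returns (row, col) pairs sorted by row; pairs landing on infeasible
    cells are discarded, so an all-infeasible matrix yields no matches.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        return []
    if infeasible is None:
        infeasible = np.zeros(cost.shape, dtype=bool)
    infeasible = np.asarray(infeasible, dtype=bool)
    if not np.all(np.isfinite(cost[~infeasible])):
        raise ValueError("feasible cells must have finite cost")
    work = np.where(infeasible, _INFEASIBLE, cost)
    rows, cols = linear_sum_assignment(work)
    return sorted(
        (int(r), int(c)) for r, c in zip(rows, cols) if not infeasible[r, c]
    )


def appearance_cost(track: Track, det: Detection) -> float:
    """Smallest cosine distance between the detection and the gallery.

    0 for an identical unit vector, 1 for orthogonal, at most 2.
    """
    if det.appearance is None or not track.gallery:
        raise ValueError("appearance_cost requires a detection feature and a non-empty gallery")
    sims = [float(g @ det.appearance) for g in track.gallery]
    return 1.0 - max(sims)


def _gated_appearance_costs(
    kf: KalmanFilter,
    tracks: list[Track],
    detections: list[Detection],
    config: TrackerConfig,
) -> tuple[np.ndarray, np.ndarray]:
    cost = np.zeros((len(tracks), len(detections)))
    infeasible = np.zeros(cost.shape, dtype=bool)
    measurements = np.array([box_to_measurement(d.box) for d in detections])
    for i, trk in enumerate(tracks):
        d2 = kf.gating_distance(trk.mean, trk.covariance, measurements)
        for j, det in enumerate(detections):
            cost[i, j] = appearance_cost(trk, det)
        infeasible[i] = (d2 > config.gating_threshold) | (
            cost[i] > config.max_cosine_distance
        )
    return cost, infeasible


def matching_cascade(
    kf: KalmanFilter,
    tracks: list[Track],
    track_indices: list[int],
    detections: list[Detection],
    detection_indices: list[int],
    config: TrackerConfig,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Appearance matching of confirmed tracks in freshness tiers.

    Tracks are grouped by ``time_since_update``; tier 1 (seen last frame)
    matches first, so a detection claimed by a fresh track is never offered
    to a staler one. Within a tier, Hungarian assignment on the gated
    appearance-cosine cost.
    """
    unmatched_dets = list(detection_indices)
    matches: list[tuple[int, int]] = []
    matched_tracks: set[int] = set()
    for age in range(1, config.max_age + 2):
        if not unmatched_dets:
            break
        tier = [ti for ti in track_indices if tracks[ti].time_since_update == age]
        if not tier:
            continue
        tier_tracks = [tracks[ti] for ti in tier]
        tier_dets = [detections[di] for di in unmatched_dets]
        cost, infeasible = _gated_appearance_costs(kf, tier_tracks, tier_dets, config)
        for r, c in hungarian_assign(cost, infeasible):
            matches.append((tier[r], unmatched_dets[c]))
            matched_tracks.add(tier[r])
        taken = {di for _, di in matches}
        unmatched_dets = [di for di in unmatched_dets if di not in taken]
    unmatched_tracks = [ti for ti in track_indices if ti not in matched_tracks]
    return matches, unmatched_tracks, unmatched_dets


def iou_match(
    tracks: list[Track],
    track_indices: list[int],
    detections: list[Detection],
    detection_indices: list[int],
    config: TrackerConfig,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Hungarian assignment on 1 - IoU; overlaps below threshold are infeasible."""
    if not track_indices or not detection_indices:
        return [], list(track_indices), list(detection_indices)
    cost = np.zeros((len(track_indices), len(detection_indices)))
    for i, ti in enumerate(track_indices):
        tbox = tracks[ti].to_box()
        for j, di in enumerate(detection_indices):
            cost[i, j] = 1.0 - iou(tbox, detections[di].box)
    infeasible = cost > config.max_iou_distance
    matches = [
        (track_indices[r], detection_indices[c])
        for r, c in hungarian_assign(cost, infeasible)
    ]
    matched_t = {t for t, _ in matches}
    matched_d = {d for _, d in matches}
    return (
        matches,
        [ti for ti in track_indices if ti not in matched_t],
        [di for di in detection_indices if di not in matched_d],
    )


class Tracker:
    """Frame-by-frame tracker; call :meth:`step` once per frame in order."""

    def __init__(self, config: TrackerConfig | None = None) -> None:
        self.config = config or TrackerConfig()
        self.kf = KalmanFilter(
            std_weight_position=self.config.std_weight_position,
            std_weight_velocity=self.config.std_weight_velocity,
        )
        self.tracks: list[Track] = []
        self._next_id = 1

    def _initiate(self, det: Detection) -> Track:
        mean, cov = self.kf.initiate(box_to_measurement(det.box))
        trk = Track(
            mean, cov, self._next_id, det.class_id,
            self.config.n_init, self.config.gallery_budget, det.appearance,
        )
        self._next_id += 1
        return trk

    def step(self, detections: list[Detection]) -> list[Track]:
        """Advance one frame: predict, associate, update, initiate, prune.

        All detections must carry the same frame index. Returns the live
        (non-deleted) tracks after the update.
        """
        if detections:
            frames = {d.frame for d in detections}
            if len(frames) > 1:
                raise ValueError(f"detections span multiple frames: {sorted(frames)}")

        for trk in self.tracks:
            if not trk.is_deleted:
                trk.predict(self.kf)

        class_ids = sorted(
            {t.class_id for t in self.tracks if not t.is_deleted}
            | {d.class_id for d in detections}
        )
        all_matches: list[tuple[int, int]] = []
        all_unmatched_tracks: list[int] = []
        all_unmatched_dets: list[int] = []
        for cid in class_ids:
            det_idx = [j for j, d in enumerate(detections) if d.class_id == cid]
            # restrict track pool by class inside association
            track_pool = [i for i, t in enumerate(self.tracks)
                          if not t.is_deleted and t.class_id == cid]
            m, ut, ud = self._associate_subset(track_pool, detections, det_idx)
            all_matches += m
            all_unmatched_tracks += ut
            all_unmatched_dets += ud

        for ti, di in all_matches:
            self.tracks[ti].update(self.kf, detections[di])
        for ti in all_unmatched_tracks:
            self.tracks[ti].mark_missed(self.config.max_age)
        for di in all_unmatched_dets:
            self.tracks.append(self._initiate(detections[di]))

        self.tracks = [t for t in self.tracks if not t.is_deleted]
        return list(self.tracks)

    def _associate_subset(
        self, track_pool: list[int], detections: list[Detection], det_indices: list[int]
    ) -> tuple[list[tuple[int, int]], list[int], list[int]]:
        cfg = self.config
        confirmed = [i for i in track_pool if self.tracks[i].is_confirmed]
        unconfirmed = [i for i in track_pool if not self.tracks[i].is_confirmed]

        cascade_tracks = [i for i in confirmed if self.tracks[i].gallery]
        plain_confirmed = [i for i in confirmed if not self.tracks[i].gallery]
        cascade_dets = [j for j in det_indices if detections[j].appearance is not None]
        plain_dets = [j for j in det_indices if detections[j].appearance is None]

        matches_a, unmatched_a, leftover_dets = matching_cascade(
            self.kf, self.tracks, cascade_tracks, detections, cascade_dets, cfg
        )
        iou_track_candidates = unconfirmed + plain_confirmed + [
            i for i in unmatched_a if self.tracks[i].time_since_update == 1
        ]
        unmatched_a = [i for i in unmatched_a if self.tracks[i].time_since_update != 1]
        matches_b, unmatched_b, unmatched_dets = iou_match(
            self.tracks, iou_track_candidates, detections,
            leftover_dets + plain_dets, cfg,
        )
        return matches_a + matches_b, unmatched_a + unmatched_b, unmatched_dets
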