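"""Tracker components: Kalman filter, assignment, matching, lifecycle."""

import itertools

import numpy as np
import pytest

from seedtrack.boxes import BoundingBox, box_to_measurement, iou, measurement_to_box
from seedtrack.kalman import KalmanFilter
from seedtrack.tracking import (
    Detection,
    Tracker,
    TrackerConfig,
    TrackStatus,
    appearance_cost,
    hungarian_assign,
    iou_match,
    matching_cascade,
)

RNG = np.random.default_rng(99)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _det(frame, cx, cy, size=10.0, cls=0, conf=0.9, appearance=None):
    half = size / 2
    return Detection(
        frame, BoundingBox(cx - half, cy - half, cx + half, cy + half), conf, cls, appearance
    )


# -- box measurement conversion --------------------------------------------


@pytest.mark.parametrize(
    "box,expected",
    [
        ((0, 0, 4, 2), (2, 1, 2, 2)),
        ((10, 10, 20, 30), (15, 20, 0.5, 20)),
    ],
)
def test_box_to_measurement_examples(box, expected):
    np.testing.assert_allclose(box_to_measurement(BoundingBox(*box)), expected)


def test_box_measurement_roundtrip():
    for _ in range(50):
        x0, y0 = RNG.uniform(-50, 50, size=2)
        w, h = RNG.uniform(0.5, 40, size=2)
        box = BoundingBox(x0, y0, x0 + w, y0 + h)
        rt = measurement_to_box(box_to_measurement(box))
        np.testing.assert_allclose(
            [rt.x_min, rt.y_min, rt.x_max, rt.y_max],
            [box.x_min, box.y_min, box.x_max, box.y_max],
            atol=1e-9,
        )


def test_degenerate_box_rejected():
    with pytest.raises(ValueError):
        BoundingBox(0, 0, 0, 5)


# -- IoU --------------------------------------------------------------------


def test_iou_identical_disjoint_partial():
    a = BoundingBox(0, 0, 2, 2)
    assert iou(a, a) == 1.0
    assert iou(a, BoundingBox(5, 5, 7, 7)) == 0.0
    assert iou(a, BoundingBox(1, 0, 3, 2)) == pytest.approx(1 / 3)
    assert iou(BoundingBox(1, 0, 3, 2), a) == pytest.approx(1 / 3)


# -- Kalman filter ----------------------------------------------------------


def test_initiate_mean_and_covariance():
    kf = KalmanFilter()
    mean, cov = kf.initiate(np.array([0.0, 0.0, 1.0, 10.0]))
    np.testing.assert_allclose(mean, [0, 0, 1, 10, 0, 0, 0, 0])
    assert np.all(np.diag(cov) > 0)
    assert np.count_nonzero(cov - np.diag(np.diag(cov))) == 0
    with pytest.raises(ValueError):
        kf.initiate(np.array([0.0, 0.0, 1.0, -1.0]))


def test_predict_moves_position_by_velocity():
    kf = KalmanFilter(process_noise_scale=0.0)
    mean = np.array([0.0, 0.0, 1.0, 10.0, 2.0, -1.0, 0.0, 0.0])
    cov = np.eye(8)
    new_mean, _ = kf.predict(mean, cov)
    np.testing.assert_allclose(new_mean[:4], [2, -1, 1, 10])
    np.testing.assert_allclose(new_mean[4:], mean[4:])


def test_predict_inflates_covariance_trace():
    kf = KalmanFilter()
    mean, cov = kf.initiate(np.array([5.0, 5.0, 1.0, 20.0]))
    _, cov2 = kf.predict(mean, cov)
    assert np.trace(cov2) > np.trace(cov)
    kf0 = KalmanFilter(process_noise_scale=0.0)
    m0, c0 = kf0.initiate(np.array([5.0, 5.0, 1.0, 20.0]))
    m1, _ = kf0.predict(m0, c0)
    np.testing.assert_allclose(m1, m0)  # zero velocity, Q = 0


def test_update_exact_measurement_limit():
    kf = KalmanFilter(measurement_noise_scale=1e-12)
    mean, cov = kf.initiate(np.array([0.0, 0.0, 1.0, 10.0]))
    mean, cov = kf.predict(mean, cov)
    z = np.array([3.0, -2.0, 1.1, 11.0])
    post, _ = kf.update(mean, cov, z)
    np.testing.assert_allclose(post[:4], z, atol=1e-6)


def test_update_zero_innovation_keeps_mean():
    kf = KalmanFilter()
    mean, cov = kf.initiate(np.array([4.0, 4.0, 1.0, 8.0]))
    mean, cov = kf.predict(mean, cov)
    post, _ = kf.update(mean, cov, mean[:4])
    np.testing.assert_allclose(post, mean, atol=1e-9)


def test_update_matches_textbook_closed_form():
    """One predict/update against an independently computed Kalman step."""
    kf = KalmanFilter()
    mean, cov = kf.initiate(np.array([10.0, 20.0, 0.5, 16.0]))
    mean_p, cov_p = kf.predict(mean, cov)
    z = np.array([11.0, 21.5, 0.52, 16.5])
    post_mean, post_cov = kf.update(mean_p, cov_p, z)

    # oracle: dense matrix arithmetic with the explicit inverse
    F = np.eye(8)
    F[:4, 4:] = np.eye(4)
    H = np.eye(4, 8)
    h = 16.0
    q_std = np.array([h / 20, h / 20, 1e-2, h / 20, h / 160, h / 160, 1e-5, h / 160])
    r_std = np.array([h / 20, h / 20, 1e-1, h / 20])
    P = F @ cov @ F.T + np.diag(q_std**2)
    x = F @ mean
    S = H @ P @ H.T + np.diag(r_std**2)
    K = P @ H.T @ np.linalg.inv(S)
    x_post = x + K @ (z - H @ x)
    P_post = P - K @ S @ K.T
    np.testing.assert_allclose(post_mean, x_post, atol=1e-9)
    np.testing.assert_allclose(post_cov, P_post, atol=1e-9)


def test_noiseless_filter_locks_onto_constant_velocity():
    """With zero process/measurement noise the posterior reproduces a
    noiseless constant-velocity trajectory exactly after two updates."""
    kf = KalmanFilter(process_noise_scale=0.0, measurement_noise_scale=1e-12)
    v = np.array([3.0, -1.0, 0.0, 0.0])
    z0 = np.array([0.0, 0.0, 1.0, 10.0])
    mean, cov = kf.initiate(z0)
    for t in (1, 2, 3):
        mean, cov = kf.predict(mean, cov)
        mean, cov = kf.update(mean, cov, z0 + t * v)
    mean, cov = kf.predict(mean, cov)
    np.testing.assert_allclose(mean[:4], z0 + 4 * v, atol=1e-4)
    np.testing.assert_allclose(mean[4:], v, atol=1e-4)


def test_gating_distance_zero_at_prediction_and_matches_inverse_oracle():
    kf = KalmanFilter()
    mean, cov = kf.initiate(np.array([50.0, 50.0, 1.0, 12.0]))
    mean, cov = kf.predict(mean, cov)
    zs = np.vstack([mean[:4], mean[:4] + [3.0, -2.0, 0.05, 1.0]])
    d = kf.gating_distance(mean, cov, zs)
    assert d[0] == pytest.approx(0.0, abs=1e-12)
    proj_mean, s = kf.project(mean, cov)
    for i, z in enumerate(zs):
        e = z - proj_mean
        assert d[i] == pytest.approx(e @ np.linalg.inv(s) @ e, rel=1e-9)


# -- appearance cost --------------------------------------------------------


def test_appearance_cost_identical_orthogonal_and_angled():
    f = _unit([1.0, 0.0])
    cfg = TrackerConfig()
    kf = KalmanFilter()
    tracker = Tracker(cfg)
    trk = tracker._initiate(_det(0, 10, 10, appearance=f))
    assert appearance_cost(trk, _det(0, 10, 10, appearance=f)) == pytest.approx(0.0)
    assert appearance_cost(trk, _det(0, 10, 10, appearance=_unit([0.0, 1.0]))) == pytest.approx(1.0)
    # gallery holding vectors at 30 and 90 degrees from f: min cost = 1 - cos(30)
    trk.gallery.clear()
    theta = np.pi / 6
    trk.gallery.append(_unit([np.cos(theta), np.sin(theta)]))
    trk.gallery.append(_unit([0.0, 1.0]))
    assert appearance_cost(trk, _det(0, 10, 10, appearance=f)) == pytest.approx(
        1 - np.cos(theta), abs=1e-9
    )


def test_detection_rejects_non_unit_appearance():
    with pytest.raises(ValueError):
        _det(0, 0, 0, appearance=np.array([1.0, 1.0]))


# -- Hungarian assignment ---------------------------------------------------


def _brute_force(cost, infeasible=None):
    """Max-cardinality, min-cost one-to-one matching by enumeration."""
    m, n = cost.shape
    if infeasible is None:
        infeasible = np.zeros((m, n), dtype=bool)
    best_count, best_total = -1, np.inf
    for k in range(min(m, n), -1, -1):
        for rsub in itertools.permutations(range(m), k):
            for csub in itertools.permutations(range(n), k):
                if any(infeasible[r, c] for r, c in zip(rsub, csub)):
                    continue
                total = sum(cost[r, c] for r, c in zip(rsub, csub))
                if k > best_count or (k == best_count and total < best_total):
                    best_count, best_total = k, total
        if best_count == k:
            break
    return best_count, best_total


def test_hungarian_simple_examples():
    assert hungarian_assign(np.array([[0.0, 1.0], [1.0, 0.0]])) == [(0, 0), (1, 1)]
    pairs = hungarian_assign(np.full((3, 3), 2.0))
    assert len(pairs) == 3
    assert sum(2.0 for _ in pairs) == pytest.approx(6.0)


def test_hungarian_all_infeasible_empty():
    cost = np.zeros((2, 2))
    assert hungarian_assign(cost, np.ones((2, 2), dtype=bool)) == []


def test_hungarian_matches_brute_force_on_random_matrices():
    rng = np.random.default_rng(7)
    for _ in range(30):
        m, n = rng.integers(1, 6, size=2)
        cost = rng.uniform(0, 1, size=(m, n))
        infeasible = rng.uniform(size=(m, n)) < 0.2
        pairs = hungarian_assign(cost, infeasible)
        total = sum(cost[r, c] for r, c in pairs)
        bf_count, bf_total = _brute_force(cost, infeasible)
        assert len(pairs) == bf_count
        assert total == pytest.approx(bf_total, abs=1e-9)


# -- matching stages --------------------------------------------------------


def _confirmed_track(tracker, cx, cy, appearance, n_init=3):
    """Drive one detection through n_init frames to get a confirmed track."""
    for f in range(n_init):
        tracker.step([_det(f, cx, cy, appearance=appearance)])
    (trk,) = tracker.tracks
    assert trk.is_confirmed
    return trk


def test_cascade_matches_single_track():
    cfg = TrackerConfig()
    tracker = Tracker(cfg)
    f = _unit(RNG.normal(size=8))
    trk = _confirmed_track(tracker, 50, 50, f)
    trk.predict(tracker.kf)
    dets = [_det(3, 50, 50, appearance=f)]
    matches, um_t, um_d = matching_cascade(tracker.kf, tracker.tracks, [0], dets, [0], cfg)
    assert matches == [(0, 0)] and not um_t and not um_d


def test_cascade_no_detections():
    cfg = TrackerConfig()
    tracker = Tracker(cfg)
    trk = _confirmed_track(tracker, 50, 50, _unit(RNG.normal(size=8)))
    trk.predict(tracker.kf)
    matches, um_t, um_d = matching_cascade(tracker.kf, tracker.tracks, [0], [], [], cfg)
    assert matches == [] and um_t == [0] and um_d == []


def test_cascade_prefers_fresher_track():
    """Two confirmed tracks compete for one detection both could take; the
    track seen more recently wins because its tier matches first."""
    cfg = TrackerConfig()
    tracker = Tracker(cfg)
    f = _unit(RNG.normal(size=8))
    for frame in range(3):
        tracker.step(
            [
                _det(frame, 50, 50, size=40, appearance=f),
                _det(frame, 60, 50, size=40, appearance=f),
            ]
        )
    t_fresh, t_stale = tracker.tracks
    assert t_fresh.is_confirmed and t_stale.is_confirmed
    # age the second track by two missed frames
    for trk in tracker.tracks:
        trk.predict(tracker.kf)
    t_fresh.update(tracker.kf, _det(3, 50, 50, size=40, appearance=f))
    for trk in tracker.tracks:
        trk.predict(tracker.kf)
    assert t_fresh.time_since_update == 1 and t_stale.time_since_update == 2
    det = _det(4, 55, 50, size=40, appearance=f)  # feasible for both
    matches, _, _ = matching_cascade(
        tracker.kf, tracker.tracks, [0, 1], [det], [0], cfg
    )
    assert matches == [(0, 0)]  # the fresher track


def test_iou_match_basic_and_crossed():
    cfg = TrackerConfig()
    tracker = Tracker(cfg)
    tracker.step([_det(0, 50, 50), _det(0, 62, 50)])
    for trk in tracker.tracks:
        trk.predict(tracker.kf)
    # identical boxes -> cost 0 match
    dets = [_det(1, 50, 50), _det(1, 62, 50)]
    matches, um_t, um_d = iou_match(tracker.tracks, [0, 1], dets, [0, 1], cfg)
    total = sum(1 - iou(tracker.tracks[t].to_box(), dets[d].box) for t, d in matches)
    # brute force over the two permutations
    best = min(
        sum(1 - iou(tracker.tracks[t].to_box(), dets[d].box) for t, d in perm)
        for perm in ([(0, 0), (1, 1)], [(0, 1), (1, 0)])
    )
    assert total == pytest.approx(best)
    # disjoint -> no matches
    far = [_det(1, 500, 500)]
    m2, _, ud = iou_match(tracker.tracks, [0, 1], far, [0], cfg)
    assert m2 == [] and ud == [0]


# -- tracker lifecycle ------------------------------------------------------


def test_step_initiates_tentative_tracks_with_sequential_ids():
    tracker = Tracker()
    live = tracker.step([_det(0, 10, 10), _det(0, 30, 10), _det(0, 50, 10)])
    assert [t.track_id for t in live] == [1, 2, 3]
    assert all(t.status is TrackStatus.TENTATIVE for t in live)


def test_step_confirms_after_n_init_hits():
    tracker = Tracker(TrackerConfig(n_init=3))
    for f in range(3):
        live = tracker.step([_det(f, 20, 20)])
    assert len(live) == 1 and live[0].is_confirmed


def test_step_rejects_mixed_frames():
    tracker = Tracker()
    with pytest.raises(ValueError):
        tracker.step([_det(0, 10, 10), _det(1, 30, 10)])


def test_constant_velocity_object_keeps_one_identity():
    """30 frames of a drifting object with 0.5 px jitter: one id, no switches."""
    rng = np.random.default_rng(42)
    tracker = Tracker()
    seen_ids = set()
    for f in range(30):
        cx = 20.0 + 4.0 * f + rng.normal(scale=0.5)
        cy = 100.0 - 2.0 * f + rng.normal(scale=0.5)
        live = tracker.step([_det(f, cx, cy)])
        seen_ids.update(t.track_id for t in live)
    assert seen_ids == {1}


def test_class_separation_spawns_separate_tracks():
    """Same position, different classes: never matched into one track."""
    tracker = Tracker()
    for f in range(5):
        live = tracker.step([_det(f, 40, 40, cls=0), _det(f, 40, 40, cls=1)])
    classes = sorted(t.class_id for t in live)
    assert classes == [0, 1]
    assert len({t.track_id for t in live}) == 2


def test_tentative_track_dies_on_first_miss_and_ids_never_reused():
    tracker = Tracker()
    tracker.step([_det(0, 10, 10)])
    tracker.step([])  # tentative track unmatched -> deleted
    assert tracker.tracks == []
    live = tracker.step([_det(2, 10, 10)])
    assert live[0].track_id == 2  # id 1 is never reused


def test_out_of_gate_detection_starts_new_track():
    tracker = Tracker()
    f = _unit(RNG.normal(size=8))
    _confirmed_track(tracker, 50, 50, f)
    live = tracker.step([_det(3, 400, 400, appearance=f)])
    ids = {t.track_id for t in live}
    assert len(ids) == 2  # far detection cannot join the confirmed track


def test_confirmed_track_survives_misses_until_max_age():
    tracker = Tracker(TrackerConfig(max_age=5))
    f = _unit(RNG.normal(size=8))
    _confirmed_track(tracker, 50, 50, f)
    for _ in range(5):
        tracker.step([])
        assert len(tracker.tracks) == 1
    tracker.step([])  # exceeds max_age
    assert tracker.tracks == []
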