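"""Kinematic statistics: trimming, filtering, smoothing, orientation,
feeding detection, activity and latency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aviforage import (
    activity_rate,
    detect_feeding,
    filter_low_likelihood,
    index_to_degrees,
    latency_to_feed,
    loess_smooth,
    orientation_index,
    session_stats,
    simulate_session,
    trim_initial,
)
from aviforage.config import ArenaGeometry, Preprocessing
from aviforage.errors import DomainError, EmptyTrajectoryError, ParameterError
from aviforage.io import make_trajectory
from aviforage.kinematics import SPEED_FLOOR, smooth_trajectory

from conftest import small_config


def _traj(body, head=None, fps=10.0, likelihood=None, units="cm"):
    body = np.asarray(body, dtype=float)
    head = np.asarray(head, dtype=float) if head is not None else body + [5.0, 0.0]
    n = len(body)
    lk = likelihood if likelihood is not None else np.full(n, 0.99)
    return make_trajectory(
        {"head": head, "body-center": body},
        {"head": lk, "body-center": np.full(n, 0.99)},
        fps=fps,
        units=units,
    )


# --------------------------------------------------------------------------
# trimming
# --------------------------------------------------------------------------


def test_trim_removes_first_two_seconds():
    traj = _traj(np.zeros((18000, 2)), fps=30.0)
    out = trim_initial(traj, 2.0)
    assert out.n_frames == 17940
    assert out.frames[0] == 60
    assert out.time[0] == pytest.approx(2.0)  # times stay absolute


def test_trim_zero_is_identity():
    traj = _traj(np.zeros((100, 2)))
    assert trim_initial(traj, 0.0) is traj


def test_trim_longer_than_session_raises():
    traj = _traj(np.zeros((10, 2)), fps=10.0)
    with pytest.raises(EmptyTrajectoryError):
        trim_initial(traj, 5.0)


# --------------------------------------------------------------------------
# likelihood filtering
# --------------------------------------------------------------------------


def test_threshold_zero_is_identity():
    traj = _traj(np.zeros((50, 2)))
    assert filter_low_likelihood(traj, 0.0) is traj


def test_single_dropout_linearly_interpolated():
    body = np.array([[0.0, 0.0], [9.0, 9.0], [2.0, 2.0]])
    lk = np.array([0.99, 0.1, 0.99])
    traj = _traj(body, head=body.copy(), likelihood=lk)
    out = filter_low_likelihood(traj, threshold=0.6)
    assert np.allclose(out.xy("head")[1], [1.0, 1.0])


def test_long_gaps_stay_missing():
    n = 40
    body = np.tile([1.0, 1.0], (n, 1))
    lk = np.full(n, 0.99)
    lk[10:30] = 0.1  # 2-s gap at 10 fps > 0.5-s max gap
    traj = _traj(body, head=body.copy(), likelihood=lk, fps=10.0)
    out = filter_low_likelihood(traj, threshold=0.6, max_gap_seconds=0.5)
    assert np.isnan(out.xy("head")[15]).all()


def test_all_frames_below_threshold_raises():
    traj = _traj(np.zeros((20, 2)), head=np.zeros((20, 2)), likelihood=np.full(20, 0.1))
    with pytest.raises(EmptyTrajectoryError):
        filter_low_likelihood(traj, threshold=0.6)


def test_interpolated_dropouts_track_clean_path():
    """Simulated dropouts, filtered at 0.6 on a noise-free signal, land
    within a small bound of the simulator's clean positions."""
    cfg = small_config(tracker_noise_sd=0.0, dropout_prob=0.05, session_length=30.0)
    sim = simulate_session(cfg, "b01", "Wall", 1)
    from aviforage import to_arena_coords

    traj = to_arena_coords(sim.trajectory, cfg.arena)
    out = filter_low_likelihood(traj, threshold=0.6, max_gap_seconds=0.5)
    head = out.xy("head")
    ok = ~np.isnan(head[:, 0])
    err = np.linalg.norm(head[ok] - sim.truth.head[ok], axis=1)
    # linear interpolation across <=0.5 s of an ~11 cm/s walk
    assert np.quantile(err, 0.99) < 3.0
    assert np.median(err) < 0.2


# --------------------------------------------------------------------------
# LOESS smoothing
# --------------------------------------------------------------------------


def test_loess_preserves_constants_and_lines():
    t = np.arange(200) / 10.0
    const = np.full(200, 3.7)
    line = 3.0 * t + 1.0
    assert np.allclose(loess_smooth(const, t, span=0.2), const)
    assert np.allclose(loess_smooth(line, t, span=0.2), line, atol=1e-8)


def test_loess_span_too_small_raises():
    t = np.arange(20.0)
    with pytest.raises(ParameterError):
        loess_smooth(np.sin(t), t, span=0.05)  # one point per window
    with pytest.raises(ParameterError):
        loess_smooth(np.sin(t), t, span=1.5)


def test_loess_reduces_noise_rmse(rng):
    """Across 20 noisy paths, smoothing lowers the RMSE to the clean path."""
    t = np.arange(600) / 30.0
    wins = 0
    for _ in range(20):
        clean = 10 * np.sin(t / 3.0) + 20
        noisy = clean + rng.normal(0, 0.5, len(t))
        sm = loess_smooth(noisy, t, span=0.05)
        rmse_sm = np.sqrt(np.mean((sm - clean) ** 2))
        rmse_raw = np.sqrt(np.mean((noisy - clean) ** 2))
        wins += rmse_sm < rmse_raw
    assert wins == 20


# --------------------------------------------------------------------------
# orientation index
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "head, target, expected",
    [
        ((1, 0), (2, 0), 1.0),  # facing the feeder
        ((1, 0), (0, 5), 0.0),  # perpendicular
        ((1, 0), (-3, 0), -1.0),  # facing away
    ],
)
def test_orientation_anchor_cases(head, target, expected):
    assert orientation_index((0, 0), head, target) == pytest.approx(expected, abs=1e-12)


def test_degenerate_orientation_is_nan():
    assert np.isnan(orientation_index((1, 1), (1, 1), (2, 2)))
    assert np.isnan(orientation_index((1, 1), (2, 2), (1, 1)))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    bx=st.floats(-50, 50),
    by=st.floats(-50, 50),
    ang_h=st.floats(0, 2 * np.pi),
    ang_t=st.floats(0, 2 * np.pi),
    shift_x=st.floats(-100, 100),
    shift_y=st.floats(-100, 100),
    rot=st.floats(0, 2 * np.pi),
    scale=st.floats(0.01, 100),
)
def test_orientation_invariant_under_rigid_motion_and_scaling(
    bx, by, ang_h, ang_t, shift_x, shift_y, rot, scale
):
    body = np.array([bx, by])
    head = body + 3.0 * np.array([np.cos(ang_h), np.sin(ang_h)])
    target = body + 8.0 * np.array([np.cos(ang_t), np.sin(ang_t)])
    base = orientation_index(body, head, target)
    c, s = np.cos(rot), np.sin(rot)
    R = np.array([[c, -s], [s, c]])
    shift = np.array([shift_x, shift_y])

    def xform(p):
        return scale * (R @ p) + shift

    moved = orientation_index(xform(body), xform(head), xform(target))
    assert moved == pytest.approx(base, abs=1e-6)
    assert -1.0 <= base <= 1.0


# --------------------------------------------------------------------------
# index -> degrees
# --------------------------------------------------------------------------


def test_index_to_degrees_values():
    assert float(index_to_degrees(0.32)) == pytest.approx(18.66, abs=0.005)
    assert float(index_to_degrees(0.0)) == 0.0
    assert float(index_to_degrees(1.0)) == pytest.approx(90.0)
    assert float(index_to_degrees(-0.5)) == pytest.approx(-30.0)


def test_index_to_degrees_domain_error():
    with pytest.raises(DomainError):
        index_to_degrees(1.5)


# --------------------------------------------------------------------------
# feeding detection, activity, latency
# --------------------------------------------------------------------------


def test_head_at_feeder_is_always_feeding(arena):
    head = np.tile(arena.feeder_center, (50, 1))
    traj = _traj(np.tile([30.0, 30.0], (50, 1)), head=head)
    assert detect_feeding(traj, arena).all()


def test_head_far_from_feeder_never_feeds(arena):
    head = np.tile([5.0, 5.0], (50, 1))
    traj = _traj(np.tile([10.0, 5.0], (50, 1)), head=head)
    assert not detect_feeding(traj, arena).any()


def test_short_zone_crossings_debounced(arena):
    head = np.tile([5.0, 5.0], (50, 1))
    head[20:22] = arena.feeder_center  # 0.2 s < 0.3 s minimum bout
    traj = _traj(np.tile([10.0, 5.0], (50, 1)), head=head)
    assert not detect_feeding(traj, arena, min_bout_seconds=0.3).any()


def test_feeding_mask_matches_ground_truth(arena):
    cfg = small_config(tracker_noise_sd=0.0, dropout_prob=0.0, session_length=60.0)
    sim = simulate_session(cfg, "b01", "Stranger", 1)
    st = session_stats(sim.trajectory, cfg.arena)
    trim = int(2.0 * cfg.fps)
    agreement = (st.feeding_mask == sim.truth.feeding_mask[trim:]).mean()
    assert agreement >= 0.95


def test_constant_speed_activity_is_log_speed():
    v, fps = 3.0, 10.0
    n = 100
    body = np.column_stack([np.arange(n) * v / fps, np.zeros(n)])
    traj = _traj(body, head=body + [0.0, 50.0], fps=fps)
    mask = np.zeros(n, dtype=bool)
    assert activity_rate(traj, mask) == pytest.approx(np.log(v))


def test_stationary_bird_hits_epsilon_floor():
    body = np.tile([10.0, 10.0], (50, 1))
    traj = _traj(body)
    assert activity_rate(traj, np.zeros(50, dtype=bool)) == pytest.approx(
        np.log(SPEED_FLOOR)
    )


def test_feeding_frames_excluded_from_activity():
    """Fast feeding frames must not contaminate the non-feeding mean."""
    fps = 10.0
    slow = np.column_stack([np.arange(50) * 0.2, np.zeros(50)])  # 2 cm/s
    fast = np.column_stack([10 + np.arange(50) * 5.0, np.zeros(50)])  # 50 cm/s
    body = np.vstack([slow, fast])
    traj = _traj(body, fps=fps)
    mask = np.zeros(100, dtype=bool)
    mask[50:] = True
    assert activity_rate(traj, mask) == pytest.approx(np.log(2.0), abs=1e-6)


def test_configured_speed_ratio_recovered_in_log_activity():
    """Conditions with a 2x speed ratio differ by ~ln 2 in mean log activity."""
    cfg = small_config(
        n_birds=2,
        n_sessions=6,
        session_length=120.0,
        conditions=("Wall", "Stranger"),
        latency_mean={"Wall": [8.0] * 6, "Stranger": [8.0] * 6},
        approach_speed_mean={"Wall": 6.0, "Stranger": 12.0},
        tracker_noise_sd=0.0,
        dropout_prob=0.0,
    )
    acts = {c: [] for c in cfg.conditions}
    for c in cfg.conditions:
        for b in cfg.bird_ids:
            for s in range(1, 7):
                sim = simulate_session(cfg, b, c, s)
                acts[c].append(session_stats(sim.trajectory, cfg.arena).log_activity)
    diff = np.mean(acts["Stranger"]) - np.mean(acts["Wall"])
    se = np.sqrt(
        np.var(acts["Stranger"], ddof=1) / 12 + np.var(acts["Wall"], ddof=1) / 12
    )
    assert abs(diff - np.log(2.0)) < 3 * se + 0.05


def test_latency_recovered_on_clean_sessions():
    cfg = small_config(tracker_noise_sd=0.0, dropout_prob=0.0, session_length=60.0)
    tol = 1.0 / cfg.fps + 0.3  # frame quantization + debounce
    for s in (1, 2):
        sim = simulate_session(cfg, "b02", "Wall", s)
        st = session_stats(sim.trajectory, cfg.arena)
        assert not st.censored
        assert abs(st.latency_s - sim.truth.latency_s) <= tol


def test_bird_starting_inside_zone_gets_trim_boundary_latency(arena):
    head = np.tile(arena.feeder_center, (100, 1))
    traj = _traj(np.tile([50.0, 44.0], (100, 1)), head=head, fps=10.0)
    trimmed = trim_initial(traj, 2.0)
    lat = latency_to_feed(trimmed, arena)
    assert not lat.censored
    assert lat.seconds == pytest.approx(2.0)


def test_no_approach_censored_at_session_length(arena):
    head = np.tile([5.0, 5.0], (100, 1))
    traj = _traj(np.tile([10.0, 5.0], (100, 1)), head=head, fps=10.0)
    lat = latency_to_feed(traj, arena, session_length=600.0)
    assert lat.censored
    assert lat.seconds == 600.0


def test_smoothing_window_shorter_than_heading_dynamics(arena):
    """The default chain does not meaningfully inflate the orientation
    index: full-chain post-approach mean within 0.05 of the clean bias."""
    cfg = small_config(
        n_sessions=4,
        session_length=120.0,
        latency_mean={"Wall": [8.0] * 4, "Stranger": [8.0] * 4},
    )
    for condition in cfg.conditions:
        vals = []
        for s in range(1, 5):
            sim = simulate_session(cfg, "b01", condition, s)
            st = session_stats(sim.trajectory, cfg.arena)
            post = (
                np.arange(int(2 * cfg.fps), sim.trajectory.n_frames)
                >= sim.truth.approach_end_frame
            )
            vals.append(np.nanmean(st.orientation.to_numpy()[post]))
        assert abs(np.mean(vals) - cfg.orientation_bias[condition]) < 0.05
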