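"""Per-session kinematic statistics from keypoint trajectories.

The chain implemented here: trim the first seconds of a session, drop and
interpolate low-confidence frames, LOESS-smooth the coordinates, then
derive the body-orientation index, the feeding-episode mask, the
log-activity rate, and the latency to the first feeding episode.

The body-orientation index is the cosine of the angle between the
body-to-head vector and the body-to-feeder vector: 1 = facing the feeder
(and hence the barrier/mirror/partner behind it), 0 = perpendicular,
-1 = facing away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import ArenaGeometry, Preprocessing
from .errors import DomainError, EmptyTrajectoryError, ParameterError
from .io import REQUIRED_BODYPARTS, Trajectory

__all__ = [
    "trim_initial",
    "filter_low_likelihood",
    "loess_smooth",
    "smooth_trajectory",
    "orientation_index",
    "index_to_degrees",
    "detect_feeding",
    "activity_rate",
    "latency_to_feed",
    "session_stats",
    "SessionStats",
    "LatencyResult",
]

#: floor (cm/s) applied to the mean speed before the log transform
SPEED_FLOOR = 1e-3


@dataclass
class LatencyResult:
    seconds: float
    censored: bool


@dataclass
class SessionStats:
    """Scalar summaries of one session plus the per-frame orientation series."""

    latency_s: float
    censored: bool
    log_activity: float
    mean_orientation: float
    orientation: pd.Series  # indexed by time (s)
    feeding_mask: np.ndarray


def trim_initial(traj: Trajectory, seconds: float = 2.0) -> Trajectory:
    """Drop frames with time < ``seconds``; frame numbers stay absolute."""
    if seconds < 0:
        raise ParameterError("trim seconds must be >= 0")
    if seconds == 0:
        return traj
    keep = traj.time >= seconds
    if not keep.any():
        raise EmptyTrajectoryError(
            f"trajectory shorter than the {seconds}-s trim window"
        )
    return traj.with_data(traj.data.loc[keep])


def filter_low_likelihood(
    traj: Trajectory,
    threshold: float = 0.6,
    max_gap_seconds: float = 0.5,
    bodyparts=REQUIRED_BODYPARTS,
) -> Trajectory:
    """Mask low-confidence frames and interpolate short gaps.

    Frames whose likelihood falls below ``threshold`` have their
    coordinates set to missing; runs of missing frames no longer than
    ``max_gap_seconds`` are filled by linear interpolation, longer runs
    stay missing and are excluded from downstream statistics.
    """
    if not 0 <= threshold <= 1:
        raise ParameterError("likelihood threshold must be in [0, 1]")
    if threshold == 0:
        return traj
    max_gap = int(round(max_gap_seconds * traj.fps))
    df = traj.data.copy()
    for bp in bodyparts:
        bad = df[(bp, "likelihood")].to_numpy() < threshold
        if bad.all():
            raise EmptyTrajectoryError(
                f"all frames of {bp!r} below the likelihood threshold"
            )
        for coord in ("x", "y"):
            col = df[(bp, coord)].to_numpy(dtype=float).copy()
            col[bad] = np.nan
            df[(bp, coord)] = _interpolate_short_gaps(col, max_gap)
    return traj.with_data(df)


def _interpolate_short_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly fill interior NaN runs of length <= max_gap."""
    out = values.copy()
    isnan = np.isnan(out)
    if not isnan.any() or isnan.all():
        return out
    idx = np.arange(len(out))
    # run-length encode the NaN stretches
    edges = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start > max_gap or start == 0 or stop == len(out):
            continue  # too long, or touches an edge (no anchor on one side)
        x0, x1 = start - 1, stop
        frac = (idx[start:stop] - x0) / (x1 - x0)
        out[start:stop] = out[x0] + frac * (out[x1] - out[x0])
    return out


def loess_smooth(
    values: np.ndarray,
    times: np.ndarray,
    span: float = 0.05,
    delta_frac: float | None = None,
) -> np.ndarray:
    """Locally weighted linear regression (tricube weights) of one series.

    ``span`` is the fraction of the series inside each local window.
    Missing values are left missing; the fit uses the observed points
    only.  ``delta_frac`` (fraction of the series duration) enables the
    standard linear-interpolation shortcut between nearby anchors; by
    default it is one fifth of the window so the shortcut never smooths
    beyond the window itself (0 disables it).
    """
    if not 0 < span <= 1:
        raise ParameterError("span must lie in (0, 1]")
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    ok = ~np.isnan(values)
    n_ok = int(ok.sum())
    if n_ok == 0:
        return values.copy()
    if span * n_ok < 2:
        raise ParameterError(
            f"span {span} leaves fewer than 2 points in the local window"
        )
    if delta_frac is None:
        delta_frac = span / 5.0
    delta = delta_frac * (times[ok].max() - times[ok].min()) if delta_frac else 0.0
    smoothed = lowess(
        values[ok], times[ok], frac=span, it=0, delta=delta, return_sorted=False
    )
    out = np.full_like(values, np.nan)
    out[ok] = smoothed
    return out


def smooth_trajectory(
    traj: Trajectory,
    span: float = 0.05,
    bodyparts=REQUIRED_BODYPARTS,
    delta_frac: float | None = None,
) -> Trajectory:
    """LOESS-smooth x and y of the given bodyparts."""
    df = traj.data.copy()
    t = traj.time
    for bp in bodyparts:
        for coord in ("x", "y"):
            df[(bp, coord)] = loess_smooth(
                df[(bp, coord)].to_numpy(dtype=float), t, span, delta_frac
            )
    return traj.with_data(df)


def orientation_index(body, head, target) -> np.ndarray | float:
    """Cosine of the angle between (head - body) and (target - body).

    Accepts single points or (n, 2) arrays.  Degenerate frames (head or
    target coinciding with the body, or missing coordinates) yield NaN
    rather than raising.
    """
    body = np.atleast_2d(np.asarray(body, dtype=float))
    head = np.atleast_2d(np.asarray(head, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    u = head - body
    v = target - body
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.einsum("ij,ij->i", u, v) / (nu * nv)
    cos = np.where((nu == 0) | (nv == 0), np.nan, cos)
    cos = np.clip(cos, -1.0, 1.0)
    return float(cos[0]) if cos.shape == (1,) else cos


def index_to_degrees(x):
    """Convert an orientation-index value to degrees via arcsin.

    Sign-preserving: arcsin(x) * 180 / pi, so 0 -> 0 deg and 1 -> 90 deg.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise DomainError("orientation index must lie in [-1, 1]")
    return np.degrees(np.arcsin(np.clip(arr, -1.0, 1.0)))


def detect_feeding(
    traj: Trajectory, geom: ArenaGeometry, min_bout_seconds: float = 0.3
) -> np.ndarray:
    """Feeding mask: head within the feeder zone, debounced.

    True runs shorter than ``min_bout_seconds`` are removed; frames with a
    missing head position count as not feeding.
    """
    if traj.units != "cm":
        raise ParameterError("detect_feeding expects a trajectory in cm")
    head = traj.xy("head")
    dist = np.linalg.norm(head - np.asarray(geom.feeder_center), axis=1)
    with np.errstate(invalid="ignore"):
        mask = dist <= geom.feeder_zone_radius
    mask[np.isnan(dist)] = False
    min_run = max(int(round(min_bout_seconds * traj.fps)), 1)
    return _debounce(mask, min_run)


def _debounce(mask: np.ndarray, min_run: int) -> np.ndarray:
    out = mask.copy()
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < min_run:
            out[start:stop] = False
    return out


def activity_rate(
    traj: Trajectory, feeding_mask: np.ndarray, fps: float | None = None
) -> float:
    """Natural log of the mean non-feeding body-center speed (cm/s).

    Speed is the frame-to-frame displacement times fps; a pair of frames
    contributes only when neither frame is feeding, the frames are
    consecutive, and both positions are present.  The mean speed is
    floored at :data:`SPEED_FLOOR` before the log so a stationary bird
    yields a finite value.
    """
    fps = fps or traj.fps
    body = traj.xy("body-center")
    frames = traj.frames
    d = np.linalg.norm(np.diff(body, axis=0), axis=1)
    consecutive = np.diff(frames) == 1
    valid = (
        consecutive
        & ~feeding_mask[:-1]
        & ~feeding_mask[1:]
        & ~np.isnan(d)
    )
    if not valid.any():
        warnings.warn("no non-feeding frame pairs; activity rate undefined")
        return float("nan")
    mean_speed = float(np.mean(d[valid]) * fps)
    return float(np.log(max(mean_speed, SPEED_FLOOR)))


def latency_to_feed(
    traj: Trajectory,
    geom: ArenaGeometry,
    min_bout_seconds: float = 0.3,
    session_length: float | None = None,
    feeding_mask: np.ndarray | None = None,
) -> LatencyResult:
    """Time of the first debounced feeding episode, from the session start.

    The first feeder-zone entry of the head stands proxy for the first
    peck.  If no feeding episode occurs the latency is right-censored at
    ``session_length`` (or the trajectory end).
    """
    if traj.n_frames == 0:
        raise EmptyTrajectoryError("empty trajectory")
    if feeding_mask is None:
        feeding_mask = detect_feeding(traj, geom, min_bout_seconds)
    if feeding_mask.any():
        first = int(np.argmax(feeding_mask))
        return LatencyResult(seconds=float(traj.frames[first] / traj.fps), censored=False)
    end = session_length if session_length is not None else float(
        (traj.frames[-1] + 1) / traj.fps
    )
    return LatencyResult(seconds=float(end), censored=True)


def session_stats(
    traj_px: Trajectory,
    geom: ArenaGeometry,
    prep: Preprocessing | None = None,
    session_length: float | None = None,
) -> SessionStats:
    """Run the full per-session chain on a raw pixel trajectory."""
    from .io import to_arena_coords

    prep = prep or Preprocessing()
    traj = trim_initial(traj_px, prep.trim_seconds)
    traj = filter_low_likelihood(
        traj, prep.likelihood_threshold, prep.max_gap_seconds
    )
    traj = to_arena_coords(traj, geom)
    if prep.loess_span is not None:
        span = prep.loess_span
    else:
        duration = max(traj.time[-1] - traj.time[0], 1e-9)
        span = min(1.0, max(prep.loess_window_seconds / duration, 3.0 / traj.n_frames))
    traj = smooth_trajectory(traj, span)

    mask = detect_feeding(traj, geom, prep.min_bout_seconds)
    lat = latency_to_feed(
        traj, geom, prep.min_bout_seconds, session_length, feeding_mask=mask
    )
    log_act = activity_rate(traj, mask)
    ori = orientation_index(
        traj.xy("body-center"), traj.xy("head"), np.asarray(geom.feeder_center)
    )
    series = pd.Series(ori, index=pd.Index(traj.time, name="time"), name="orientation")
    return SessionStats(
        latency_s=lat.seconds,
        censored=lat.censored,
        log_activity=log_act,
        mean_orientation=float(np.nanmean(ori)) if np.any(~np.isnan(ori)) else float("nan"),
        orientation=series,
        feeding_mask=mask,
    )
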