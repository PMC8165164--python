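"""Synthetic arena-foraging sessions with known ground truth.

The generator emulates the mirror-exposure foraging design: a bird is
placed at the entrance, dwells, walks a curved path to the feeder in the
far corner, then alternates feeding bouts (head inside the feeder zone)
with excursions around the compartment.  Two processes are deliberately
decoupled:

* the **locomotion** process (body-center path): entrance dwell, an
  approach with Ornstein-Uhlenbeck heading noise, exponential-duration
  feeding bouts, and reflecting-random-walk excursions;
* the **body-axis** process (heading that places the head a fixed offset
  from the body-center): after the approach it is the bearing to the
  feeder plus a stationary OU angular offset whose standard deviation s
  is chosen so that E[cos(offset)] = exp(-s^2/2) equals the configured
  per-condition orientation bias.  The time-mean body-orientation index
  of the clean path is therefore known by construction.

Tracker degradation is applied last: iid Gaussian jitter on every
coordinate, and dropout frames whose coordinates are corrupted and whose
likelihood falls below 0.5.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import SimConfig
from .errors import ConfigError
from .io import Trajectory, make_trajectory, write_trajectory

__all__ = [
    "GroundTruth",
    "SimulatedSession",
    "EthogramData",
    "simulate_session",
    "simulate_ethogram",
    "write_fixture_set",
]

_CLEAN_LIKELIHOOD = 0.99
_HEADING_RELAX = 0.5  # 1/s, OU relaxation rate of the body-axis offset
_APPROACH_WOBBLE = 0.30  # rad, stationary sd of approach-heading noise
_DWELL_TURN_RATE = 0.8  # rad/sqrt(s), heading diffusion while dwelling


@dataclass
class GroundTruth:
    """Noise-free state of one simulated session (all in cm)."""

    latency_s: float
    feeding_mask: np.ndarray  # bool per frame
    body: np.ndarray  # (n, 2)
    head: np.ndarray  # (n, 2)
    heading: np.ndarray  # rad per frame
    speed_cm_s: float  # locomotion speed drawn for this session
    approach_end_frame: int  # first frame of the post-approach segment


@dataclass
class SimulatedSession:
    bird_id: str
    condition: str
    session: int
    trajectory: Trajectory  # pixel units, with noise/dropouts
    truth: GroundTruth


@dataclass
class EthogramData:
    """Behavior counts for both raters plus interval-level label pairs."""

    counts: pd.DataFrame  # bird_id, condition, session, behavior, count, rater
    labels_a: np.ndarray
    labels_b: np.ndarray


def _bias_to_sd(bias: float) -> tuple[float, float]:
    """Map a target mean cosine to (center, sd) of the angular offset.

    For offset ~ N(center, sd^2), E[cos offset] = cos(center) exp(-sd^2/2);
    center is 0 for positive bias and pi for negative bias.
    """
    if bias > 1 or bias < -1:
        raise ConfigError("orientation_bias must lie in [-1, 1]")
    if bias == 0:
        return 0.0, 4.0  # exp(-8) ~ 3e-4, mean cosine effectively 0
    center = 0.0 if bias > 0 else np.pi
    mag = abs(bias)
    sd = np.sqrt(-2.0 * np.log(mag)) if mag < 1 else 0.0
    return center, sd


def _ou_series(n: int, sd: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary OU samples with stationary sd ``sd`` (zero mean)."""
    if n == 0:
        return np.zeros(0)
    if sd == 0:
        return np.zeros(n)
    phi = np.exp(-_HEADING_RELAX * dt)
    innov = rng.normal(0.0, sd * np.sqrt(1 - phi**2), size=n)
    innov[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], innov)


def _fold(p: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect an unbounded coordinate into [lo, hi] (triangular fold)."""
    span = hi - lo
    q = np.mod(p - lo, 2 * span)
    return lo + span - np.abs(span - q)


def _session_rng(cfg: SimConfig, bird_idx: int, cond_idx: int, session: int):
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(1, bird_idx, cond_idx, session))
    return np.random.default_rng(ss)


def _resolve_bird(cfg: SimConfig, bird) -> tuple[int, str]:
    ids = cfg.bird_ids
    if isinstance(bird, (int, np.integer)):
        if not 0 <= bird < cfg.n_birds:
            raise ConfigError(f"bird index {bird} outside 0..{cfg.n_birds - 1}")
        return int(bird), ids[int(bird)]
    if bird not in ids:
        raise ConfigError(f"unknown bird id {bird!r}")
    return ids.index(bird), bird


def simulate_session(cfg: SimConfig, bird, condition: str, session: int) -> SimulatedSession:
    """Simulate one session; deterministic given (cfg.seed, bird, condition, session)."""
    if condition not in cfg.conditions:
        raise ConfigError(
            f"unknown condition {condition!r}; configured: {list(cfg.conditions)}"
        )
    if not 1 <= session <= cfg.n_sessions:
        raise ConfigError(f"session {session} outside 1..{cfg.n_sessions}")
    bird_idx, bird_id = _resolve_bird(cfg, bird)
    cond_idx = cfg.conditions.index(condition)
    rng = _session_rng(cfg, bird_idx, cond_idx, session)

    dt = 1.0 / cfg.fps
    n_frames = cfg.n_frames
    geom = cfg.arena
    feeder = np.asarray(geom.feeder_center, dtype=float)
    entrance = np.asarray(geom.entrance, dtype=float)

    # feeding spot: body-center rests just off the feeder center so the
    # head (head_offset away) can never leave the feeder zone mid-bout
    margin = max(geom.feeder_zone_radius - cfg.head_offset - 0.1, 0.2)
    to_entrance = entrance - feeder
    feed_pt = feeder + margin * to_entrance / np.linalg.norm(to_entrance)

    shape = cfg.latency_shape
    lat_mean = cfg.latency_mean[condition][session - 1]
    latency_target = rng.gamma(shape, lat_mean / shape)
    speed = rng.gamma(25.0, cfg.approach_speed_mean[condition] / 25.0)

    # --- approach path (loop; a few hundred frames) -----------------------
    approach_body = []
    approach_move = []
    pos = entrance.copy()
    wobble = 0.0
    phi = np.exp(-_HEADING_RELAX * dt)
    innov_sd = _APPROACH_WOBBLE * np.sqrt(1 - phi**2)
    step = speed * dt
    for _ in range(4 * n_frames):  # hard cap; approach is ~distance/speed
        delta = feed_pt - pos
        dist = np.linalg.norm(delta)
        if dist <= step:
            break
        bearing = np.arctan2(delta[1], delta[0])
        wobble = phi * wobble + rng.normal(0.0, innov_sd)
        ang = bearing + wobble
        pos = pos + step * np.array([np.cos(ang), np.sin(ang)])
        pos[0] = np.clip(pos[0], 0.0, geom.width)
        pos[1] = np.clip(pos[1], 0.0, geom.depth)
        approach_body.append(pos.copy())
        approach_move.append(ang)
    approach_body.append(feed_pt.copy())
    approach_move.append(approach_move[-1] if approach_move else 0.0)
    approach_body = np.asarray(approach_body)
    approach_move = np.asarray(approach_move)
    n_app = len(approach_body)

    # first head-in-zone frame within the approach determines how much
    # entrance dwell is needed to hit the drawn latency
    app_head = approach_body + cfg.head_offset * np.column_stack(
        [np.cos(approach_move), np.sin(approach_move)]
    )
    in_zone = np.linalg.norm(app_head - feeder, axis=1) <= geom.feeder_zone_radius
    entry_idx = int(np.argmax(in_zone)) if in_zone.any() else n_app - 1
    entry_offset_s = entry_idx * dt
    n_dwell = max(0, int(round((latency_target - entry_offset_s) * cfg.fps)))
    n_dwell = min(n_dwell, n_frames)

    # --- dwell segment ----------------------------------------------------
    dwell_body = np.tile(entrance, (n_dwell, 1))
    dwell_heading = rng.uniform(0, 2 * np.pi) + np.cumsum(
        rng.normal(0.0, _DWELL_TURN_RATE * np.sqrt(dt), size=n_dwell)
    )

    # --- post-arrival schedule -------------------------------------------
    n_app_used = min(n_app, n_frames - n_dwell)
    n_post = n_frames - n_dwell - n_app_used
    post_body = np.empty((n_post, 2))
    cycle_s = 60.0 / cfg.feeding_bout_rate if cfg.feeding_bout_rate > 0 else np.inf
    exc_mean = max(cycle_s - cfg.feeding_bout_length, 3.0)
    i = 0
    while i < n_post:
        # feeding bout: body parked at the feeding spot
        dur = max(int(round(rng.exponential(cfg.feeding_bout_length) * cfg.fps)), int(cfg.fps))
        dur = min(dur, n_post - i)
        post_body[i : i + dur] = feed_pt
        i += dur
        if i >= n_post or not np.isfinite(cycle_s):
            if not np.isfinite(cycle_s):
                post_body[i:] = feed_pt
                i = n_post
            continue
        # excursion: random-walk out, straight return
        dur_out = max(int(round(rng.exponential(exc_mean / 2) * cfg.fps)), int(cfg.fps))
        dur_out = min(dur_out, n_post - i)
        move = rng.uniform(0, 2 * np.pi) + np.cumsum(
            rng.normal(0.0, 1.2 * np.sqrt(dt), size=dur_out)
        )
        steps = speed * dt * np.column_stack([np.cos(move), np.sin(move)])
        raw = feed_pt + np.cumsum(steps, axis=0)
        out = np.column_stack(
            [_fold(raw[:, 0], 0.0, geom.width), _fold(raw[:, 1], 0.0, geom.depth)]
        )
        post_body[i : i + dur_out] = out
        i += dur_out
        if i >= n_post:
            break
        # straight return to the feeding spot at walking speed
        back = feed_pt - out[-1]
        n_ret = max(int(np.ceil(np.linalg.norm(back) / (speed * dt))), 1)
        n_ret_used = min(n_ret, n_post - i)
        frac = np.arange(1, n_ret_used + 1) / n_ret
        post_body[i : i + n_ret_used] = out[-1] + frac[:, None] * back
        i += n_ret_used

    body = np.concatenate([dwell_body, approach_body[:n_app_used], post_body])

    # --- body-axis heading ------------------------------------------------
    center, sd = _bias_to_sd(cfg.orientation_bias[condition])
    bias_offset = center + _ou_series(n_app_used + n_post, sd, dt, rng)
    post_start = n_dwell + n_app_used
    heading = np.empty(n_frames)
    heading[:n_dwell] = dwell_heading
    heading[n_dwell:post_start] = approach_move[:n_app_used]
    delta = feeder - body[post_start:]
    bearing_post = np.arctan2(delta[:, 1], delta[:, 0])
    heading[post_start:] = bearing_post + bias_offset[n_app_used:]

    head = body + cfg.head_offset * np.column_stack([np.cos(heading), np.sin(heading)])

    feeding_mask = np.linalg.norm(head - feeder, axis=1) <= geom.feeder_zone_radius
    latency_s = float(np.argmax(feeding_mask)) / cfg.fps if feeding_mask.any() else np.nan

    truth = GroundTruth(
        latency_s=latency_s,
        feeding_mask=feeding_mask,
        body=body,
        head=head,
        heading=heading,
        speed_cm_s=float(speed),
        approach_end_frame=post_start,
    )

    # --- tracker degradation and pixel conversion ------------------------
    noisy = {}
    lk = {}
    dropout = rng.random(n_frames) < cfg.dropout_prob
    for name, clean in (("head", head), ("body-center", body)):
        xy = clean + rng.normal(0.0, cfg.tracker_noise_sd, size=clean.shape)
        corrupt = np.column_stack(
            [
                rng.uniform(0.0, geom.width, size=n_frames),
                rng.uniform(0.0, geom.depth, size=n_frames),
            ]
        )
        xy = np.where(dropout[:, None], corrupt, xy)
        noisy[name] = xy * geom.px_per_cm
        like = np.full(n_frames, _CLEAN_LIKELIHOOD)
        like[dropout] = rng.uniform(0.0, 0.5, size=int(dropout.sum()))
        lk[name] = like

    traj = make_trajectory(noisy, lk, fps=cfg.fps, units="px")
    return SimulatedSession(bird_id, condition, session, traj, truth)


# --------------------------------------------------------------------------
# ethogram simulation
# --------------------------------------------------------------------------

_JUDGMENT_INTERVAL_S = 5.0
_NONE_LABEL = "none"


def simulate_ethogram(cfg: SimConfig) -> EthogramData:
    """Draw overdispersed behavior counts and dual-rater interval labels.

    Counts are negative-binomial with the configured per-condition mean and
    variance/mean ratio (``overdispersion``; 1 reduces to Poisson).  The
    second rater re-judges each 5-s interval label, flipping it to a random
    label with probability ``rater_disagreement``, which makes the expected
    inter-rater kappa controllable.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))
    behaviors = list(cfg.behavior_rates)
    alphabet = behaviors + [_NONE_LABEL]
    n_int = max(int(cfg.session_length / _JUDGMENT_INTERVAL_S), 1)

    rows = []
    seq_a, seq_b = [], []
    for bird_id in cfg.bird_ids:
        for condition in cfg.conditions:
            for session in range(1, cfg.n_sessions + 1):
                labels = np.full(n_int, _NONE_LABEL, dtype=object)
                free = list(range(n_int))
                rng.shuffle(free)
                for behavior in behaviors:
                    m = cfg.behavior_rates[behavior][condition]
                    count = _draw_count(rng, m, cfg.overdispersion)
                    rows.append(
                        (bird_id, condition, session, behavior, count, "R1")
                    )
                    take = min(count, len(free))
                    for _ in range(take):
                        labels[free.pop()] = behavior
                flips = rng.random(n_int) < cfg.rater_disagreement
                other = rng.choice(alphabet, size=n_int)
                labels_b = np.where(flips, other, labels)
                for behavior in behaviors:
                    rows.append(
                        (
                            bird_id,
                            condition,
                            session,
                            behavior,
                            int(np.sum(labels_b == behavior)),
                            "R2",
                        )
                    )
                seq_a.append(labels)
                seq_b.append(labels_b)

    counts = pd.DataFrame(
        rows, columns=["bird_id", "condition", "session", "behavior", "count", "rater"]
    )
    return EthogramData(
        counts=counts,
        labels_a=np.concatenate(seq_a),
        labels_b=np.concatenate(seq_b),
    )


def _draw_count(rng: np.random.Generator, mean: float, overdispersion: float) -> int:
    if mean < 0:
        raise ConfigError("behavior rate must be >= 0")
    if mean == 0:
        return 0
    if overdispersion <= 1.0:
        return int(rng.poisson(mean))
    r = mean / (overdispersion - 1.0)
    p = 1.0 / overdispersion
    return int(rng.negative_binomial(r, p))


# --------------------------------------------------------------------------
# fixture writer
# --------------------------------------------------------------------------


def write_fixture_set(cfg: SimConfig, out_dir) -> pd.DataFrame:
    """Write the full fixture set: trajectory CSVs, manifest, ethogram, truth.

    Emits one pose CSV per bird x condition x session under
    ``out_dir/trajectories/``, plus ``manifest.csv``, ``ethogram.csv`` and
    ``truth.csv`` (ground-truth latencies).  Returns the manifest frame.
    """
    out_dir = Path(out_dir)
    traj_dir = out_dir / "trajectories"
    try:
        traj_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {traj_dir}: {exc}") from exc

    manifest_rows = []
    truth_rows = []
    for bird_id in cfg.bird_ids:
        for condition in cfg.conditions:
            for session in range(1, cfg.n_sessions + 1):
                sim = simulate_session(cfg, bird_id, condition, session)
                fname = f"{bird_id}_{condition}_s{session}.csv"
                path = traj_dir / fname
                try:
                    write_trajectory(sim.trajectory, path)
                except OSError as exc:
                    raise OSError(f"failed writing {path}: {exc}") from exc
                manifest_rows.append(
                    (bird_id, condition, session, str(Path("trajectories") / fname), cfg.fps)
                )
                truth_rows.append(
                    (bird_id, condition, session, sim.truth.latency_s, sim.truth.speed_cm_s)
                )

    manifest = pd.DataFrame(
        manifest_rows, columns=["bird_id", "condition", "session", "path", "fps"]
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    truth = pd.DataFrame(
        truth_rows,
        columns=["bird_id", "condition", "session", "true_latency_s", "speed_cm_s"],
    )
    truth.to_csv(out_dir / "truth.csv", index=False, float_format="%.4f")
    simulate_ethogram(cfg).counts.to_csv(out_dir / "ethogram.csv", index=False)
    return manifest


def fixture_checksums(out_dir) -> dict[str, str]:
    """SHA-256 of every CSV in a fixture set (for determinism checks)."""
    out_dir = Path(out_dir)
    sums = {}
    for path in sorted(out_dir.rglob("*.csv")):
        sums[str(path.relative_to(out_dir))] = hashlib.sha256(
            path.read_bytes()
        ).hexdigest()
    return sums
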