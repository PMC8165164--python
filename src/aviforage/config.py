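"""Configuration objects: arena geometry, simulation design, pipeline run config.

All geometry is expressed in centimetres in a right-handed frame whose
origin is the arena corner next to the entrance; y increases toward the
separation panel (wall / Plexiglas / mirror).  Trajectory files are in
pixels; ``px_per_cm`` converts between the two.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError

#: canonical condition labels for the mirror-exposure foraging design
CONDITIONS = ("Wall", "Mirror", "Stranger")

#: ethogram behaviors scored per session
BEHAVIORS = (
    "shaking",
    "preening",
    "head scratching",
    "wing flapping/opening",
    "pecking barrier",
    "attack",
)

#: self-directed maintenance behaviors (displacement-behavior group)
BODY_ORIENTED = ("shaking", "preening", "head scratching", "wing flapping/opening")
#: behaviors directed at the separation barrier
SURROUNDING_ORIENTED = ("pecking barrier", "attack")


@dataclass(frozen=True)
class ArenaGeometry:
    """One compartment of the two-chamber foraging box.

    The compartment is 60 cm wide (x) by 50 cm deep (y); the feeder bowl
    sits in front of the separation panel in the corner opposite the
    entrance.  ``feeder_zone_radius`` is the head-proximity radius that
    defines a feeding episode.
    """

    width: float = 60.0
    depth: float = 50.0
    feeder_center: tuple[float, float] = (54.0, 46.0)
    entrance: tuple[float, float] = (6.0, 5.0)
    px_per_cm: float = 10.0
    feeder_zone_radius: float = 8.0

    def __post_init__(self):
        if self.width <= 0 or self.depth <= 0:
            raise ConfigError("arena dimensions must be positive")
        if self.px_per_cm <= 0:
            raise ConfigError("px_per_cm must be > 0")
        if self.feeder_zone_radius <= 0:
            raise ConfigError("feeder_zone_radius must be > 0")
        fx, fy = self.feeder_center
        if not (0 <= fx <= self.width and 0 <= fy <= self.depth):
            raise ConfigError("feeder_center must lie inside the compartment")


def _per_condition(values: Mapping[str, float], conditions) -> dict[str, float]:
    missing = [c for c in conditions if c not in values]
    if missing:
        raise ConfigError(f"missing per-condition values for {missing}")
    return {c: float(values[c]) for c in conditions}


# Session-mean latencies (s).  Approach latency drops steeply over the six
# sessions as birds habituate; the mirror image initially causes marked
# hesitation, most visible in session 1.
_DEFAULT_LATENCY = {
    "Wall": (40.0, 25.0, 18.0, 15.0, 13.0, 12.0),
    "Mirror": (80.0, 45.0, 28.0, 20.0, 16.0, 14.0),
    "Stranger": (55.0, 30.0, 20.0, 16.0, 13.0, 12.0),
}

# Locomotion speed (cm/s): a stranger behind the Plexiglas evokes
# competitive foraging and higher activity; the mirror slightly dampens it.
_DEFAULT_SPEED = {"Wall": 9.0, "Mirror": 8.0, "Stranger": 11.0}

# Target time-mean body-orientation index per condition, ordered
# Wall < Mirror < Stranger (feeder/partner-directed orientation rises when
# another bird, real or reflected, is visible).
_DEFAULT_ORIENT = {"Wall": 0.30, "Mirror": 0.46, "Stranger": 0.62}

# Mean manually-scored behavior counts per 10-min session.
_DEFAULT_BEHAVIOR_RATES = {
    "shaking": {"Wall": 3.90, "Mirror": 3.81, "Stranger": 4.75},
    "preening": {"Wall": 5.12, "Mirror": 5.19, "Stranger": 7.48},
    "head scratching": {"Wall": 0.21, "Mirror": 0.08, "Stranger": 0.25},
    "wing flapping/opening": {"Wall": 0.29, "Mirror": 0.35, "Stranger": 0.125},
    "pecking barrier": {"Wall": 0.0, "Mirror": 0.19, "Stranger": 0.44},
    "attack": {"Wall": 0.0, "Mirror": 0.25, "Stranger": 0.21},
}


@dataclass
class SimConfig:
    """Design and statistical parameters of the synthetic foraging study.

    Defaults reproduce the study design: 8 birds, three conditions
    (Wall / Mirror / Stranger), 6 ten-minute sessions per condition.
    """

    n_birds: int = 8
    conditions: tuple[str, ...] = CONDITIONS
    n_sessions: int = 6
    session_length: float = 600.0  # s
    fps: float = 30.0
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    approach_speed_mean: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SPEED)
    )
    orientation_bias: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ORIENT)
    )
    latency_mean: dict[str, Sequence[float]] = field(
        default_factory=lambda: {c: tuple(v) for c, v in _DEFAULT_LATENCY.items()}
    )
    latency_shape: float = 9.0  # gamma shape of per-session latency draws
    feeding_bout_rate: float = 2.0  # bouts / min
    feeding_bout_length: float = 12.0  # mean bout duration, s
    tracker_noise_sd: float = 0.3  # cm
    dropout_prob: float = 0.02
    behavior_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {b: dict(v) for b, v in _DEFAULT_BEHAVIOR_RATES.items()}
    )
    overdispersion: float = 2.0  # variance/mean of per-session counts
    rater_disagreement: float = 0.05  # per-judgment flip probability, rater 2
    head_offset: float = 5.0  # cm, body-center -> head along the heading
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_birds < 1 or self.n_sessions < 1:
            raise ConfigError("n_birds and n_sessions must be >= 1")
        if not self.conditions:
            raise ConfigError("conditions must be nonempty")
        if self.fps <= 0 or self.session_length <= 0:
            raise ConfigError("fps and session_length must be > 0")
        if self.tracker_noise_sd < 0:
            raise ConfigError("tracker_noise_sd must be >= 0")
        if not (0 <= self.dropout_prob <= 1):
            raise ConfigError("dropout_prob must be in [0, 1]")
        if not (0 <= self.rater_disagreement <= 1):
            raise ConfigError("rater_disagreement must be in [0, 1]")
        if self.feeding_bout_rate < 0 or self.feeding_bout_length <= 0:
            raise ConfigError("feeding bout parameters must be positive")
        if self.overdispersion < 1:
            raise ConfigError("overdispersion must be >= 1 (1 = Poisson)")
        _per_condition(self.approach_speed_mean, self.conditions)
        _per_condition(self.orientation_bias, self.conditions)
        for c in self.conditions:
            if c not in self.latency_mean:
                raise ConfigError(f"latency_mean missing condition {c!r}")
            lat = self.latency_mean[c]
            if len(lat) != self.n_sessions:
                raise ConfigError(
                    f"latency_mean[{c!r}] must list {self.n_sessions} session means"
                )
            if any(v <= 0 for v in lat):
                raise ConfigError("latency means must be > 0")
        for b, rates in self.behavior_rates.items():
            for c in self.conditions:
                if c not in rates:
                    raise ConfigError(f"behavior_rates[{b!r}] missing {c!r}")
                if rates[c] < 0:
                    raise ConfigError(f"behavior_rates[{b!r}][{c!r}] is negative")
        for c, v in self.approach_speed_mean.items():
            if v <= 0:
                raise ConfigError("approach speeds must be > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.session_length * self.fps))

    @property
    def bird_ids(self) -> list[str]:
        return [f"b{i + 1:02d}" for i in range(self.n_birds)]


@dataclass
class Preprocessing:
    """Trajectory preprocessing thresholds."""

    trim_seconds: float = 2.0
    likelihood_threshold: float = 0.6
    max_gap_seconds: float = 0.5
    #: LOESS window expressed in seconds of trajectory; the span fraction
    #: is derived per session (window / duration) so smoothing strength
    #: does not depend on session length or frame rate
    loess_window_seconds: float = 0.3
    #: explicit span fraction override; None = derive from the window
    loess_span: float | None = None
    min_bout_seconds: float = 0.3


@dataclass
class McmcSettings:
    draws: int = 1000
    warmup: int = 1000
    chains: int = 4

    def validate(self):
        if min(self.draws, self.warmup, self.chains) < 1:
            raise ConfigError("mcmc draws/warmup/chains must be >= 1")


@dataclass
class RunConfig:
    """Full pipeline configuration (simulate -> ingest -> model -> stats)."""

    manifest: str = "fixtures/manifest.csv"
    ethogram: str = "fixtures/ethogram.csv"
    out_dir: str = "out"
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    preprocessing: Preprocessing = field(default_factory=Preprocessing)
    bin_width: float = 1.0
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    conditions: tuple[str, ...] = CONDITIONS
    comparisons: tuple[tuple[str, str], ...] = (
        ("Wall", "Mirror"),
        ("Wall", "Stranger"),
        ("Mirror", "Stranger"),
    )
    seed: int = 0
    sim: SimConfig | None = None

    def validate(self) -> None:
        self.mcmc.validate()
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be > 0")
        for ref, alt in self.comparisons:
            for label in (ref, alt):
                if label not in self.conditions:
                    raise ConfigError(
                        f"comparison condition {label!r} not in configured "
                        f"conditions {list(self.conditions)}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        kwargs = dict(raw)
        if "arena" in kwargs:
            kwargs["arena"] = ArenaGeometry(**_tupled(kwargs["arena"]))
        if "preprocessing" in kwargs:
            kwargs["preprocessing"] = Preprocessing(**kwargs["preprocessing"])
        if "mcmc" in kwargs:
            kwargs["mcmc"] = McmcSettings(**kwargs["mcmc"])
        if "conditions" in kwargs:
            kwargs["conditions"] = tuple(kwargs["conditions"])
        if "comparisons" in kwargs:
            kwargs["comparisons"] = tuple(tuple(p) for p in kwargs["comparisons"])
        if "sim" in kwargs and kwargs["sim"] is not None:
            sim_kwargs = dict(kwargs["sim"])
            if "arena" in sim_kwargs:
                sim_kwargs["arena"] = ArenaGeometry(**_tupled(sim_kwargs["arena"]))
            elif "arena" in kwargs:
                sim_kwargs["arena"] = kwargs["arena"]
            if "conditions" in sim_kwargs:
                sim_kwargs["conditions"] = tuple(sim_kwargs["conditions"])
            if "latency_mean" in sim_kwargs:
                sim_kwargs["latency_mean"] = {
                    c: tuple(v) for c, v in sim_kwargs["latency_mean"].items()
                }
            kwargs["sim"] = SimConfig(**sim_kwargs)
        try:
            cfg = cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        """Stable digest of the full configuration (for run manifests)."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _tupled(d: Mapping) -> dict:
    out = dict(d)
    for key in ("feeder_center", "entrance"):
        if key in out:
            out[key] = tuple(out[key])
    return out
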