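"""Reading and validating keypoint trajectory files, manifests and ethograms.

Trajectory files use the common pose-tracker CSV dialect: three header
rows (scorer / bodyparts / coords), then one row per frame with
``x, y, likelihood`` triplets for each bodypart; the first column is the
0-based frame number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ArenaGeometry
from .errors import FormatError, SchemaError

#: bodyparts every analysis needs
REQUIRED_BODYPARTS = ("head", "body-center")

#: default alias table; tracking projects name parts inconsistently
DEFAULT_ALIASES = {
    "center": "body-center",
    "body": "body-center",
    "bodycenter": "body-center",
    "body_center": "body-center",
    "Head": "head",
}

_COORDS = ("x", "y", "likelihood")


@dataclass
class Trajectory:
    """Per-frame keypoint positions and tracker confidences for one session.

    ``data`` has a two-level column index (bodypart, coord) with coords
    ``x, y, likelihood`` and a 0-based frame index; frame numbers are
    preserved under trimming so times stay absolute (``time = frame/fps``).
    ``units`` is ``"px"`` or ``"cm"``.
    """

    data: pd.DataFrame
    fps: float
    units: str = "px"
    extra_bodyparts: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.fps <= 0:
            raise FormatError("fps must be > 0")
        lk = self.data.loc[:, pd.IndexSlice[:, "likelihood"]].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(lk < 0) or np.any(lk > 1):
                raise FormatError("likelihood values must lie in [0, 1]")

    @property
    def bodyparts(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def frames(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def time(self) -> np.ndarray:
        """Seconds since the original session start."""
        return self.frames / self.fps

    def xy(self, bodypart: str) -> np.ndarray:
        """(n, 2) positions of one bodypart."""
        if bodypart not in self.bodyparts:
            raise SchemaError(f"bodypart {bodypart!r} not in trajectory")
        return self.data[bodypart][["x", "y"]].to_numpy(dtype=float)

    def likelihood(self, bodypart: str) -> np.ndarray:
        if bodypart not in self.bodyparts:
            raise SchemaError(f"bodypart {bodypart!r} not in trajectory")
        return self.data[(bodypart, "likelihood")].to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame) -> "Trajectory":
        return replace(self, data=data)


@dataclass
class SessionRecord:
    """One bird x condition x session with its trajectory and derived stats."""

    bird_id: str
    condition: str
    session: int
    trajectory: Trajectory
    stats: object | None = None  # filled by kinematics.session_stats


def make_trajectory(
    arrays: dict[str, np.ndarray],
    likelihoods: dict[str, np.ndarray],
    fps: float,
    units: str = "px",
    frames: np.ndarray | None = None,
) -> Trajectory:
    """Assemble a Trajectory from per-bodypart (n, 2) arrays."""
    cols = {}
    for bp, xy in arrays.items():
        xy = np.asarray(xy, dtype=float)
        cols[(bp, "x")] = xy[:, 0]
        cols[(bp, "y")] = xy[:, 1]
        cols[(bp, "likelihood")] = np.asarray(likelihoods[bp], dtype=float)
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodyparts", "coords"])
    if frames is not None:
        df.index = pd.Index(frames, name="frame")
    return Trajectory(data=df, fps=fps, units=units)


def write_trajectory(traj: Trajectory, path, scorer: str = "synthetic") -> None:
    """Write a trajectory in the three-header-row pose CSV dialect."""
    df = traj.data.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, bp, coord) for bp, coord in df.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    df.to_csv(path, float_format="%.3f")


def read_trajectory(
    path,
    fps: float,
    bodypart_aliases: dict[str, str] | None = None,
) -> Trajectory:
    """Read a pose CSV file, resolving bodypart aliases.

    Unknown bodyparts are retained and listed in ``extra_bodyparts``; a
    missing required bodypart raises :class:`SchemaError`.
    """
    aliases = dict(DEFAULT_ALIASES)
    if bodypart_aliases:
        aliases.update(bodypart_aliases)

    with open(path) as fh:
        header = [fh.readline().rstrip("\n") for _ in range(3)]
    expected = ("scorer", "bodyparts", "coords")
    for i, (line, name) in enumerate(zip(header, expected), start=1):
        first = line.split(",", 1)[0].strip()
        if first != name:
            raise FormatError(
                f"expected header row {i} to start with {name!r}, got {first!r}",
                path=path,
                line=i,
            )

    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    df.columns = df.columns.droplevel(0)  # drop the scorer level
    # resolve aliases on the bodypart level
    renamed = [
        (aliases.get(bp, bp), coord) for bp, coord in df.columns.to_flat_index()
    ]
    df.columns = pd.MultiIndex.from_tuples(renamed, names=["bodyparts", "coords"])

    present = set(df.columns.get_level_values(0))
    for bp in REQUIRED_BODYPARTS:
        triplet = [(bp, c) for c in _COORDS]
        if bp not in present or not all(t in df.columns for t in triplet):
            raise SchemaError(
                f"required bodypart {bp!r} (x, y, likelihood) missing from {path}"
            )
    extras = tuple(sorted(present - set(REQUIRED_BODYPARTS)))
    df.index.name = "frame"
    return Trajectory(data=df, fps=fps, units="px", extra_bodyparts=extras)


def to_arena_coords(traj: Trajectory, geom: ArenaGeometry) -> Trajectory:
    """Convert pixel coordinates to arena centimetres.

    Scaling is linear (x, y divided by ``px_per_cm``); the y axis keeps
    the writer's convention that y increases toward the separation panel.
    """
    if traj.units == "cm":
        return traj
    df = traj.data.copy()
    xy = pd.IndexSlice[:, ["x", "y"]]
    df.loc[:, xy] = df.loc[:, xy] / geom.px_per_cm
    return replace(traj, data=df, units="cm")


def read_manifest(path) -> pd.DataFrame:
    """Session manifest: bird_id, condition, session, path, fps."""
    df = pd.read_csv(path)
    required = {"bird_id", "condition", "session", "path", "fps"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"manifest {path} missing columns {sorted(missing)}")
    return df


def read_ethogram(path) -> pd.DataFrame:
    """Long-format ethogram: bird_id, condition, session, behavior, count, rater."""
    df = pd.read_csv(path)
    required = {"bird_id", "condition", "session", "behavior", "count", "rater"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"ethogram {path} missing columns {sorted(missing)}")
    if (df["count"] < 0).any():
        raise FormatError("ethogram counts must be non-negative", path=path)
    return df
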