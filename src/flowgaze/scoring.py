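"""Moving-AOI gaze scoring.

Scores 60 Hz gaze streams against a circular area of interest (AOI, 9.2 deg
diameter) locked to the moving focus of the radial flow, and against the
whole-screen AOI (AOIW, the 35.3 x 26.4 deg background).  Per-trial measures:

* looking time — total duration of valid samples inside the AOI, each sample
  contributing one nominal sample period (1/60 s);
* latency — time of the first valid in-AOI sample, censored at the 10 s trial
  duration when the AOI is never entered;
* AOIW looking time — same accumulation against the background rectangle;
* asymmetry index — expansion looking time divided by the summed expansion and
  contraction looking times (0.5 = no bias).

The AOI boundary is inclusive (distance <= radius counts as inside); invalid
samples never count as inside anything.  Analytic chance levels for a gaze
fixed at the screen centre follow from the AOI geometry alone: the nearest AOI
edge starts 4.6 deg (134 px) from centre and approaches at 3.68 deg/s
(107.2 px/s), giving a 1.25 s chance latency, a 2.5 s centre-crossing time,
and a 5 s chance looking time over the out-and-back sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stimulus import PX_PER_DEG, FocusTrajectory, focus_position, trajectory_for_path

__all__ = [
    "GazeStream",
    "AoiSpec",
    "TrialScore",
    "ChanceLevels",
    "NOMINAL_RATE_HZ",
    "FIELD_DEG",
    "in_aoi",
    "looking_time",
    "latency",
    "looking_time_whole",
    "asymmetry_index",
    "chance_levels",
    "score_trial",
    "score_dataset",
    "condition_means",
    "center_fixed_stream",
]

NOMINAL_RATE_HZ = 60.0
FIELD_DEG = (35.3, 26.4)
TRIAL_DURATION_S = 10.0


@dataclass
class GazeStream:
    """One trial's gaze samples: times (s from onset), positions (deg, centred
    coordinates) and per-sample validity.  Invalid samples carry undefined
    coordinates (NaN) and never count as in-AOI."""

    trial_id: str
    t: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray
    participant_id: str = ""
    age_group: str = ""
    direction: str = ""
    speed: str = ""
    path: str = ""
    nominal_rate_hz: float = NOMINAL_RATE_HZ

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x_deg) == len(self.y_deg) == len(self.valid) == n):
            raise ValueError("sample arrays must have equal length")
        if n and (np.any(np.diff(self.t) <= 0)):
            raise ValueError("timestamps must be strictly increasing")
        if n and (self.t[0] < 0 or self.t[-1] > TRIAL_DURATION_S):
            raise ValueError(f"timestamps must lie in [0, {TRIAL_DURATION_S}]")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def sample_dt(self) -> float:
        return 1.0 / self.nominal_rate_hz


@dataclass(frozen=True)
class AoiSpec:
    """Circular AOI locked to the focus trajectory."""

    trajectory: FocusTrajectory
    diameter_deg: float = 9.2

    @property
    def radius_deg(self) -> float:
        return self.diameter_deg / 2.0

    @classmethod
    def for_path(cls, path: str, diameter_deg: float = 9.2) -> "AoiSpec":
        return cls(trajectory=trajectory_for_path(path), diameter_deg=diameter_deg)


@dataclass(frozen=True)
class TrialScore:
    """Per-trial dependent measures with condition labels."""

    participant_id: str
    age_group: str
    trial_id: str
    direction: str
    speed: str
    path: str
    looking_time_aoi_s: float
    latency_aoi_s: float
    looking_time_aoiw_s: float


@dataclass(frozen=True)
class ChanceLevels:
    """Analytic chance levels for a centre-fixed gaze."""

    chance_latency_s: float
    aoi_crossing_time_s: float
    chance_looking_time_s: float


def in_aoi(x_deg, y_deg, t, aoi: AoiSpec) -> np.ndarray:
    """True where the gaze position lies within the AOI at each time.

    Boundary inclusive: distance exactly equal to the radius counts as inside.
    NaN coordinates compare False.
    """
    fx, fy = focus_position(aoi.trajectory, np.asarray(t, dtype=float))
    dx = np.asarray(x_deg, dtype=float) - fx
    dy = np.asarray(y_deg, dtype=float) - fy
    with np.errstate(invalid="ignore"):
        return np.hypot(dx, dy) <= aoi.radius_deg


def _valid_in_aoi(stream: GazeStream, aoi: AoiSpec) -> np.ndarray:
    if len(stream) == 0:
        return np.zeros(0, dtype=bool)
    inside = np.zeros(len(stream), dtype=bool)
    v = stream.valid
    if v.any():
        inside[v] = in_aoi(stream.x_deg[v], stream.y_deg[v], stream.t[v], aoi)
    return inside


def looking_time(stream: GazeStream, aoi: AoiSpec) -> float:
    """Total AOI looking time: 1/60 s per valid in-AOI sample, clamped to the
    trial duration.  An empty stream scores 0."""
    hits = _valid_in_aoi(stream, aoi)
    return float(np.clip(hits.sum() * stream.sample_dt, 0.0, TRIAL_DURATION_S))


def latency(stream: GazeStream, aoi: AoiSpec) -> float:
    """Time of the first valid in-AOI sample; censored at 10 s if the AOI is
    never entered (including entirely invalid or empty streams)."""
    hits = _valid_in_aoi(stream, aoi)
    idx = np.flatnonzero(hits)
    if idx.size == 0:
        return TRIAL_DURATION_S
    return float(stream.t[idx[0]])


def looking_time_whole(stream: GazeStream, field_deg: tuple[float, float] = FIELD_DEG) -> float:
    """Looking time against the whole-background AOIW rectangle."""
    if len(stream) == 0:
        return 0.0
    half_w, half_h = field_deg[0] / 2.0, field_deg[1] / 2.0
    with np.errstate(invalid="ignore"):
        inside = (
            stream.valid
            & (np.abs(stream.x_deg) <= half_w)
            & (np.abs(stream.y_deg) <= half_h)
        )
    return float(np.clip(inside.sum() * stream.sample_dt, 0.0, TRIAL_DURATION_S))


def asymmetry_index(total_expansion_s: float, total_contraction_s: float) -> float:
    """Expansion looking time over summed expansion+contraction looking time.

    0.5 = no bias, > 0.5 expansion bias, < 0.5 contraction bias.  Returns NaN
    (undefined; the participant is excluded from index tests) when both totals
    are zero.
    """
    if total_expansion_s < 0 or total_contraction_s < 0:
        raise ValueError("looking times must be non-negative")
    total = total_expansion_s + total_contraction_s
    if total == 0:
        return float("nan")
    return total_expansion_s / total


def chance_levels(aoi: AoiSpec, px_per_deg: float = PX_PER_DEG) -> ChanceLevels:
    """Analytic chance looking time and latency for a centre-fixed gaze.

    Latency: time for the nearest AOI edge (|start offset| - radius from the
    centre) to reach the screen centre at the sweep speed.  Crossing: time for
    the full AOI diameter to pass over the centre.  Chance looking time:
    two crossings (outbound and return legs of the sweep).
    """
    v = aoi.trajectory.sweep_speed_deg_s
    if v <= 0:
        raise ValueError("trajectory sweep speed must be positive")
    edge_px = (abs(aoi.trajectory.start_offset_deg) - aoi.radius_deg) * px_per_deg
    speed_px = v * px_per_deg
    diameter_px = aoi.diameter_deg * px_per_deg
    crossing = diameter_px / speed_px
    return ChanceLevels(
        chance_latency_s=edge_px / speed_px,
        aoi_crossing_time_s=crossing,
        chance_looking_time_s=2.0 * crossing,
    )


def center_fixed_stream(
    trial_id: str = "center",
    duration_s: float = TRIAL_DURATION_S,
    rate_hz: float = NOMINAL_RATE_HZ,
) -> GazeStream:
    """A synthetic stream with every sample fixed exactly at the screen centre
    (the construction behind the analytic chance levels)."""
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    zeros = np.zeros(n)
    return GazeStream(
        trial_id=trial_id, t=t, x_deg=zeros, y_deg=zeros.copy(), valid=np.ones(n, bool)
    )


def score_trial(
    stream: GazeStream,
    aoi: AoiSpec | None = None,
    field_deg: tuple[float, float] = FIELD_DEG,
) -> TrialScore:
    """Score one trial.  The AOI defaults to the one implied by the stream's
    path label."""
    if aoi is None:
        aoi = AoiSpec.for_path(stream.path)
    return TrialScore(
        participant_id=stream.participant_id,
        age_group=stream.age_group,
        trial_id=stream.trial_id,
        direction=stream.direction,
        speed=stream.speed,
        path=stream.path,
        looking_time_aoi_s=looking_time(stream, aoi),
        latency_aoi_s=latency(stream, aoi),
        looking_time_aoiw_s=looking_time_whole(stream, field_deg),
    )


def score_dataset(streams: Iterable[GazeStream]) -> pd.DataFrame:
    """Score every trial; one row per stream.

    Raises on duplicate (participant, direction, speed, path) experimental
    trials — each condition x path combination occurs once per participant.
    """
    rows = [score_trial(s).__dict__ for s in streams]
    scores = pd.DataFrame(rows)
    if scores.empty:
        return scores
    exp = scores[scores["direction"].isin(["expansion", "contraction"])]
    dup = exp.duplicated(subset=["participant_id", "direction", "speed", "path"])
    if dup.any():
        bad = exp.loc[dup, ["participant_id", "direction", "speed", "path"]]
        raise ValueError(f"duplicate experimental trials:\n{bad.to_string(index=False)}")
    return scores


def condition_means(scores: pd.DataFrame) -> pd.DataFrame:
    """Average the two repetitions (motion paths) of each condition.

    Returns one row per participant x direction x speed with the mean looking
    time, latency and AOIW time — four condition means per participant per
    measure, the dependent-variable table for the group-level ANOVAs.
    """
    exp = scores[scores["direction"].isin(["expansion", "contraction"])]
    return (
        exp.groupby(["participant_id", "age_group", "direction", "speed"], as_index=False)[
            ["looking_time_aoi_s", "latency_aoi_s", "looking_time_aoiw_s"]
        ]
        .mean()
    )
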