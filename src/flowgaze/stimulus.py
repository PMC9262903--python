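"""Radial optic-flow stimulus simulation.

Generates the dot-motion movies used in the gaze experiment as frame sets of
dot coordinates: an expansion flow whose focus (the point of zero dot speed)
sweeps horizontally across the screen, the matching contraction flow obtained
by frame reversal, and a benchmark movie of a single square following the
same trajectory.

Kinematics: every dot moves radially away from the instantaneous focus with
speed ``k * eccentricity`` (deg/s), where ``k`` is 0.33 (low speed) or 0.66
(high speed) and eccentricity is the Euclidean distance from the focus in
degrees.  Dots live for a fixed number of frames and respawn uniformly on the
background when they expire or leave the field.  Contraction is produced only
by playing the expansion frame set in reverse order, so expansion and
contraction movies contain bit-identical frames.

Coordinates are degrees of visual angle with the origin at screen centre,
x rightward and y upward; :func:`deg_to_px` converts to the raster convention
(origin top-left, y downward) using a single fixed pixels-per-degree constant.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "PX_PER_DEG",
    "StimulusParams",
    "FocusTrajectory",
    "FrameSet",
    "Dots",
    "focus_position",
    "trajectory_for_path",
    "init_dots",
    "step_dots",
    "generate_expansion_frames",
    "make_contraction",
    "make_benchmark",
    "deg_to_px",
    "mean_dot_speed",
    "frames_to_csv",
    "trajectory_to_csv",
]

#: Pixels per degree of visual angle: the 9.2 deg AOI diameter corresponds to
#: 268 px on the 1024x768 monitor.  All deg<->px conversions use this constant.
PX_PER_DEG = 268.0 / 9.2

_DIRECTIONS = ("expansion", "contraction", "benchmark")
_SIDES = ("left", "right")


@dataclass(frozen=True)
class StimulusParams:
    """Full parameterization of one flow movie."""

    screen_px: tuple[int, int] = (1024, 768)
    field_deg: tuple[float, float] = (35.3, 26.4)
    px_per_deg: float = PX_PER_DEG
    n_dots: int = 500
    speed_constant: float = 0.33  # deg/s of dot speed per deg of eccentricity
    dot_lifetime_frames: int = 10
    movie_fps: int = 30
    movie_duration_s: float = 10.0
    focus_start_side: str = "right"
    focus_speed_deg_s: float = 3.68  # 2 * 9.2 / 5 so the sweep closes exactly
    focus_start_offset_deg: float = 9.2
    aoi_diameter_deg: float = 9.2
    direction: str = "expansion"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.px_per_deg <= 0:
            raise ValueError("px_per_deg must be positive")
        if self.n_dots < 0:
            raise ValueError("n_dots must be non-negative")
        if self.dot_lifetime_frames < 1:
            raise ValueError("dot_lifetime_frames must be >= 1")
        if self.movie_fps <= 0 or self.movie_duration_s <= 0:
            raise ValueError("movie_fps and movie_duration_s must be positive")
        if self.focus_start_side not in _SIDES:
            raise ValueError(f"focus_start_side must be one of {_SIDES}")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")

    @property
    def n_frames(self) -> int:
        return int(round(self.movie_fps * self.movie_duration_s))

    @property
    def frame_dt(self) -> float:
        return 1.0 / self.movie_fps

    @property
    def start_offset_deg(self) -> float:
        """Signed start offset of the focus (+right, -left)."""
        sign = 1.0 if self.focus_start_side == "right" else -1.0
        return sign * self.focus_start_offset_deg

    def trajectory(self) -> "FocusTrajectory":
        return FocusTrajectory(
            start_offset_deg=self.start_offset_deg,
            sweep_speed_deg_s=self.focus_speed_deg_s,
            duration_s=self.movie_duration_s,
        )


@dataclass(frozen=True)
class FocusTrajectory:
    """Horizontal out-and-back sweep of the flow focus.

    The focus starts at the signed offset ``s``, moves at constant speed ``v``
    toward the opposite side, and returns, closing the loop at ``t = T``.
    Vertical offset is zero throughout.
    """

    start_offset_deg: float = 9.2
    sweep_speed_deg_s: float = 3.68
    duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sweep_speed_deg_s < 0:
            raise ValueError("sweep_speed_deg_s must be non-negative")


def focus_position(traj: FocusTrajectory, t):
    """Focus centre ``(x_deg, y_deg)`` at time ``t`` (scalar or array).

    Piecewise linear: outbound for ``t <= T/2``, return leg after.  Raises
    ``ValueError`` for times outside ``[0, T]``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > traj.duration_s):
        raise ValueError(f"t outside [0, {traj.duration_s}]")
    s = traj.start_offset_deg
    v = traj.sweep_speed_deg_s
    half = traj.duration_s / 2.0
    sgn = np.sign(s) if s != 0 else 1.0
    x = np.where(t <= half, s - sgn * v * t, -s + sgn * v * (t - half))
    y = np.zeros_like(x)
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def trajectory_for_path(path: str, params: StimulusParams | None = None) -> FocusTrajectory:
    """Trajectory for a named motion path: ``RLR`` starts right, ``LRL`` left."""
    if params is None:
        params = StimulusParams()
    if path not in ("RLR", "LRL"):
        raise ValueError("path must be 'RLR' or 'LRL'")
    sign = 1.0 if path == "RLR" else -1.0
    return FocusTrajectory(
        start_offset_deg=sign * params.focus_start_offset_deg,
        sweep_speed_deg_s=params.focus_speed_deg_s,
        duration_s=params.movie_duration_s,
    )


class Dots(NamedTuple):
    """Dot field state: positions (n, 2) in degrees and ages in frames."""

    xy: np.ndarray
    age: np.ndarray


@dataclass(frozen=True)
class FrameSet:
    """A movie as data: per-frame dot coordinates plus the focus path."""

    frames: np.ndarray  # (n_frames, n_dots, 2) degrees
    focus_positions: np.ndarray  # (n_frames, 2) degrees
    params: StimulusParams

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.focus_positions):
            raise ValueError("frames and focus_positions length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.params.frame_dt


def _uniform_field(n: int, field_deg: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    half_w, half_h = field_deg[0] / 2.0, field_deg[1] / 2.0
    return rng.uniform([-half_w, -half_h], [half_w, half_h], size=(n, 2))


def init_dots(params: StimulusParams, rng: np.random.Generator) -> Dots:
    """Initial dot field: positions uniform over the background, ages staggered
    uniformly over ``[0, lifetime)`` so respawns are desynchronized."""
    xy = _uniform_field(params.n_dots, params.field_deg, rng)
    age = rng.integers(0, params.dot_lifetime_frames, size=params.n_dots)
    return Dots(xy=xy, age=age)


def step_dots(
    dots: Dots,
    focus: tuple[float, float],
    params: StimulusParams,
    dt: float,
    rng: np.random.Generator,
) -> Dots:
    """Advance the dot field by one frame of expansion kinematics.

    Each dot moves radially away from the instantaneous focus by
    ``k * ecc * dt`` along the focus->dot ray; a dot exactly at the focus has
    zero speed and stays in place.  Ages increment; dots past their lifetime or
    outside the field respawn uniformly with age 0 (evaluated after the motion
    step).
    """
    fx, fy = focus
    # radial step of k*ecc*dt along the unit ray collapses to vec * (k*dt)
    vec = dots.xy - np.array([fx, fy])
    xy = dots.xy + vec * (params.speed_constant * dt)
    age = dots.age + 1

    half_w, half_h = params.field_deg[0] / 2.0, params.field_deg[1] / 2.0
    outside = (np.abs(xy[:, 0]) > half_w) | (np.abs(xy[:, 1]) > half_h)
    expired = age >= params.dot_lifetime_frames
    respawn = outside | expired
    n_new = int(respawn.sum())
    if n_new:
        xy = xy.copy()
        age = age.copy()
        xy[respawn] = _uniform_field(n_new, params.field_deg, rng)
        age[respawn] = 0
    return Dots(xy=xy, age=age)


def generate_expansion_frames(
    params: StimulusParams, rng: np.random.Generator | None = None
) -> FrameSet:
    """Generate the full expansion movie as a :class:`FrameSet`.

    Frame ``i`` is the dot field at time ``i / fps``; forward Euler with the
    focus evaluated at the start of each step, so the radial pattern tracks the
    moving focus.
    """
    if params.direction != "expansion":
        raise ValueError("generate_expansion_frames requires direction='expansion'")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    traj = params.trajectory()
    n = params.n_frames
    times = np.arange(n) * params.frame_dt
    fx, fy = focus_position(traj, times)
    focus_xy = np.column_stack([fx, fy])

    frames = np.empty((n, params.n_dots, 2))
    dots = init_dots(params, rng)
    for i in range(n):
        frames[i] = dots.xy
        if i < n - 1:
            dots = step_dots(dots, (focus_xy[i, 0], focus_xy[i, 1]), params, params.frame_dt, rng)
    return FrameSet(frames=frames, focus_positions=focus_xy, params=params)


def make_contraction(frame_set: FrameSet) -> FrameSet:
    """Contraction movie: the expansion frame set played in reverse order.

    Output frame ``i`` equals input frame ``N-1-i`` bit-exactly; the focus
    path is reversed identically.
    """
    if frame_set.params.direction != "expansion":
        raise ValueError("make_contraction expects an expansion frame set")
    return FrameSet(
        frames=frame_set.frames[::-1].copy(),
        focus_positions=frame_set.focus_positions[::-1].copy(),
        params=replace(frame_set.params, direction="contraction"),
    )


#: Benchmark square area in deg^2; the side length is its square root.
BENCHMARK_SQUARE_AREA_DEG2 = 1.9


def make_benchmark(params: StimulusParams) -> FrameSet:
    """Benchmark movie: a single square whose centre follows the focus path."""
    traj = params.trajectory()
    times = np.arange(params.n_frames) * params.frame_dt
    fx, fy = focus_position(traj, times)
    focus_xy = np.column_stack([fx, fy])
    frames = focus_xy[:, None, :].copy()  # one "dot" = the square centre
    return FrameSet(
        frames=frames,
        focus_positions=focus_xy,
        params=replace(params, direction="benchmark", n_dots=1),
    )


def deg_to_px(xy_deg: np.ndarray, params: StimulusParams) -> np.ndarray:
    """Convert centred degree coordinates to raster pixels (origin top-left,
    y downward)."""
    xy_deg = np.asarray(xy_deg, dtype=float)
    w, h = params.screen_px
    px = np.empty_like(xy_deg)
    px[..., 0] = w / 2.0 + xy_deg[..., 0] * params.px_per_deg
    px[..., 1] = h / 2.0 - xy_deg[..., 1] * params.px_per_deg
    return px


def mean_dot_speed(frame_set: FrameSet) -> float:
    """Measured mean instantaneous dot speed (deg/s) over the whole movie.

    Speed of each dot in each frame is ``k * eccentricity`` from that frame's
    focus; the mean is taken over all dots and frames.
    """
    ecc = np.linalg.norm(
        frame_set.frames - frame_set.focus_positions[:, None, :], axis=-1
    )
    return float(np.mean(frame_set.params.speed_constant * ecc))


def _metadata_header(params: StimulusParams) -> str:
    buf = io.StringIO()
    buf.write(f"# direction={params.direction}\n")
    buf.write(f"# speed_constant={params.speed_constant}\n")
    buf.write(f"# n_dots={params.n_dots} lifetime_frames={params.dot_lifetime_frames}\n")
    buf.write(f"# fps={params.movie_fps} duration_s={params.movie_duration_s}\n")
    buf.write(
        f"# field_deg={params.field_deg[0]}x{params.field_deg[1]}"
        f" screen_px={params.screen_px[0]}x{params.screen_px[1]}"
        f" px_per_deg={params.px_per_deg:.6f}\n"
    )
    buf.write(f"# focus_start={params.start_offset_deg} deg, sweep={params.focus_speed_deg_s} deg/s\n")
    buf.write(f"# rng_seed={params.rng_seed}\n")
    return buf.getvalue()


def frames_to_csv(frame_set: FrameSet, path) -> None:
    """Export a frame set as CSV: a ``#`` metadata block then one row per
    (frame, dot) with columns frame_index, dot_id, x_deg, y_deg."""
    with open(path, "w") as fh:
        fh.write(_metadata_header(frame_set.params))
        fh.write("frame_index,dot_id,x_deg,y_deg\n")
        for i, frame in enumerate(frame_set.frames):
            for j, (x, y) in enumerate(frame):
                fh.write(f"{i},{j},{x:.6f},{y:.6f}\n")


def trajectory_to_csv(frame_set: FrameSet, path) -> None:
    """Export the focus trajectory: t_s, focus_x_deg, focus_y_deg."""
    with open(path, "w") as fh:
        fh.write("t_s,focus_x_deg,focus_y_deg\n")
        for t, (x, y) in zip(frame_set.frame_times, frame_set.focus_positions):
            fh.write(f"{t:.6f},{x:.6f},{y:.6f}\n")
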