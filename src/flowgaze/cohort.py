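"""Synthetic gaze-cohort generation.

Stands in for the human data: a full study cohort (13 age groups x 20
participants, 8 experimental trials each — expansion/contraction x low/high
speed x two motion paths — plus two benchmark trials) of 60 Hz gaze streams
with a controllable, age-dependent expansion/contraction bias.

Generative model per trial
--------------------------
The gaze starts near the screen centre; an orienting saccade lands in the
moving AOI at a lognormally distributed latency; thereafter a two-state
Markov chain per sample alternates between an in-AOI state (Gaussian jitter
around the moving AOI centre) and an off-AOI excursion (uniform off-AOI
point), with per-sample leave/return probabilities chosen so the stationary
in-AOI occupancy hits a group x direction x speed target looking time.
Samples drop out (invalid) i.i.d. per sample.  Pre-orienting samples are
off-AOI by construction: the gaze holds near the centre but is displaced to a
random off-AOI point whenever the sweeping AOI covers it, so looking time is
governed entirely by the latency and the dwell chain.

The closed-form stationary occupancy of the chain is
``p_return / (p_leave + p_return)``; expected post-entry looking time is that
occupancy times the time remaining after entry, which is how target looking
times are mapped to transition probabilities.

Participant-level parameters are drawn around the group presets (normal on
the logit scale for occupancy and on the log scale for latency medians),
inducing the between-participant variance picked up by the random-intercept
analysis downstream.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .scoring import FIELD_DEG, NOMINAL_RATE_HZ, TRIAL_DURATION_S, AoiSpec, GazeStream
from .stimulus import focus_position, trajectory_for_path

__all__ = [
    "AGE_GROUPS",
    "CohortDesign",
    "load_presets",
    "occupancy_from_target",
    "stationary_occupancy",
    "sample_participant",
    "simulate_trial",
    "generate_cohort",
    "Cohort",
]

AGE_GROUPS = (
    "1y", "2y", "3y", "4y", "5y", "6y", "7y",
    "8y", "9y", "10y", "11y", "12y", "adult",
)

_DIRECTIONS = ("expansion", "contraction")
_SPEEDS = ("low", "high")
_PATHS = ("RLR", "LRL")


@dataclass(frozen=True)
class CohortDesign:
    """Study design: groups, group size and the per-participant trial set."""

    age_groups: tuple[str, ...] = AGE_GROUPS
    n_per_group: int = 20
    include_benchmark: bool = True
    aoi_diameter_deg: float = 9.2
    rate_hz: float = NOMINAL_RATE_HZ
    duration_s: float = TRIAL_DURATION_S

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if len(set(self.age_groups)) != len(self.age_groups):
            raise ValueError("age_groups must be unique")

    @property
    def n_samples(self) -> int:
        return int(round(self.rate_hz * self.duration_s))

    def experimental_conditions(self) -> list[tuple[str, str, str]]:
        """The eight (direction, speed, path) trials; the two repetitions of
        each condition take the two motion paths."""
        return [
            (d, s, p) for d in _DIRECTIONS for s in _SPEEDS for p in _PATHS
        ]


def load_presets(path=None) -> dict:
    """Load behavior presets (the shipped versioned file by default)."""
    if path is None:
        ref = importlib.resources.files("flowgaze").joinpath("presets.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    presets = yaml.safe_load(text)
    groups = presets["groups"]
    for g, spec in groups.items():
        t = spec["target_looking_s"]
        if not (0 <= t["expansion"] <= TRIAL_DURATION_S and 0 <= t["contraction"] <= TRIAL_DURATION_S):
            raise ValueError(f"target looking times out of [0, 10] for group {g}")
    return presets


def stationary_occupancy(p_leave: float, p_return: float) -> float:
    """Stationary in-AOI occupancy of the two-state per-sample chain."""
    if p_leave + p_return == 0:
        return 1.0  # absorbing in-state
    return p_return / (p_leave + p_return)


def occupancy_from_target(
    target_looking_s: float,
    latency_median_s: float,
    latency_sigma: float,
    duration_s: float = TRIAL_DURATION_S,
) -> float:
    """Map a target mean looking time to the in-AOI occupancy that yields it.

    Expected post-entry looking time is occupancy x (duration - mean latency);
    the lognormal mean is ``median * exp(sigma^2 / 2)``.
    """
    mean_latency = latency_median_s * float(np.exp(latency_sigma**2 / 2.0))
    effective = max(duration_s - min(mean_latency, duration_s), 1e-6)
    return float(np.clip(target_looking_s / effective, 0.02, 0.98))


def sample_participant(
    group: str, presets: Mapping, rng: np.random.Generator
) -> dict:
    """Draw one participant's generative parameters around the group presets.

    Occupancies are jittered on the logit scale per direction x speed, the
    latency median on the log scale.  With zero between-participant variance
    the draws equal the group values exactly.
    """
    g = presets["groups"][group]
    sigma = presets["latency_sigma"]
    bp = presets["between_participant"]
    speed_add = presets.get("speed_effect_s", 0.0)

    lat_median = g["latency_median_s"] * float(
        np.exp(rng.normal(0.0, bp["latency_log_sd"]))
    )
    occ = {}
    for d in _DIRECTIONS:
        for s in _SPEEDS:
            target = g["target_looking_s"][d] + (speed_add if s == "high" else 0.0)
            base = occupancy_from_target(target, g["latency_median_s"], sigma)
            logit = np.log(base / (1.0 - base)) + rng.normal(0.0, bp["occupancy_logit_sd"])
            occ[(d, s)] = float(1.0 / (1.0 + np.exp(-logit)))
    bench = presets["benchmark"]
    return {
        "age_group": group,
        "latency_median_s": lat_median,
        "latency_sigma": sigma,
        "occupancy": occ,
        "state_rate": presets["state_rate_per_sample"],
        "jitter_sd_deg": presets["jitter_sd_deg"],
        "p_invalid": presets["p_invalid"],
        "benchmark_latency_median_s": bench["latency_median_s"],
        "benchmark_latency_sigma": bench["latency_sigma"],
        "benchmark_occupancy": bench["occupancy"],
    }


def _leave_return(occupancy: float, rate: float) -> tuple[float, float]:
    """Split the relaxation rate into leave/return probabilities with the
    requested stationary occupancy."""
    return (1.0 - occupancy) * rate, occupancy * rate


def _simulate_batch(
    p_leave: np.ndarray,
    p_return: np.ndarray,
    latency_s: np.ndarray,
    jitter_sd: np.ndarray,
    p_invalid: np.ndarray,
    path_idx: np.ndarray,
    rng: np.random.Generator,
    design: CohortDesign,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized gaze simulation for a batch of trials.

    Returns (x_deg, y_deg, valid) arrays of shape (n_trials, n_samples).
    State codes: 0 pre-orienting, 1 in-AOI, 2 off-AOI excursion.
    """
    n_tr = len(p_leave)
    n = design.n_samples
    t = np.arange(n) / design.rate_hz
    radius = design.aoi_diameter_deg / 2.0

    # the two possible AOI centre tracks (paths RLR and LRL)
    tracks = np.stack(
        [focus_position(trajectory_for_path(p), t)[0] for p in _PATHS]
    )
    cx = tracks[path_idx]  # (n_tr, n)

    # entry sample: first sample at or after the drawn latency (may be >= n)
    k0 = np.ceil(latency_s * design.rate_hz).astype(int)

    u = rng.random((n_tr, n))
    states = np.empty((n_tr, n), dtype=np.int8)
    cur = np.zeros(n_tr, dtype=np.int8)
    for k in range(n):
        active = cur > 0
        if k > 0 and active.any():
            leave = active & (cur == 1) & (u[:, k] < p_leave)
            ret = active & (cur == 2) & (u[:, k] < p_return)
            cur = np.where(leave, 2, np.where(ret, 1, cur)).astype(np.int8)
        cur = np.where(k0 == k, 1, cur).astype(np.int8)
        states[:, k] = cur

    jitter = rng.normal(0.0, 1.0, size=(n_tr, n, 2)) * jitter_sd[:, None, None]

    x = np.zeros((n_tr, n))
    y = np.zeros((n_tr, n))
    in_mask = states == 1
    x[in_mask] = (cx + jitter[:, :, 0])[in_mask]
    y[in_mask] = jitter[:, :, 1][in_mask]

    pre_mask = states == 0
    x[pre_mask] = jitter[:, :, 0][pre_mask]
    y[pre_mask] = jitter[:, :, 1][pre_mask]

    # displace to an off-AOI point: excursions always, pre samples only while
    # the sweeping AOI covers the held gaze
    need_off = (states == 2) | (pre_mask & (np.hypot(x - cx, y) <= radius))
    half_w, half_h = FIELD_DEG[0] / 2.0, FIELD_DEG[1] / 2.0
    pending = need_off.copy()
    for _ in range(12):
        m = int(pending.sum())
        if m == 0:
            break
        cand = rng.uniform([-half_w, -half_h], [half_w, half_h], size=(m, 2))
        ok = np.hypot(cand[:, 0] - cx[pending], cand[:, 1]) > radius
        idx = np.flatnonzero(pending.ravel())[ok]
        x.ravel()[idx] = cand[ok, 0]
        y.ravel()[idx] = cand[ok, 1]
        rem = np.flatnonzero(pending.ravel())[~ok]
        pending = np.zeros_like(pending).ravel()
        pending[rem] = True
        pending = pending.reshape(need_off.shape)

    valid = rng.random((n_tr, n)) >= p_invalid[:, None]
    x[~valid] = np.nan
    y[~valid] = np.nan
    return x, y, valid


def simulate_trial(
    participant: Mapping,
    condition: tuple[str, str, str],
    rng: np.random.Generator,
    design: CohortDesign | None = None,
) -> GazeStream:
    """Simulate one trial for a participant.  ``condition`` is
    (direction, speed, path); direction 'benchmark' uses the benchmark preset
    (speed label is carried through unchanged)."""
    if design is None:
        design = CohortDesign()
    direction, speed, path = condition
    if direction == "benchmark":
        occ = participant["benchmark_occupancy"]
        lat = rng.lognormal(
            np.log(participant["benchmark_latency_median_s"]),
            participant["benchmark_latency_sigma"],
        )
    else:
        occ = participant["occupancy"][(direction, speed)]
        lat = rng.lognormal(
            np.log(participant["latency_median_s"]), participant["latency_sigma"]
        )
    p_leave, p_return = _leave_return(occ, participant["state_rate"])
    x, y, valid = _simulate_batch(
        np.array([p_leave]),
        np.array([p_return]),
        np.array([lat]),
        np.array([participant["jitter_sd_deg"]]),
        np.array([participant["p_invalid"]]),
        np.array([_PATHS.index(path)]),
        rng,
        design,
    )
    t = np.arange(design.n_samples) / design.rate_hz
    return GazeStream(
        trial_id="trial",
        t=t,
        x_deg=x[0],
        y_deg=y[0],
        valid=valid[0],
        age_group=participant.get("age_group", ""),
        direction=direction,
        speed=speed,
        path=path,
    )


@dataclass
class Cohort:
    """A generated cohort: the trial table plus raw gaze arrays.

    ``trials`` has one row per trial with condition labels and the generating
    per-trial parameters; ``x_deg``/``y_deg``/``valid`` are
    (n_trials, n_samples) arrays.
    """

    trials: pd.DataFrame
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray
    truth: pd.DataFrame
    design: CohortDesign

    @property
    def sample_times(self) -> np.ndarray:
        return np.arange(self.design.n_samples) / self.design.rate_hz

    def to_streams(self) -> list[GazeStream]:
        t = self.sample_times
        out = []
        for i, row in enumerate(self.trials.itertuples()):
            out.append(
                GazeStream(
                    trial_id=row.trial_id,
                    t=t,
                    x_deg=self.x_deg[i],
                    y_deg=self.y_deg[i],
                    valid=self.valid[i],
                    participant_id=row.participant_id,
                    age_group=row.age_group,
                    direction=row.direction,
                    speed=row.speed,
                    path=row.path,
                )
            )
        return out

    def score(self) -> pd.DataFrame:
        """Vectorized trial scoring; equals scoring the individual streams."""
        t = self.sample_times
        radius = self.design.aoi_diameter_deg / 2.0
        tracks = np.stack(
            [focus_position(trajectory_for_path(p), t)[0] for p in _PATHS]
        )
        path_idx = self.trials["path"].map({p: i for i, p in enumerate(_PATHS)}).to_numpy()
        cx = tracks[path_idx]
        with np.errstate(invalid="ignore"):
            inside = (np.hypot(self.x_deg - cx, self.y_deg) <= radius) & self.valid
            half_w, half_h = FIELD_DEG[0] / 2.0, FIELD_DEG[1] / 2.0
            on_screen = (
                (np.abs(self.x_deg) <= half_w)
                & (np.abs(self.y_deg) <= half_h)
                & self.valid
            )
        dt = 1.0 / self.design.rate_hz
        looking = inside.sum(axis=1) * dt
        aoiw = on_screen.sum(axis=1) * dt
        first = np.argmax(inside, axis=1)
        entered = inside.any(axis=1)
        lat = np.where(entered, t[first], self.design.duration_s)
        out = self.trials[
            ["participant_id", "age_group", "trial_id", "direction", "speed", "path"]
        ].copy()
        out["looking_time_aoi_s"] = looking
        out["latency_aoi_s"] = lat
        out["looking_time_aoiw_s"] = aoiw
        return out


def generate_cohort(
    design: CohortDesign | None = None,
    presets: Mapping | None = None,
    rng: np.random.Generator | int | None = None,
) -> Cohort:
    """Generate a full synthetic cohort.

    Returns a :class:`Cohort` whose truth table records the generating
    parameters per participant (for recovery tests).  Trial order is
    randomized per participant; the two benchmark trials follow the
    experimental trials with path order counterbalanced across participants.
    """
    if design is None:
        design = CohortDesign()
    if presets is None:
        presets = load_presets()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    rows = []
    truth_rows = []
    conditions = design.experimental_conditions()
    counter = 0
    for group in design.age_groups:
        for j in range(design.n_per_group):
            pid = f"{group}_p{j:02d}"
            part = sample_participant(group, presets, rng)
            order = rng.permutation(len(conditions))
            trial_list = [conditions[o] for o in order]
            if design.include_benchmark:
                bench_paths = _PATHS if counter % 2 == 0 else _PATHS[::-1]
                trial_list = trial_list + [
                    ("benchmark", "benchmark", p) for p in bench_paths
                ]
            for idx, (d, s, p) in enumerate(trial_list):
                if d == "benchmark":
                    occ = part["benchmark_occupancy"]
                    lat = rng.lognormal(
                        np.log(part["benchmark_latency_median_s"]),
                        part["benchmark_latency_sigma"],
                    )
                else:
                    occ = part["occupancy"][(d, s)]
                    lat = rng.lognormal(
                        np.log(part["latency_median_s"]), part["latency_sigma"]
                    )
                p_leave, p_return = _leave_return(occ, part["state_rate"])
                rows.append(
                    {
                        "participant_id": pid,
                        "age_group": group,
                        "trial_id": f"{pid}_t{idx}",
                        "direction": d,
                        "speed": s,
                        "path": p,
                        "p_leave": p_leave,
                        "p_return": p_return,
                        "latency_draw_s": lat,
                        "jitter_sd_deg": part["jitter_sd_deg"],
                        "p_invalid": part["p_invalid"],
                    }
                )
            truth = {
                "participant_id": pid,
                "age_group": group,
                "latency_median_s": part["latency_median_s"],
            }
            for (d, s), v in part["occupancy"].items():
                truth[f"occupancy_{d}_{s}"] = v
            truth_rows.append(truth)
            counter += 1

    trials = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    path_idx = trials["path"].map({p: i for i, p in enumerate(_PATHS)}).to_numpy()
    x, y, valid = _simulate_batch(
        trials["p_leave"].to_numpy(),
        trials["p_return"].to_numpy(),
        trials["latency_draw_s"].to_numpy(),
        trials["jitter_sd_deg"].to_numpy(),
        trials["p_invalid"].to_numpy(),
        path_idx,
        rng,
        design,
    )
    return Cohort(trials=trials, x_deg=x, y_deg=y, valid=valid, truth=truth, design=design)
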