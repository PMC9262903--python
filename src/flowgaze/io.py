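"""Gaze-file formats, run configuration and the end-to-end pipeline.

The gaze interchange format is a flat TSV, one row per sample::

    participant_id  age_group  trial_id  direction  speed  path  t_s  x_px  y_px  valid

Positions are raster pixels (origin top-left, y downward) converted with the
single fixed pixels-per-degree constant; invalid samples (valid = 0) carry
empty coordinate fields.  The writer emits a canonical dialect (fixed float
formats) so read -> write round-trips are byte-identical.

``run_pipeline`` ties simulate-cohort -> score -> analyze into one seeded,
reproducible run and records a manifest (config echo, seeds, SHA-256
checksums of every stage output).
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import AGE_GROUPS, Cohort, CohortDesign, generate_cohort, load_presets
from .scoring import GazeStream, score_dataset
from .stats import analyze_scores
from .stimulus import PX_PER_DEG, StimulusParams

__all__ = [
    "GAZE_COLUMNS",
    "read_gaze_tsv",
    "write_gaze_tsv",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

GAZE_COLUMNS = [
    "participant_id",
    "age_group",
    "trial_id",
    "direction",
    "speed",
    "path",
    "t_s",
    "x_px",
    "y_px",
    "valid",
]

_SCREEN_PX = (1024, 768)


def _deg_to_px_xy(x_deg, y_deg):
    return (
        _SCREEN_PX[0] / 2.0 + np.asarray(x_deg) * PX_PER_DEG,
        _SCREEN_PX[1] / 2.0 - np.asarray(y_deg) * PX_PER_DEG,
    )


def _px_to_deg_xy(x_px, y_px):
    return (
        (np.asarray(x_px) - _SCREEN_PX[0] / 2.0) / PX_PER_DEG,
        (_SCREEN_PX[1] / 2.0 - np.asarray(y_px)) / PX_PER_DEG,
    )


def write_gaze_tsv(streams, path) -> None:
    """Write gaze streams in the canonical TSV dialect."""
    with open(path, "w") as fh:
        fh.write("\t".join(GAZE_COLUMNS) + "\n")
        for s in streams:
            x_px, y_px = _deg_to_px_xy(s.x_deg, s.y_deg)
            for i in range(len(s)):
                if s.valid[i]:
                    xs, ys, v = f"{x_px[i]:.3f}", f"{y_px[i]:.3f}", "1"
                else:
                    xs, ys, v = "", "", "0"
                fh.write(
                    f"{s.participant_id}\t{s.age_group}\t{s.trial_id}\t{s.direction}\t"
                    f"{s.speed}\t{s.path}\t{s.t[i]:.6f}\t{xs}\t{ys}\t{v}\n"
                )


def read_gaze_tsv(path) -> list[GazeStream]:
    """Read gaze streams from the TSV dialect.

    Malformed input is rejected with the offending line number: missing
    columns, validity flags outside {0, 1}, non-monotone timestamps within a
    trial, and valid samples with missing coordinates.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"participant_id": str, "age_group": str, "trial_id": str},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    # line numbers: header is line 1
    lines = df.index.to_numpy() + 2
    if not df["valid"].isin([0, 1]).all():
        bad = lines[~df["valid"].isin([0, 1])]
        raise ValueError(f"{path}: validity flag not in {{0,1}} at line(s) {bad[:5].tolist()}")
    valid = df["valid"].astype(bool)
    coord_missing = valid & (df["x_px"].isna() | df["y_px"].isna())
    if coord_missing.any():
        raise ValueError(
            f"{path}: valid sample with missing coordinates at line(s) "
            f"{lines[coord_missing][:5].tolist()}"
        )

    streams = []
    for trial_id, sub in df.groupby("trial_id", sort=False):
        dt = np.diff(sub["t_s"].to_numpy())
        if np.any(dt <= 0):
            bad_line = lines[sub.index.to_numpy()[1:][dt <= 0][0] - df.index[0]]
            raise ValueError(
                f"{path}: non-increasing timestamp in trial {trial_id!r} at line {bad_line}"
            )
        x_deg, y_deg = _px_to_deg_xy(sub["x_px"].to_numpy(), sub["y_px"].to_numpy())
        first = sub.iloc[0]
        streams.append(
            GazeStream(
                trial_id=str(trial_id),
                t=sub["t_s"].to_numpy(),
                x_deg=x_deg,
                y_deg=y_deg,
                valid=sub["valid"].to_numpy().astype(bool),
                participant_id=str(first["participant_id"]),
                age_group=str(first["age_group"]),
                direction=str(first["direction"]),
                speed=str(first["speed"]),
                path=str(first["path"]),
            )
        )
    return streams


@dataclass
class RunConfig:
    """Configuration for one end-to-end pipeline run."""

    out_dir: str = "results/run"
    n_per_group: int = 20
    age_groups: tuple[str, ...] = AGE_GROUPS
    include_benchmark: bool = True
    presets_path: str | None = None
    cohort_seed: int = 0
    df_method: str = "exact-strata"
    write_gaze: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if "age_groups" in data:
            cfg.age_groups = tuple(data["age_groups"])
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["age_groups"] = list(self.age_groups)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def design(self) -> CohortDesign:
        return CohortDesign(
            age_groups=tuple(self.age_groups),
            n_per_group=self.n_per_group,
            include_benchmark=self.include_benchmark,
        )


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig | str | pathlib.Path) -> dict:
    """Execute simulate-cohort -> score -> analyze and write a run manifest.

    Every stage output lands under ``config.out_dir``; the manifest records
    the config echo, seed, and a SHA-256 checksum per file, so re-running
    with identical inputs reproduces identical outputs bit for bit.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times = {}
    files: list[pathlib.Path] = []

    try:
        t0 = time.perf_counter()
        presets = load_presets(config.presets_path)
        cohort = generate_cohort(
            design=config.design(), presets=presets, rng=config.cohort_seed
        )
        cohort.truth.to_csv(out / "truth.csv", index=False)
        files.append(out / "truth.csv")
        with open(out / "design.json", "w") as fh:
            json.dump(
                {
                    "age_groups": list(config.age_groups),
                    "n_per_group": config.n_per_group,
                    "n_trials": len(cohort.trials),
                    "cohort_seed": config.cohort_seed,
                },
                fh,
                indent=2,
            )
        files.append(out / "design.json")
        if config.write_gaze:
            write_gaze_tsv(cohort.to_streams(), out / "gaze.tsv")
            files.append(out / "gaze.tsv")
        stage_times["simulate"] = time.perf_counter() - t0
        logger.info("simulate: %d trials in %.2fs", len(cohort.trials), stage_times["simulate"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {exc}") from exc

    try:
        t0 = time.perf_counter()
        scores = cohort.score()
        scores.to_csv(out / "scores.csv", index=False)
        files.append(out / "scores.csv")
        stage_times["score"] = time.perf_counter() - t0
        logger.info("score: %d trials in %.2fs", len(scores), stage_times["score"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'score' failed: {exc}") from exc

    try:
        t0 = time.perf_counter()
        results = analyze_scores(scores, out_dir=out)
        for name in results:
            files.append(out / f"{name}.csv")
        stage_times["analyze"] = time.perf_counter() - t0
        logger.info("analyze: %d tables in %.2fs", len(results), stage_times["analyze"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'analyze' failed: {exc}") from exc

    config_echo = asdict(config)
    config_echo["age_groups"] = list(config.age_groups)
    manifest = {
        "config": config_echo,
        "config_hash": hashlib.sha256(
            json.dumps(config_echo, sort_keys=True).encode()
        ).hexdigest(),
        "seeds": {"cohort": config.cohort_seed},
        "df_method": config.df_method,
        "stage_times_s": stage_times,
        "checksums": {f.name: _sha256(f) for f in files if f.exists()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
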