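"""Generate the four flow movies and the benchmark movie; summarize their
structure and measured dot speeds.

Writes results/stimuli_summary.csv and results/focus_trajectory.csv; the
full per-frame dot coordinate dumps (several MB each) go to scratch/stimuli/.
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from flowgaze.stimulus import (
    StimulusParams,
    frames_to_csv,
    generate_expansion_frames,
    make_benchmark,
    make_contraction,
    mean_dot_speed,
    trajectory_to_csv,
)

SEED = 0
ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "stimuli"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rows = []
    for speed_label, k in [("low", 0.33), ("high", 0.66)]:
        for path, side in [("RLR", "right"), ("LRL", "left")]:
            params = StimulusParams(
                speed_constant=k, focus_start_side=side, rng_seed=SEED
            )
            exp = generate_expansion_frames(params)
            con = make_contraction(exp)
            frames_to_csv(exp, SCRATCH / f"expansion_{speed_label}_{path}.csv")
            for fs, direction in [(exp, "expansion"), (con, "contraction")]:
                rows.append(
                    {
                        "direction": direction,
                        "speed": speed_label,
                        "path": path,
                        "n_frames": fs.n_frames,
                        "n_dots": fs.params.n_dots,
                        "lifetime_ms": round(
                            fs.params.dot_lifetime_frames / fs.params.movie_fps * 1000
                        ),
                        "measured_mean_dot_speed_deg_s": round(mean_dot_speed(fs), 3),
                    }
                )
    bench = make_benchmark(StimulusParams())
    trajectory_to_csv(bench, RESULTS / "focus_trajectory.csv")
    rows.append(
        {
            "direction": "benchmark",
            "speed": "",
            "path": "RLR",
            "n_frames": bench.n_frames,
            "n_dots": 1,
            "lifetime_ms": "",
            "measured_mean_dot_speed_deg_s": "",
        }
    )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "stimuli_summary.csv", index=False)
    print(summary.to_string(index=False))
    low = summary[summary["speed"] == "low"]["measured_mean_dot_speed_deg_s"].iloc[0]
    high = summary[summary["speed"] == "high"]["measured_mean_dot_speed_deg_s"].iloc[0]
    print(
        f"\nMeasured mean dot speeds: {low} (low) / {high} (high) deg/s; "
        f"ratio {high/low:.3f} (the speed rule is linear in the constant k)."
    )
    print(
        "Each movie is 300 frames of 500 dots; contraction frames are the "
        "expansion frames in reverse order."
    )


if __name__ == "__main__":
    main()
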