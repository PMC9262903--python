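"""Seeded replication studies over synthetic cohorts.

Small drivers that repeat generate -> score -> analyze across independent
seeds to measure operating characteristics of the pipeline: sign recovery of
the per-group direction effect, power for the age x direction interaction,
and type-I error on null cohorts (no direction difference anywhere).
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd

from .cohort import CohortDesign, generate_cohort, load_presets
from .scoring import condition_means
from .stats import asymmetry_table, asymmetry_ttests, fit_threeway_lmm, simple_effects_by_age

__all__ = [
    "preset_direction_signs",
    "null_presets",
    "bias_study",
    "null_study",
    "asymmetry_bias_study",
]


def preset_direction_signs(presets) -> dict[str, int]:
    """Generating-truth sign of the expansion - contraction target per group."""
    out = {}
    for g, spec in presets["groups"].items():
        t = spec["target_looking_s"]
        out[g] = int(np.sign(t["expansion"] - t["contraction"]))
    return out


def null_presets(presets) -> dict:
    """Remove every direction difference: both directions get the group's
    mean target, preserving the age trend."""
    null = copy.deepcopy(presets)
    for spec in null["groups"].values():
        t = spec["target_looking_s"]
        m = (t["expansion"] + t["contraction"]) / 2.0
        t["expansion"] = m
        t["contraction"] = m
    return null


def _seeds(base_seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(base_seed).spawn(n)]


def bias_study(
    n_reps: int = 50,
    base_seed: int = 0,
    presets=None,
    design: CohortDesign | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Replicate the cohort under the shipped presets.

    Per replication: whether every age group's direction simple-effect sign
    matches the generating truth, and whether the age x direction interaction
    in the looking-time ANOVA is significant at ``alpha``.
    """
    if presets is None:
        presets = load_presets()
    if design is None:
        design = CohortDesign(include_benchmark=False)
    truth_signs = preset_direction_signs(presets)
    rows = []
    for rep, rng in enumerate(_seeds(base_seed, n_reps)):
        cohort = generate_cohort(design=design, presets=presets, rng=rng)
        means = condition_means(cohort.score())
        anova = fit_threeway_lmm(means, "looking_time_aoi_s")
        simple = simple_effects_by_age(means, "looking_time_aoi_s")
        signs_ok = all(
            int(np.sign(row.estimate)) == truth_signs[row.age_group]
            for row in simple.itertuples()
        )
        p_int = float(anova.loc["age_group:direction", "p"])
        rows.append(
            {
                "rep": rep,
                "all_signs_match": signs_ok,
                "interaction_p": p_int,
                "interaction_significant": p_int < alpha,
            }
        )
    return pd.DataFrame(rows)


def null_study(
    n_reps: int = 200,
    base_seed: int = 1,
    presets=None,
    design: CohortDesign | None = None,
) -> np.ndarray:
    """Age x direction interaction p-values across null-cohort replications."""
    if presets is None:
        presets = load_presets()
    presets = null_presets(presets)
    if design is None:
        design = CohortDesign(include_benchmark=False)
    ps = []
    for rng in _seeds(base_seed, n_reps):
        cohort = generate_cohort(design=design, presets=presets, rng=rng)
        means = condition_means(cohort.score())
        anova = fit_threeway_lmm(means, "looking_time_aoi_s")
        ps.append(float(anova.loc["age_group:direction", "p"]))
    return np.asarray(ps)


def asymmetry_bias_study(
    delta_s: float = 1.5,
    n_reps: int = 100,
    base_seed: int = 2,
    n_participants: int = 20,
) -> pd.DataFrame:
    """One-group replications with a fixed expansion advantage.

    Each replication generates one group of participants whose expansion
    target exceeds the contraction target by ``delta_s`` seconds, computes
    per-participant AOI asymmetry indices, and tests the group mean against
    0.5 (two-tailed one-sample t at 0.05, direction required positive).
    """
    presets = load_presets()
    presets = copy.deepcopy(presets)
    base = presets["groups"]["adult"]["target_looking_s"]
    mid = (base["expansion"] + base["contraction"]) / 2.0
    presets["groups"] = {
        "adult": {
            "latency_median_s": presets["groups"]["adult"]["latency_median_s"],
            "target_looking_s": {
                "expansion": mid + delta_s / 2.0,
                "contraction": mid - delta_s / 2.0,
            },
        }
    }
    design = CohortDesign(
        age_groups=("adult",), n_per_group=n_participants, include_benchmark=False
    )
    rows = []
    for rep, rng in enumerate(_seeds(base_seed, n_reps)):
        cohort = generate_cohort(design=design, presets=presets, rng=rng)
        idx = asymmetry_table(cohort.score(), column="looking_time_aoi_s")
        tests = asymmetry_ttests(idx)
        # uncorrected per-cell test at 0.05, both speed conditions
        sig = bool(((tests["p"] < 0.05) & (tests["mean_index"] > 0.5)).all())
        rows.append({"rep": rep, "expansion_bias_detected": sig})
    return pd.DataFrame(rows)
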