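# flowgaze

Simulation and analysis pipeline for a developmental eye-tracking paradigm on
radial optic flow: how long, and how quickly, observers of different ages look
at the **focus of expansion/contraction** of a moving radial dot pattern.

The package is aimed at visual-development and psychophysics researchers who
want to (a) regenerate the dot-motion stimuli as data, (b) score eye-tracker
gaze streams against a moving area of interest, and (c) run the group-level
mixed-design statistics — all without access to the original participant data,
using a synthetic gaze cohort whose biases are controllable ground truth.

## The paradigm

A field of 500 bright dots moves radially on a 35.3° × 26.4° background. Each
dot's speed is `k · ecc` — the speed constant `k` (0.33 low, 0.66 high, in
s⁻¹) times its eccentricity from the flow focus — so speed is zero at the
focus and grows linearly to the periphery. Dots live 10 frames (333 ms) and
respawn uniformly. The focus starts 9.2° left or right of centre and sweeps at
3.68°/s to the other side and back over the 10 s trial (30 fps, 300 frames).
A contraction movie is the expansion frame set played in reverse, so both
directions contain identical frames. A benchmark movie replaces the flow with
a single square on the same trajectory.

Gaze (60 Hz) is scored against a circular AOI of diameter 9.2° locked to the
focus:

* **looking time** — Σ (valid in-AOI samples) × 1/60 s,
* **latency** — time of first in-AOI sample, censored at 10 s,
* **AOIW looking time** — same against the whole background,
* **asymmetry index** — `LT_exp / (LT_exp + LT_con)`; 0.5 = no bias.

Because the AOI sweeps over the screen centre, a gaze parked at centre scores
non-trivial "chance" values that follow from geometry alone: the nearest AOI
edge starts 4.6° (134 px) away and approaches at 107.2 px/s, giving a 1.25 s
chance latency; each full crossing of the 268 px AOI takes 2.5 s, giving 5 s
chance looking time over the out-and-back sweep.

Group statistics use a mixed three-way design (age group between; flow
direction and dot speed within; participant random effect). Each fixed term
is F-tested against its exact error stratum (between: subjects-within-groups;
each within term: its term × subject stratum), all on `N − a = 247`
denominator df for the full 13 × 20 design. Effect sizes are partial eta
squared, `η_p² = F·df1 / (F·df1 + df2)`, with 95% CIs from noncentral-F
inversion.

## Worked example

```python
from flowgaze import (AoiSpec, center_fixed_stream, chance_levels,
                      latency, looking_time, generate_cohort,
                      condition_means, fit_threeway_lmm)

# chance geometry: a gaze fixed at screen centre
aoi = AoiSpec.for_path("RLR")
s = center_fixed_stream()
print(looking_time(s, aoi), latency(s, aoi))   # 5.0 1.25
print(chance_levels(aoi).aoi_crossing_time_s)  # 2.5

# a full synthetic cohort: 13 age groups x 20 participants x 8 trials
cohort = generate_cohort(rng=0)
means = condition_means(cohort.score())
print(fit_threeway_lmm(means, "looking_time_aoi_s").round(3)[["F", "df1", "df2", "p"]])
```

which prints (seed 0):

```
                                  F  df1  df2      p
term
age_group                    57.854   12  247  0.000
direction                   117.781    1  247  0.000
age_group:direction          17.472   12  247  0.000
speed                        40.962    1  247  0.000
age_group:speed               1.339   12  247  0.197
direction:speed               0.891    1  247  0.346
age_group:direction:speed     1.009   12  247  0.441
```

The age × direction interaction is the developmental signature: the shipped
cohort presets give the youngest group a contraction bias (e.g. 3.72 s vs
2.52 s mean looking at seed 0) and groups ≥ 5 y an expansion bias (adults
6.31 s vs 4.77 s), while the benchmark latency shows no age effect
(F(12,247) = 0.64, p = 0.81) and the whole-screen asymmetry index never
deviates from 0.5 (0 of 26 cells at α = 0.05/26).

The numbered scripts under `analysis/` run this narrative end to end
(stimuli → cohort → statistics → chance levels → replication study) and
write their tables under `results/`. A `flowgaze` CLI exposes the same
stages (`simulate-stimulus`, `simulate-cohort`, `score`, `analyze`,
`chance`, `run`).

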