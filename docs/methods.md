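# Methods

## Stimulus model

The stimulus is represented as data — per-frame dot coordinates — rather than
rendered video. Dots move under forward Euler with `dt = 1/30 s`; at each
step a dot at position **p** with the focus at **f** is displaced by
`k · (p − f) · dt`, i.e. radially away from the *instantaneous* focus with
speed `k · ‖p − f‖` (deg/s). The radial direction is re-evaluated every frame
against the moving focus; this is the only reading under which the zero-speed
point of the pattern actually travels with the focus. A dot exactly at the
focus has zero speed and stays in place (tie-break).

Respawning is evaluated after the motion step: dots whose age reaches the
10-frame lifetime or that left the 35.3° × 26.4° field are redrawn uniformly
on the field with age 0. Initial ages are staggered uniformly over
`[0, lifetime)` to avoid synchronized mass respawns. Contraction movies are
produced *only* by reversing the expansion frame order (never by integrating
inward motion), so the two directions are guaranteed to contain bit-identical
frames.

The focus trajectory is piecewise linear: start offset s = ±9.2°, sweep speed
v = 2·|s|/(T/2) = 3.68°/s exactly (the nominal "≈3.7°/s" does not close the
out-and-back loop in 10 s; geometric consistency was preferred). All
degree↔pixel conversions use the single constant 268 px / 9.2° ≈ 29.13 px/°;
pixel export flips to raster convention (origin top-left, y down).

**Measured mean dot speed.** With dots uniform over the field and the literal
rule `speed = k · ecc`, the measured whole-movie mean speed is ≈ 4.2 deg/s
(low) and ≈ 8.3 deg/s (high) — exactly ratio 2, as the linearity demands, but
lower than the nominal 5.8/11.6 deg/s figures sometimes quoted for this kind
of display, whose averaging convention is not derivable from the speed rule.
The package therefore reports its own measured mean
(`stimulus.mean_dot_speed`) and hard-codes nothing.

## Gaze scoring

Samples are instants; each valid sample contributes one nominal sample period
(1/60 s) to looking time. Dropped/invalid samples shorten the accumulated
time — no interpolation, the simplest defensible convention. The AOI boundary
is inclusive (`distance ≤ 4.6°` counts as inside, evaluated in degrees to
avoid raster rounding), and latency is measured from stimulus onset (t = 0),
censored at the 10 s trial duration when the AOI is never entered. The
asymmetry index is undefined (NaN) when both direction totals are zero; such
participants are excluded from index tests rather than imputed 0 or 0.5.

With 600 samples at t = k/60 and the ±9.2°, 3.68°/s trajectory, a
centre-fixed stream yields exactly 300 in-AOI samples (5.000 s) and first
entry at t = 1.25 s under IEEE double arithmetic — the discrete scoring
reproduces the analytic chance levels exactly, which the acceptance checks
exploit.

## Synthetic cohort

The generative gaze model is the package's own construction (no generative
model of infant gaze exists to copy): per trial,

1. an orienting latency L ~ lognormal(median by age, σ = 0.5) determines the
   first in-AOI sample;
2. afterwards a two-state Markov chain per 60 Hz sample alternates in-AOI
   (AOI centre + isotropic Gaussian jitter, σ = 1.0°) and off-AOI excursions
   (uniform off-AOI point, redrawn per sample);
3. samples are invalid i.i.d. with p = 0.05.

The chain's relaxation rate is fixed at `p_leave + p_return = 0.05` per
sample (~0.33 s mixing) and split to hit a target stationary occupancy
π = p_return/(p_leave + p_return). Group × direction × speed looking-time
targets map to π via `target = π · (10 − E[L])`. Between-participant
variation enters on the logit scale for occupancy (σ = 0.35) and the log
scale for latency medians (σ = 0.15), giving the random-intercept variance
the mixed model estimates downstream.

**Pre-orienting samples are off-AOI by construction.** A gaze literally
parked at the screen centre would be swept over by the AOI at ~1.25 s, which
would couple every trial's looking time to the chance geometry and make a
"never oriented" trial impossible. Instead, pre-orienting gaze holds near the
centre but is displaced to a random off-AOI point whenever the moving AOI
covers it — the semantics being that a participant who has not yet oriented
to the focus is, by definition, not looking at it. The chance geometry is
exercised separately through an explicitly constructed centre-fixed stream.
Consequences: generated looking time is governed entirely by L and the dwell
chain (clean closed-form expectations), at the cost of not modelling passive
AOI capture.

Preset targets encode the qualitative developmental pattern (contraction
bias at 1 y, expansion bias from 5 y, looking time rising to a plateau by
5–6 y, latency shortening with age, +0.5 s looking under high speed,
age-independent benchmark latency with median 0.8 s). Direction differences
are kept ≥ 0.8 s so that per-group effect signs are recoverable at n = 20.
What the generator does **not** emulate: saccade main-sequence dynamics,
smooth pursuit gain, dropout bursts, head movement, or any dependence of
gaze on the dot pattern itself beyond the AOI trajectory — so passing tests
demonstrate pipeline correctness and statistical operating characteristics,
not fidelity to human gaze microstructure.

## Statistics

The three-way analysis is computed as the exact split-plot decomposition:
every within-subject term is reduced to an orthonormal contrast score per
participant, and each term is tested against its own contrast's
between-subject residual (term × subject stratum); the age effect is tested
on subject means against subjects-within-groups. For the full 13 × 20 design
every term lands on denominator df 247; for a single-group two-level design
the direction F equals the paired t². Under balance these strata tests are
exact for the compound-symmetry mixed model, so no Kenward–Roger or
Satterthwaite approximation is required; the `error_stratum` column of every
ANOVA table records which stratum was used. Participants with incomplete
condition cells raise an explicit error (`on_missing="drop"` removes them
with a logged warning) — the strata decomposition needs complete cases, a
deliberate trade against silent unbalanced fits.

Simple effects of direction per age group use the pooled direction × subject
stratum (df 247) on participant direction contrasts. Pairwise age
comparisons (78 per direction) pool the within-group error of participant
means and apply the Bonferroni threshold 0.05/78; the asymmetry t tests use
0.05/26 across the 13 × 2 cells, with listwise exclusion of undefined
indices. Zero-variance index cells are handled explicitly (t = 0, p = 1 at
the null mean). η_p² CIs invert the noncentral-F cdf by bracketed root
finding (NaN cdf values at extreme noncentrality treated as 0, lower bound
floored at 0); published intervals computed with other CI conventions agree
with this inversion to about ±0.02.

## Problem sizes and determinism

Replication studies run the full 13 × 20 design: 50 seeded replications for
sign-recovery/power and 200 for null type-I error (binomial 2-SE band around
α = 0.05), each replication a fresh generate → score → fit cycle (~0.3 s,
vectorized across all 2 080 trials). All randomness flows through
`numpy.random.Generator` seeds; identical seeds give bit-identical frame
sets, cohorts, score tables and pipeline outputs (the run manifest records
SHA-256 checksums to make this checkable).
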