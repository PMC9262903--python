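"""Synthetic cohort generator: design counts, determinism, dwell-chain math."""

import numpy as np
import pandas as pd
import pytest

from flowgaze.cohort import (
    AGE_GROUPS,
    CohortDesign,
    generate_cohort,
    load_presets,
    occupancy_from_target,
    sample_participant,
    simulate_trial,
    stationary_occupancy,
)
from flowgaze.scoring import AoiSpec, latency, looking_time, score_dataset


def degenerate_participant(occupancy, latency_median_s, jitter=0.0, p_invalid=0.0, rate=0.05):
    occ = {(d, s): occupancy for d in ("expansion", "contraction") for s in ("low", "high")}
    return {
        "age_group": "adult",
        "latency_median_s": latency_median_s,
        "latency_sigma": 1e-9,
        "occupancy": occ,
        "state_rate": rate,
        "jitter_sd_deg": jitter,
        "p_invalid": p_invalid,
        "benchmark_latency_median_s": 0.8,
        "benchmark_latency_sigma": 0.3,
        "benchmark_occupancy": 0.85,
    }


class TestDesign:
    def test_full_design_counts(self, full_cohort):
        trials = full_cohort.trials
        exp = trials[trials["direction"].isin(["expansion", "contraction"])]
        assert len(exp) == 13 * 20 * 8  # 2080 experimental streams
        assert len(trials) == 13 * 20 * 10  # + 2 benchmark trials each
        assert len(full_cohort.truth) == 260

    def test_eight_experimental_trials_each_condition_twice(self, full_cohort):
        trials = full_cohort.trials
        exp = trials[trials["direction"].isin(["expansion", "contraction"])]
        per = exp.groupby("participant_id")
        assert (per.size() == 8).all()
        counts = exp.groupby(["participant_id", "direction", "speed"]).size()
        assert (counts == 2).all()
        # the two repetitions take the two motion paths
        paths = exp.groupby(["participant_id", "direction", "speed"])["path"].nunique()
        assert (paths == 2).all()

    def test_benchmark_order_counterbalanced(self, full_cohort):
        bench = full_cohort.trials[full_cohort.trials["direction"] == "benchmark"]
        first = bench.groupby("participant_id", sort=False).first()["path"]
        assert set(first.unique()) == {"RLR", "LRL"}
        assert abs((first == "RLR").sum() - (first == "LRL").sum()) <= 1

    def test_trial_order_randomized_across_participants(self, full_cohort):
        exp = full_cohort.trials[full_cohort.trials["direction"] != "benchmark"]
        orders = exp.groupby("participant_id", sort=False).apply(
            lambda g: tuple(zip(g["direction"], g["speed"], g["path"])),
            include_groups=False,
        )
        assert orders.nunique() > 1

    def test_seeded_determinism(self, presets):
        design = CohortDesign(age_groups=("1y",), n_per_group=2)
        a = generate_cohort(design=design, presets=presets, rng=42)
        b = generate_cohort(design=design, presets=presets, rng=42)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        np.testing.assert_array_equal(a.x_deg, b.x_deg)
        np.testing.assert_array_equal(a.valid, b.valid)


class TestParticipantSampling:
    def test_zero_variance_matches_group_values(self, presets, rng):
        import copy

        p0 = copy.deepcopy(presets)
        p0["between_participant"] = {"occupancy_logit_sd": 0.0, "latency_log_sd": 0.0}
        part = sample_participant("adult", p0, rng)
        g = p0["groups"]["adult"]
        assert part["latency_median_s"] == pytest.approx(g["latency_median_s"])
        expected = occupancy_from_target(
            g["target_looking_s"]["expansion"], g["latency_median_s"], p0["latency_sigma"]
        )
        assert part["occupancy"][("expansion", "low")] == pytest.approx(expected)

    def test_reproducible_and_distinct_draws(self, presets):
        a = [sample_participant("5y", presets, np.random.default_rng(3)) for _ in range(1)]
        b = [sample_participant("5y", presets, np.random.default_rng(3)) for _ in range(1)]
        assert a[0]["occupancy"] == b[0]["occupancy"]
        rng = np.random.default_rng(3)
        many = [sample_participant("5y", presets, rng) for _ in range(20)]
        assert len({p["latency_median_s"] for p in many}) == 20


class TestTrialSimulation:
    def test_absorbing_in_state_fills_trial(self):
        part = degenerate_participant(occupancy=1.0, latency_median_s=1e-6)
        s = simulate_trial(part, ("expansion", "low", "RLR"), np.random.default_rng(0))
        aoi = AoiSpec.for_path("RLR")
        assert looking_time(s, aoi) >= 10.0 - 2 / 60
        assert latency(s, aoi) <= 1 / 60

    def test_censored_trial_never_enters(self):
        part = degenerate_participant(occupancy=0.0, latency_median_s=50.0)
        s = simulate_trial(part, ("expansion", "low", "RLR"), np.random.default_rng(0))
        aoi = AoiSpec.for_path("RLR")
        assert looking_time(s, aoi) == 0.0
        assert latency(s, aoi) == 10.0

    def test_occupancy_matches_two_state_closed_form(self):
        # stationary occupancy p_return/(p_leave+p_return) plus the start-in-state
        # transient, averaged over the n samples of the trial
        occ, rate, n = 0.4, 0.05, 600
        part = degenerate_participant(occupancy=occ, latency_median_s=1e-6, jitter=0.3)
        aoi = AoiSpec.for_path("RLR")
        rng = np.random.default_rng(11)
        times = [
            looking_time(simulate_trial(part, ("expansion", "low", "RLR"), rng), aoi)
            for _ in range(150)
        ]
        assert stationary_occupancy(rate * (1 - occ), rate * occ) == pytest.approx(occ)
        decay = (1 - rate) ** np.arange(n)
        expected_frac = occ + (1 - occ) * decay.mean()
        expected = 10.0 * expected_frac
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert np.mean(times) == pytest.approx(expected, abs=3 * se)

    def test_invalid_rate_close_to_preset(self):
        part = degenerate_participant(occupancy=0.5, latency_median_s=0.5, p_invalid=0.2)
        s = simulate_trial(part, ("expansion", "low", "RLR"), np.random.default_rng(5))
        frac = 1.0 - s.valid.mean()
        assert frac == pytest.approx(0.2, abs=0.06)


class TestPresets:
    def test_qualitative_developmental_pattern(self, presets):
        targets = {g: s["target_looking_s"] for g, s in presets["groups"].items()}
        assert targets["1y"]["contraction"] > targets["1y"]["expansion"]
        for g in ("5y", "6y", "7y", "8y", "9y", "10y", "11y", "12y", "adult"):
            assert targets[g]["expansion"] > targets[g]["contraction"]
        young = ["1y", "2y", "3y", "4y", "5y", "6y"]
        for d in ("expansion", "contraction"):
            series = [targets[g][d] for g in young]
            assert all(b >= a for a, b in zip(series, series[1:]))

    def test_latency_shortens_with_age(self, presets):
        lats = [presets["groups"][g]["latency_median_s"] for g in AGE_GROUPS]
        assert all(b <= a for a, b in zip(lats, lats[1:]))

    def test_target_bounds_validated(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        text = (
            "version: 1\nlatency_sigma: 0.5\nstate_rate_per_sample: 0.05\n"
            "jitter_sd_deg: 1.0\np_invalid: 0.05\n"
            "between_participant: {occupancy_logit_sd: 0.3, latency_log_sd: 0.1}\n"
            "benchmark: {latency_median_s: 0.8, latency_sigma: 0.3, occupancy: 0.85}\n"
            "groups:\n  adult: {latency_median_s: 1.0, target_looking_s: {expansion: 12.0, contraction: 3.0}}\n"
        )
        bad.write_text(text)
        with pytest.raises(ValueError, match="out of"):
            load_presets(bad)


class TestBatchScoring:
    def test_fast_path_equals_per_stream_scoring(self, tiny_cohort):
        fast = tiny_cohort.score().sort_values("trial_id").reset_index(drop=True)
        slow = (
            score_dataset(tiny_cohort.to_streams())
            .sort_values("trial_id")
            .reset_index(drop=True)[fast.columns]
        )
        pd.testing.assert_frame_equal(fast, slow, check_dtype=False)


class TestPipelineClosure:
    def test_group_direction_means_recovered(self, full_cohort, full_scores, presets):
        """A 13x20 cohort's group x direction looking means agree with an
        independent Monte-Carlo estimate of the same generator."""
        mc = generate_cohort(
            design=CohortDesign(n_per_group=60, include_benchmark=False),
            presets=presets,
            rng=12345,
        )

        def cell_stats(scores):
            exp = scores[scores["direction"].isin(["expansion", "contraction"])]
            per = exp.groupby(["participant_id", "age_group", "direction"])[
                "looking_time_aoi_s"
            ].mean()
            g = per.groupby(["age_group", "direction"])
            return g.mean(), g.std(ddof=1), g.size()

        m_a, s_a, n_a = cell_stats(full_scores)
        m_b, s_b, n_b = cell_stats(mc.score())
        z = (m_a - m_b) / np.sqrt(s_a**2 / n_a + s_b**2 / n_b)
        assert (np.abs(z) <= 2.0).sum() >= len(z) - 2  # 26 cells, allow chance excursions
        assert np.abs(z).max() <= 3.5
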