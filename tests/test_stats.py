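"""Mixed-design ANOVA, simple effects, post hocs and effect sizes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from flowgaze.stats import (
    asymmetry_table,
    asymmetry_ttests,
    benchmark_anova,
    eta_squared_ci,
    fit_threeway_lmm,
    pairwise_ages,
    partial_eta_squared,
    simple_effects_by_age,
)


def toy_direction_table():
    # two direction levels per participant; paired t on diffs (1, 2, 0) is 1.732
    rows = []
    for pid, (con, exp) in {"P1": (1, 2), "P2": (2, 4), "P3": (3, 3)}.items():
        rows.append({"participant_id": pid, "age_group": "all", "direction": "contraction", "value": con})
        rows.append({"participant_id": pid, "age_group": "all", "direction": "expansion", "value": exp})
    return pd.DataFrame(rows)


def make_threeway(rng, n_groups=3, n_per=5, dir_effect=0.8, inter=0.2, noise=0.5):
    rows = []
    for a, g in enumerate(f"g{i+1}" for i in range(n_groups)):
        for s in range(n_per):
            pid = f"{g}_s{s}"
            u = rng.normal(0, 1)
            for d in ["expansion", "contraction"]:
                for sp in ["lo", "hi"]:
                    mu = (
                        a * 0.5
                        + (dir_effect if d == "expansion" else 0)
                        + (0.3 if sp == "hi" else 0)
                        + inter * a * (d == "expansion")
                    )
                    rows.append((pid, g, d, sp, mu + u + rng.normal(0, noise)))
    return pd.DataFrame(
        rows, columns=["participant_id", "age_group", "direction", "speed", "value"]
    )


class TestThreeWayAnova:
    def test_direction_f_equals_paired_t_squared(self):
        res = fit_threeway_lmm(toy_direction_table(), "value", within=("direction",))
        assert res.loc["direction", "F"] == pytest.approx(3.0, rel=1e-10)
        assert res.loc["direction", "df1"] == 1
        assert res.loc["direction", "df2"] == 2

    def test_matches_r_aov_strata(self, rng):
        """Frozen oracle: R's aov with Error(participant/(direction*speed))
        on this exact dataset."""
        table = make_threeway(np.random.default_rng(1))
        res = fit_threeway_lmm(table, "value")
        expected = {
            "age_group": (0.874299, 0.44211691),
            "direction": (82.960457, 0.00000097),
            "age_group:direction": (4.730119, 0.03056893),
            "speed": (12.851295, 0.00374859),
            "age_group:speed": (0.821094, 0.46321553),
            "direction:speed": (0.254061, 0.62335610),
            "age_group:direction:speed": (0.740199, 0.49758967),
        }
        for term, (F, p) in expected.items():
            assert res.loc[term, "F"] == pytest.approx(F, rel=1e-4), term
            assert res.loc[term, "p"] == pytest.approx(p, abs=5e-7), term
            assert res.loc[term, "df2"] == 12

    def test_within_terms_match_statsmodels_anova_rm(self, rng):
        """Single-group within design cross-checked against AnovaRM."""
        from statsmodels.stats.anova import AnovaRM

        table = make_threeway(rng, n_groups=1, n_per=12)
        res = fit_threeway_lmm(table, "value")
        rm = AnovaRM(
            table, depvar="value", subject="participant_id", within=["direction", "speed"]
        ).fit()
        for term in ["direction", "speed", "direction:speed"]:
            assert res.loc[term, "F"] == pytest.approx(
                rm.anova_table.loc[term, "F Value"], rel=1e-8
            )

    def test_between_term_matches_f_oneway(self, rng):
        table = make_threeway(rng)
        res = fit_threeway_lmm(table, "value")
        per = table.groupby(["participant_id", "age_group"])["value"].mean().reset_index()
        F, p = sps.f_oneway(
            *[g["value"].to_numpy() for _, g in per.groupby("age_group")]
        )
        assert res.loc["age_group", "F"] == pytest.approx(F, rel=1e-8)
        assert res.loc["age_group", "p"] == pytest.approx(p, rel=1e-6)

    def test_constant_dv_gives_zero_f(self):
        table = make_threeway(np.random.default_rng(0))
        table["value"] = 3.0
        res = fit_threeway_lmm(table, "value")
        assert (res["F"] == 0.0).all()
        assert (res["p"] == 1.0).all()

    def test_missing_cell_raises_then_drops(self, rng):
        table = make_threeway(rng).iloc[1:]
        with pytest.raises(ValueError, match="missing within cells"):
            fit_threeway_lmm(table, "value")
        res = fit_threeway_lmm(table, "value", on_missing="drop")
        assert res.loc["age_group", "df2"] == 11  # one participant dropped

    def test_degenerate_group_size_rejected(self, rng):
        table = make_threeway(rng, n_groups=2, n_per=1)
        with pytest.raises(ValueError):
            fit_threeway_lmm(table, "value")


class TestEffectSize:
    def test_partial_eta_formula(self):
        assert partial_eta_squared(51.470, 1, 247) == pytest.approx(0.172, abs=5e-4)
        assert partial_eta_squared(12.073, 12, 247) == pytest.approx(0.370, abs=5e-4)

    def test_ci_brackets_point_estimate(self):
        for F, df1, df2 in [(51.470, 1, 247), (3.938, 1, 247), (1.349, 12, 247)]:
            eta = partial_eta_squared(F, df1, df2)
            lo, hi = eta_squared_ci(F, df1, df2)
            assert 0.0 <= lo <= eta <= hi < 1.0

    def test_ci_close_to_published_intervals(self):
        # noncentral-F inversion; the study's CI routine differs slightly
        cases = {
            (12.073, 12, 247): (0.26, 0.44),
            (51.470, 1, 247): (0.10, 0.26),
            (82.631, 1, 247): (0.16, 0.34),
        }
        for (F, df1, df2), (lo_ref, hi_ref) in cases.items():
            lo, hi = eta_squared_ci(F, df1, df2)
            assert lo == pytest.approx(lo_ref, abs=0.03)
            assert hi == pytest.approx(hi_ref, abs=0.03)

    def test_null_f_gives_zero_interval(self):
        assert eta_squared_ci(0.0, 1, 100) == (0.0, 0.0)


class TestSimpleEffects:
    def test_null_group_contrast_near_zero(self, rng):
        table = make_threeway(rng, dir_effect=0.0, inter=0.0, n_per=40)
        se = simple_effects_by_age(table, "value")
        assert np.abs(se["estimate"]).max() < 0.4

    def test_sign_recovery_on_preset_cohort(self, full_scores, presets):
        from flowgaze.replication import preset_direction_signs
        from flowgaze.scoring import condition_means

        means = condition_means(full_scores)
        se = simple_effects_by_age(means, "looking_time_aoi_s")
        truth = preset_direction_signs(presets)
        for row in se.itertuples():
            assert int(np.sign(row.estimate)) == truth[row.age_group], row.age_group
        assert se.loc[se["age_group"] == "1y", "estimate"].iloc[0] < 0
        assert se.loc[se["age_group"] == "adult", "estimate"].iloc[0] > 0


class TestPairwise:
    def test_78_pairs_and_corrected_alpha(self, full_scores):
        from flowgaze.scoring import condition_means

        means = condition_means(full_scores)
        pw = pairwise_ages(means, "looking_time_aoi_s", "expansion")
        assert len(pw) == 78
        assert pw.attrs["corrected_alpha"] == pytest.approx(0.05 / 78)
        # adjacent-age pairs mostly indistinguishable, extremes separate
        extreme = pw[(pw["group_1"] == "1y") & (pw["group_2"] == "adult")]
        assert bool(extreme["significant"].iloc[0])

    def test_identical_groups_never_flagged(self, rng):
        rows = []
        for g in [f"g{i}" for i in range(13)]:
            for s in range(4):
                rows.append(
                    {
                        "participant_id": f"{g}_{s}",
                        "age_group": g,
                        "direction": "expansion",
                        "speed": "low",
                        "value": float(rng.normal(5, 1)),
                    }
                )
        df = pd.DataFrame(rows)
        # same distribution everywhere: no pair should clear 0.05/78
        pw = pairwise_ages(df, "value", "expansion")
        assert not pw["significant"].any()


class TestAsymmetry:
    def test_t_matches_closed_form(self):
        vals = np.array([0.62, 0.55, 0.58, 0.61, 0.49, 0.66, 0.57, 0.60])
        df = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(len(vals))],
                "age_group": "adult",
                "speed": "low",
                "index": vals,
            }
        )
        res = asymmetry_ttests(df)
        expected_t = (vals.mean() - 0.5) / (vals.std(ddof=1) / np.sqrt(len(vals)))
        assert res["t"].iloc[0] == pytest.approx(expected_t)

    def test_all_half_indices_give_t_zero(self):
        df = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(6)],
                "age_group": "adult",
                "speed": "low",
                "index": [0.5] * 6,
            }
        )
        res = asymmetry_ttests(df)
        assert res["t"].iloc[0] == pytest.approx(0.0)
        assert not res["significant"].iloc[0]

    def test_26_cells_on_full_design(self, full_scores):
        idx = asymmetry_table(full_scores)
        res = asymmetry_ttests(idx)
        assert len(res) == 26
        assert res.attrs["corrected_alpha"] == pytest.approx(0.05 / 26)

    def test_undefined_indices_excluded(self):
        df = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(5)],
                "age_group": "1y",
                "speed": "low",
                "index": [0.6, 0.7, np.nan, 0.55, np.nan],
            }
        )
        res = asymmetry_ttests(df)
        assert res["n"].iloc[0] == 3


class TestBenchmark:
    def test_age_independent_benchmark_not_significant(self, full_scores):
        bench = full_scores[full_scores["direction"] == "benchmark"]
        res = benchmark_anova(bench)
        assert res.loc["age_group", "df1"] == 12
        assert res.loc["age_group", "df2"] == 247
        assert res.loc["age_group", "p"] > 0.05

    def test_constant_latency_gives_zero_f(self):
        df = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(8)],
                "age_group": ["a"] * 4 + ["b"] * 4,
                "latency_aoi_s": 1.0,
            }
        )
        res = benchmark_anova(df)
        assert res.loc["age_group", "F"] == 0.0
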