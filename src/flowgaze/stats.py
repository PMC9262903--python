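"""Group-level inference for the gaze measures.

Implements the study's inferential stage: three-way mixed-design ANOVAs
(age between participants; flow direction and dot speed within), simple
effects of direction per age group, Bonferroni-corrected pairwise age
comparisons, one-sample tests of the asymmetry index against 0.5, and the
one-way benchmark ANOVA.

Model and F tests
-----------------
The design is a split plot: participants are nested in age groups and
provide all four direction x speed condition means (repetitions averaged
upstream).  With a participant random effect, each fixed term has an exact
error stratum under balance:

* age — subjects-within-groups mean square, df ``N - a``;
* each within term (direction, speed, their interaction, and their
  interactions with age) — its own term x subject stratum, also df ``N - a``.

These strata F tests are computed exactly via orthonormal within-subject
contrast scores (each within effect reduces to a one-way between-groups
ANOVA on the corresponding contrast score), so no denominator-df
approximation is needed; this reproduces the usual mixed-model ANOVA table
for this design, with every term on ``N - a`` denominator df.

Effect sizes are partial eta squared, ``F df1 / (F df1 + df2)``, with a 95%
confidence interval from inversion of the noncentral-F distribution (lower
bound floored at 0).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scoring import asymmetry_index

__all__ = [
    "partial_eta_squared",
    "eta_squared_ci",
    "fit_threeway_lmm",
    "simple_effects_by_age",
    "pairwise_ages",
    "asymmetry_table",
    "asymmetry_ttests",
    "benchmark_anova",
    "aoiw_simple_interactions",
    "analyze_scores",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """Partial eta squared for an F-tested fixed effect."""
    if not np.isfinite(F):
        return 1.0
    return F * df1 / (F * df1 + df2)


def eta_squared_ci(F: float, df1: float, df2: float, conf: float = 0.95) -> tuple[float, float]:
    """95% CI for partial eta squared by noncentral-F inversion.

    The noncentrality bounds solve ``P(F <= F_obs | nc) = 1 -/+ alpha/2``;
    each bound maps to eta via ``nc / (nc + df1 + df2 + 1)``.  The lower
    bound is floored at 0.
    """
    if not np.isfinite(F) or F <= 0:
        return 0.0, 0.0
    alpha = 1.0 - conf

    def cdf(nc: float) -> float:
        val = stats.ncf.cdf(F, df1, df2, nc)
        return float(val) if np.isfinite(val) else 0.0

    def solve(level: float) -> float:
        if cdf(0.0) < level:
            return 0.0
        hi = 1.0
        while cdf(hi) > level:
            hi *= 2.0
            if hi > 1e8:  # pragma: no cover - pathological F
                break
        return float(optimize.brentq(lambda nc: cdf(nc) - level, 0.0, hi))

    nc_lo = solve(1.0 - alpha / 2.0)
    nc_hi = solve(alpha / 2.0)

    def to_eta(nc: float) -> float:
        return nc / (nc + df1 + df2 + 1.0)

    return max(0.0, to_eta(nc_lo)), to_eta(nc_hi)


def _contrast_vectors(factors: list[str], levels: dict[str, list[str]], cells: list[tuple]):
    """Orthonormal contrast vector over the within cells for each within term.

    Yields (term_name, weight_vector).  Each 2-level factor contributes a
    mean vector (.5, .5) or an effect vector (.5, -.5); Kronecker products
    over factors give the cell weights, normalized to unit length.
    """
    per_factor = {}
    for f in factors:
        lv = levels[f]
        if len(lv) != 2:
            raise ValueError(f"within factor {f} must have exactly 2 levels, got {lv}")
        per_factor[f] = {"mean": np.array([0.5, 0.5]), "effect": np.array([0.5, -0.5])}

    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            w = np.array([1.0])
            for f in factors:
                w = np.kron(w, per_factor[f]["effect" if f in combo else "mean"])
            w = w / np.linalg.norm(w)
            yield ":".join(combo), w


def _oneway_strata(z: np.ndarray, group_codes: np.ndarray, n_groups: int):
    """Decompose contrast scores into overall-mean, group and residual SS."""
    N = len(z)
    zbar = z.mean()
    ss_mean = N * zbar**2
    group_means = np.array([z[group_codes == g].mean() for g in range(n_groups)])
    n_per = np.array([(group_codes == g).sum() for g in range(n_groups)])
    ss_group = float(np.sum(n_per * (group_means - zbar) ** 2))
    ss_resid = float(np.sum((z - group_means[group_codes]) ** 2))
    return ss_mean, ss_group, ss_resid


def _f_row(ss: float, df1: float, ms_err: float, df2: float) -> tuple[float, float]:
    if ms_err <= _EPS:
        if ss <= _EPS:
            return 0.0, 1.0
        return np.inf, 0.0
    F = (ss / df1) / ms_err
    return float(F), float(stats.f.sf(F, df1, df2))


def fit_threeway_lmm(
    table: pd.DataFrame,
    dv: str,
    participant: str = "participant_id",
    between: str = "age_group",
    within: tuple[str, ...] = ("direction", "speed"),
    on_missing: str = "error",
    conf: float = 0.95,
) -> pd.DataFrame:
    """Mixed-design factorial ANOVA with a participant random effect.

    ``table`` is long format with one row per participant x within-cell
    (repetitions already averaged).  Within factors with a single observed
    level are dropped from the model; the between factor is dropped when only
    one group is present (the within tests then reduce to one-sample tests on
    contrast scores — e.g. the 2-level direction F equals the paired t
    squared).

    Participants missing any within cell raise ``ValueError`` unless
    ``on_missing='drop'``, which removes them with a logged warning.

    Returns a DataFrame indexed by term with columns F, df1, df2, p,
    eta_p2, eta_lo, eta_hi and error_stratum.
    """
    if dv not in table.columns:
        raise ValueError(f"dv column {dv!r} not in table")
    within = tuple(f for f in within if f in table.columns and table[f].nunique() > 1)
    levels = {f: sorted(table[f].unique()) for f in within}
    cells = list(itertools.product(*[levels[f] for f in within])) if within else [()]

    cols = [participant, between, *within] if between in table.columns else [participant, *within]
    sub = table[cols + [dv]].copy()
    if sub[dv].isna().any():
        raise ValueError("dv contains missing values")

    if within:
        wide = sub.pivot_table(
            index=[participant] + ([between] if between in sub.columns else []),
            columns=list(within),
            values=dv,
            aggfunc="mean",
        )
        want = [c if len(within) > 1 else c[0] for c in cells]
        wide = wide.reindex(columns=want)
        incomplete = wide.isna().any(axis=1)
        if incomplete.any():
            bad = list(wide.index[incomplete])
            if on_missing == "drop":
                logger.warning("dropping %d participants with incomplete cells: %s", len(bad), bad)
                wide = wide[~incomplete]
            else:
                raise ValueError(
                    f"participants with missing within cells: {bad}; "
                    "pass on_missing='drop' to remove them"
                )
        y = wide.to_numpy()
        if between in sub.columns:
            groups = wide.index.get_level_values(between)
        else:
            groups = pd.Index(["all"] * len(wide))
    else:
        grp = sub.groupby([participant] + ([between] if between in sub.columns else []))[dv].mean()
        y = grp.to_numpy()[:, None]
        groups = (
            grp.index.get_level_values(between)
            if between in sub.columns
            else pd.Index(["all"] * len(grp))
        )

    group_labels = sorted(pd.unique(groups))
    a = len(group_labels)
    code = pd.Categorical(groups, categories=group_labels).codes
    N = len(y)
    if N < 2:
        raise ValueError("need at least 2 participants")
    if a > 1 and min((code == g).sum() for g in range(a)) < 2:
        raise ValueError("each group needs at least 2 participants")
    n_cells = y.shape[1]
    df_err = N - a
    if df_err < 1:
        raise ValueError("no residual degrees of freedom (N <= number of groups)")

    results = []

    # between stratum: subject means vs subjects-within-groups
    w0 = np.full(n_cells, 1.0 / np.sqrt(n_cells))
    z0 = y @ w0
    _, ss_between, ss_subj = _oneway_strata(z0, code, a)
    if a > 1:
        ms_err = ss_subj / df_err
        F, p = _f_row(ss_between, a - 1, ms_err, df_err)
        results.append((between, F, a - 1, df_err, p, "subjects-within-groups"))

    # within strata: one contrast score per within term
    if within:
        for term, w in _contrast_vectors(list(within), levels, cells):
            z = y @ w
            ss_term, ss_inter, ss_resid = _oneway_strata(z, code, a)
            ms_err = ss_resid / df_err
            F, p = _f_row(ss_term, 1, ms_err, df_err)
            results.append((term, F, 1, df_err, p, f"{term} x subject"))
            if a > 1:
                F2, p2 = _f_row(ss_inter, a - 1, ms_err, df_err)
                results.append(
                    (f"{between}:{term}", F2, a - 1, df_err, p2, f"{term} x subject")
                )

    rows = []
    for term, F, df1, df2, p, stratum in results:
        eta = partial_eta_squared(F, df1, df2)
        lo, hi = eta_squared_ci(F, df1, df2, conf)
        rows.append(
            {
                "term": term,
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "eta_p2": eta,
                "eta_lo": lo,
                "eta_hi": hi,
                "error_stratum": stratum,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def simple_effects_by_age(
    table: pd.DataFrame,
    dv: str,
    participant: str = "participant_id",
    between: str = "age_group",
    factor: str = "direction",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Simple main effect of flow direction within each age group.

    Per participant, the direction contrast is the difference of direction
    means (averaged over speed), signed expansion - contraction.  Each group's
    contrast mean is tested against the pooled contrast variance across all
    groups (the direction x subject stratum), df ``N - a`` — the
    least-squares-means style simple effect with a common error term.
    """
    lv = sorted(table[factor].unique())
    if lv != ["contraction", "expansion"]:
        raise ValueError(f"{factor} must have levels contraction/expansion, got {lv}")
    per = table.pivot_table(index=[participant, between], columns=factor, values=dv, aggfunc="mean")
    if per.isna().any().any():
        missing = list(per.index[per.isna().any(axis=1)])
        raise ValueError(f"participants missing a {factor} level: {missing}")
    d = (per["expansion"] - per["contraction"]).rename("contrast")
    groups = d.index.get_level_values(between)
    group_labels = sorted(pd.unique(groups))
    a = len(group_labels)
    N = len(d)
    df = N - a
    resid = d.groupby(groups).transform("mean")
    ms = float(((d - resid) ** 2).sum() / df)
    rows = []
    for g in group_labels:
        dg = d[groups == g]
        n_g = len(dg)
        if n_g == 0:
            raise ValueError(f"empty age group {g}")
        est = float(dg.mean())
        se = np.sqrt(ms / n_g)
        t = est / se if se > 0 else (0.0 if est == 0 else np.inf)
        p = float(2 * stats.t.sf(abs(t), df))
        rows.append(
            {
                "age_group": g,
                "n": n_g,
                "estimate": est,
                "se": se,
                "t": float(t),
                "df": df,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def pairwise_ages(
    table: pd.DataFrame,
    dv: str,
    direction: str,
    participant: str = "participant_id",
    between: str = "age_group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise age-group comparisons within one flow direction.

    Participant means (over speed and repetitions) enter pairwise t tests
    with the pooled within-group error, df ``N - a``.  With 13 groups there
    are C(13,2) = 78 pairs; the Bonferroni-corrected threshold ``alpha / 78``
    flags significance, and Bonferroni-adjusted p values are also returned.
    """
    sub = table[table["direction"] == direction]
    if sub.empty:
        raise ValueError(f"no rows with direction={direction!r}")
    per = sub.groupby([participant, between])[dv].mean()
    groups = per.index.get_level_values(between)
    group_labels = sorted(pd.unique(groups))
    a = len(group_labels)
    N = len(per)
    df = N - a
    gm = per.groupby(groups).mean()
    gn = per.groupby(groups).size()
    mse = float(((per - gm[groups].to_numpy()) ** 2).sum() / df)
    pairs = list(itertools.combinations(group_labels, 2))
    m = len(pairs)
    corrected_alpha = alpha / m
    rows = []
    for g1, g2 in pairs:
        diff = float(gm[g1] - gm[g2])
        se = np.sqrt(mse * (1.0 / gn[g1] + 1.0 / gn[g2]))
        t = diff / se if se > 0 else (0.0 if diff == 0 else np.inf)
        p = float(2 * stats.t.sf(abs(t), df))
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "direction": direction,
                "estimate": diff,
                "t": float(t),
                "df": df,
                "p": p,
                "p_bonferroni": min(1.0, p * m),
                "significant": p < corrected_alpha,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["corrected_alpha"] = corrected_alpha
    out.attrs["n_comparisons"] = m
    return out


def asymmetry_table(
    scores: pd.DataFrame,
    column: str = "looking_time_aoiw_s",
    participant: str = "participant_id",
) -> pd.DataFrame:
    """Per participant x speed asymmetry index from trial scores.

    The index divides the participant's total looking time for expansion
    trials by the total for expansion plus contraction trials, separately per
    speed (whole-screen AOIW looking time by default).  Participants with
    zero total in a cell get NaN (undefined, excluded downstream).
    """
    exp = scores[scores["direction"].isin(["expansion", "contraction"])]
    totals = exp.pivot_table(
        index=[participant, "age_group", "speed"],
        columns="direction",
        values=column,
        aggfunc="sum",
    ).reset_index()
    totals["index"] = [
        asymmetry_index(e, c)
        for e, c in zip(totals["expansion"].fillna(0.0), totals["contraction"].fillna(0.0))
    ]
    return totals[[participant, "age_group", "speed", "index"]]


def asymmetry_ttests(
    indices: pd.DataFrame,
    between: str = "age_group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-tailed one-sample t tests of the asymmetry index against 0.5.

    One test per age group x speed cell (26 for the full design), with the
    Bonferroni-corrected threshold ``alpha / n_cells``.  Cells are evaluated
    after excluding undefined (NaN) indices; a cell with fewer than two valid
    indices is reported untested with a log message.
    """
    cells = indices.groupby([between, "speed"])
    m = len(cells)
    corrected_alpha = alpha / m if m else alpha
    rows = []
    for (g, s), cell in cells:
        vals = cell["index"].dropna().to_numpy()
        excluded = len(cell) - len(vals)
        if excluded:
            logger.info("asymmetry cell (%s, %s): excluded %d undefined indices", g, s, excluded)
        if len(vals) < 2:
            logger.warning("asymmetry cell (%s, %s): <2 valid indices, not tested", g, s)
            rows.append(
                {
                    "age_group": g,
                    "speed": s,
                    "n": len(vals),
                    "mean_index": float(np.mean(vals)) if len(vals) else np.nan,
                    "t": np.nan,
                    "df": np.nan,
                    "p": np.nan,
                    "significant": False,
                }
            )
            continue
        if np.std(vals, ddof=1) == 0.0:
            # degenerate: identical indices; t is 0 at the null mean, infinite off it
            t = 0.0 if vals[0] == 0.5 else np.inf * np.sign(vals[0] - 0.5)
            p = 1.0 if vals[0] == 0.5 else 0.0
        else:
            t, p = stats.ttest_1samp(vals, 0.5)
        rows.append(
            {
                "age_group": g,
                "speed": s,
                "n": len(vals),
                "mean_index": float(np.mean(vals)),
                "t": float(t),
                "df": len(vals) - 1,
                "p": float(p),
                "significant": float(p) < corrected_alpha,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["corrected_alpha"] = corrected_alpha
    out.attrs["n_cells"] = m
    return out


def benchmark_anova(
    latencies: pd.DataFrame,
    dv: str = "latency_aoi_s",
    participant: str = "participant_id",
    between: str = "age_group",
) -> pd.DataFrame:
    """One-way ANOVA of benchmark latency on age (participant trial means)."""
    per = latencies.groupby([participant, between])[dv].mean().reset_index()
    return fit_threeway_lmm(per, dv, participant=participant, between=between, within=())


def aoiw_simple_interactions(
    table: pd.DataFrame, dv: str = "looking_time_aoiw_s"
) -> dict[str, pd.DataFrame]:
    """Two-way (age x direction) refits within each speed level.

    The follow-up to a three-way interaction on whole-screen looking time:
    the age x direction structure is re-examined separately per speed with
    the same strata F tests.
    """
    out = {}
    for s, sub in table.groupby("speed"):
        out[s] = fit_threeway_lmm(sub, dv, within=("direction",))
    return out


def analyze_scores(scores: pd.DataFrame, out_dir=None) -> dict[str, pd.DataFrame]:
    """Run the full inferential stage on a table of trial scores.

    Produces the three-way ANOVAs for AOI looking time, latency and AOIW
    looking time, direction simple effects per age, pairwise age comparisons
    per direction, asymmetry-index t tests, the benchmark one-way ANOVA, and
    per-speed AOIW refits.  Writes one CSV per table into ``out_dir`` when
    given.
    """
    from .scoring import condition_means  # local import to avoid cycle at module load

    means = condition_means(scores)
    results: dict[str, pd.DataFrame] = {}
    results["anova_looking"] = fit_threeway_lmm(means, "looking_time_aoi_s")
    results["anova_latency"] = fit_threeway_lmm(means, "latency_aoi_s")
    results["anova_aoiw"] = fit_threeway_lmm(means, "looking_time_aoiw_s")
    results["simple_effects"] = simple_effects_by_age(means, "looking_time_aoi_s")
    results["pairwise_ages"] = pd.concat(
        [
            pairwise_ages(means, "looking_time_aoi_s", d)
            for d in ("expansion", "contraction")
        ],
        ignore_index=True,
    )
    results["asymmetry_tests"] = asymmetry_ttests(asymmetry_table(scores))
    bench = scores[scores["direction"] == "benchmark"]
    if not bench.empty:
        results["benchmark_anova"] = benchmark_anova(bench)
    else:
        results["benchmark_anova"] = pd.DataFrame()
        logger.warning("no benchmark trials in scores; benchmark ANOVA skipped")
    for s, res in aoiw_simple_interactions(means).items():
        results[f"anova_aoiw_{s}_speed"] = res

    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out / f"{name}.csv")
    return results
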