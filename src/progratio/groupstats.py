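"""Group-level statistical pipeline for fitted parameters and breakpoints.

Two designs are covered, mirroring how PR experiments of this kind are
analysed:

* a 2×2 mixed (split-plot) design — reinforcer type as a between-groups
  factor, deprivation condition as a within-subject factor — analysed per
  parameter by a two-factor ANOVA with partial η² effect sizes, followed,
  when the interaction is significant, by Student's t post hocs (paired
  across conditions within a group, unpaired across groups within a
  condition);
* a one-factor repeated-measures design (drug dose as the within-subject
  factor) with a linear contrast across ordered doses, followed, when the
  treatment effect is significant, by Dunnett many-to-one comparisons of
  each dose against the vehicle control.

The sums of squares are computed by explicit partitioning (exact for any
between-group sizes as long as every retained subject has complete
within-subject data; subjects missing a condition are dropped listwise).
Dunnett adjustment uses the equicorrelated multivariate-t distribution of
the paired-difference t statistics (correlation ½ under balance).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import roots_hermitenorm

from .errors import ArgumentError, DesignError

ALPHA_DEFAULT = 0.05  # two-tailed

ANOVA_COLUMNS = ("effect", "ss", "df1", "df2", "ms", "F", "p", "eta_p2")


def _pivot_complete(
    data: pd.DataFrame, dv: str, subject: str, within: str, extra_index: list[str]
) -> pd.DataFrame:
    """Subject × within-level table, listwise-deleting incomplete subjects."""
    pivot = data.pivot_table(
        index=[subject, *extra_index], columns=within, values=dv, aggfunc="mean"
    )
    return pivot.dropna()


def _effect_row(effect, ss, df1, df2, ss_err) -> dict:
    ms = ss / df1
    ms_err = ss_err / df2
    f = ms / ms_err if ms_err > 0 else (0.0 if ss == 0 else np.inf)
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
    return {
        "effect": effect, "ss": ss, "df1": int(df1), "df2": int(df2),
        "ms": ms, "F": f, "p": p, "eta_p2": eta,
    }


def _error_row(effect, ss, df) -> dict:
    return {
        "effect": effect, "ss": ss, "df1": int(df), "df2": np.nan,
        "ms": ss / df if df else np.nan, "F": np.nan, "p": np.nan, "eta_p2": np.nan,
    }


def mixed_anova_2x2(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "rat_id",
    between: str = "group",
    within: str = "condition",
) -> pd.DataFrame:
    """Two-factor mixed ANOVA: one between-groups and one within-subject factor.

    Returns a table with rows for the between main effect, the within main
    effect and their interaction (F, df, p, partial η²), plus the two error
    strata (subjects within groups; residual) so the full SS partition is
    visible.  Subjects missing any within level are dropped listwise;
    every group must retain at least two subjects.
    """
    pivot = _pivot_complete(data, dv, subject, within, [between])
    if pivot.shape[1] < 2:
        raise DesignError("need at least two within-subject levels")
    groups = pivot.index.get_level_values(between)
    glabels = list(pd.unique(groups))
    if len(glabels) < 2:
        raise DesignError("need at least two groups")
    counts = pd.Series(groups).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise DesignError(f"groups with fewer than 2 complete subjects: {list(small.index)}")

    C = pivot.shape[1]
    N = pivot.shape[0]
    G = len(glabels)
    grand = float(pivot.to_numpy().mean())
    ss_total = float(((pivot.to_numpy() - grand) ** 2).sum())

    subj_means = pivot.mean(axis=1)
    group_means = subj_means.groupby(groups).mean()
    n_g = subj_means.groupby(groups).size()
    ss_between = float(C * (n_g * (group_means - grand) ** 2).sum())
    ss_subj = float(C * ((subj_means - group_means.reindex(groups).to_numpy()) ** 2).sum())

    # condition means within each group, and their size-weighted average
    cond_in_group = pivot.groupby(groups).mean()  # G × C
    dev = cond_in_group.sub(cond_in_group.mean(axis=1), axis=0)  # ȳ_g.c − ȳ_g..
    b_c = dev.mul(n_g, axis=0).sum(axis=0) / N
    ss_within = float(N * (b_c**2).sum())
    ss_inter = float(((dev - b_c) ** 2).mul(n_g, axis=0).to_numpy().sum())

    centered = (
        pivot
        - subj_means.to_numpy()[:, None]
        - cond_in_group.reindex(groups).to_numpy()
        + cond_in_group.mean(axis=1).reindex(groups).to_numpy()[:, None]
    )
    ss_resid = float((centered.to_numpy() ** 2).sum())

    df_b, df_subj = G - 1, N - G
    df_w, df_i = C - 1, (G - 1) * (C - 1)
    df_resid = (N - G) * (C - 1)
    rows = [
        _effect_row(between, ss_between, df_b, df_subj, ss_subj),
        _error_row(f"subjects({between})", ss_subj, df_subj),
        _effect_row(within, ss_within, df_w, df_resid, ss_resid),
        _effect_row(f"{between}*{within}", ss_inter, df_i, df_resid, ss_resid),
        _error_row("residual", ss_resid, df_resid),
        _error_row("total", ss_total, N * C - 1),
    ]
    return pd.DataFrame(rows, columns=list(ANOVA_COLUMNS))


def rm_anova_dose(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "rat_id",
    within: str = "condition",
    order: Sequence | None = None,
    contrast_coding: str = "index",
) -> tuple[pd.DataFrame, dict]:
    """One-factor repeated-measures ANOVA plus a linear trend contrast.

    Every subject must have a complete series over the treatment levels
    (``order`` gives their ordering; default: order of first appearance).
    The linear contrast uses equally spaced centred coefficients over the
    ordered levels (``contrast_coding="index"``) or centred log-dose values
    (``"log"``, requires positive numeric levels); its F is the squared
    one-sample t of the per-subject contrast scores, df (1, n−1).
    """
    levels = list(order) if order is not None else list(pd.unique(data[within]))
    pivot = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    missing_levels = [lv for lv in levels if lv not in pivot.columns]
    if missing_levels:
        raise DesignError(f"levels absent from data: {missing_levels}")
    pivot = pivot[levels]
    if pivot.isna().any().any():
        bad = pivot.index[pivot.isna().any(axis=1)].tolist()
        raise DesignError(f"subjects with incomplete dose series: {bad}")
    n, C = pivot.shape
    if n < 2 or C < 2:
        raise DesignError("need at least 2 subjects and 2 treatment levels")

    Y = pivot.to_numpy(dtype=float)
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    cond_means = Y.mean(axis=0)
    ss_total = float(((Y - grand) ** 2).sum())
    ss_subj = float(C * ((subj_means - grand) ** 2).sum())
    ss_treat = float(n * ((cond_means - grand) ** 2).sum())
    ss_err = float(((Y - subj_means[:, None] - cond_means[None, :] + grand) ** 2).sum())
    df_t, df_e = C - 1, (C - 1) * (n - 1)
    table = pd.DataFrame(
        [
            _effect_row(within, ss_treat, df_t, df_e, ss_err),
            _error_row("subjects", ss_subj, n - 1),
            _error_row("residual", ss_err, df_e),
            _error_row("total", ss_total, n * C - 1),
        ],
        columns=list(ANOVA_COLUMNS),
    )

    if contrast_coding == "index":
        coef = np.arange(C, dtype=float)
    elif contrast_coding == "log":
        try:
            doses = np.array([float(lv) for lv in levels])
        except (TypeError, ValueError) as exc:
            raise ArgumentError("log contrast coding requires numeric dose levels") from exc
        if np.any(doses <= 0):
            raise ArgumentError("log contrast coding requires positive doses")
        coef = np.log(doses)
    else:
        raise ArgumentError(f"unknown contrast coding {contrast_coding!r}")
    coef = coef - coef.mean()
    scores = Y @ coef
    mean_l = scores.mean()
    var_l = scores.var(ddof=1)
    if var_l == 0:
        f_lin = 0.0 if mean_l == 0 else np.inf
    else:
        f_lin = n * mean_l**2 / var_l
    p_lin = float(stats.f.sf(f_lin, 1, n - 1)) if np.isfinite(f_lin) else 0.0
    ss_lin = n * (coef @ cond_means) ** 2 / (coef @ coef)
    contrast = {
        "F": float(f_lin),
        "df1": 1,
        "df2": n - 1,
        "p": p_lin,
        "ss": float(ss_lin),
        "eta_p2": float(f_lin / (f_lin + (n - 1))) if np.isfinite(f_lin) else 1.0,
        "coefficients": coef,
    }
    return table, contrast


def _student_max_abs_cdf(q: float, k: int, df: int, rho: float = 0.5) -> float:
    """P(max_j |T_j| <= q) for k equicorrelated t statistics sharing one
    error estimate (the Dunnett distribution)."""
    if q <= 0:
        return 0.0
    # T_j = Z_j / W with Z_j = sqrt(rho) Z0 + sqrt(1-rho) X_j, W = sqrt(chi2_df/df)
    gh_x, gh_w = roots_hermitenorm(96)  # ∫ f(z) φ(z) dz ≈ Σ w f(x) / sqrt(2π)
    gh_w = gh_w / np.sqrt(2 * np.pi)
    gl_x, gl_w = np.polynomial.legendre.leggauss(96)
    u = 0.5 * (gl_x + 1.0)
    w_nodes = stats.chi.ppf(u, df) / np.sqrt(df)
    sq = np.sqrt(1 - rho)
    sr = np.sqrt(rho)
    # inner product over z0 for each W node
    zz = gh_x[None, :]
    ww = w_nodes[:, None]
    upper = (q * ww - sr * zz) / sq
    lower = (-q * ww - sr * zz) / sq
    inner = (stats.norm.cdf(upper) - stats.norm.cdf(lower)) ** k
    per_w = inner @ gh_w
    return float(np.clip(0.5 * gl_w @ per_w, 0.0, 1.0))


def dunnett(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "rat_id",
    within: str = "condition",
    control: str = "vehicle",
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Within-subject Dunnett test: each treatment level vs a shared control.

    Paired differences (treatment − control) per subject give one t
    statistic per level (df n−1); familywise adjustment evaluates each |t|
    against the maximum of k equicorrelated (ρ=½) t variates.  With a
    single comparison the adjusted p equals the ordinary two-sided paired-t
    p.
    """
    pivot = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if control not in pivot.columns:
        raise ArgumentError(f"control level {control!r} absent from data")
    pivot = pivot.dropna()
    n = len(pivot)
    if n < 2:
        raise DesignError("need at least 2 complete subjects")
    others = [c for c in pivot.columns if c != control]
    if not others:
        raise DesignError("no treatment levels besides the control")
    k = len(others)
    df = n - 1
    rows = []
    for lev in others:
        d = (pivot[lev] - pivot[control]).to_numpy(dtype=float)
        se = d.std(ddof=1) / np.sqrt(n)
        t = d.mean() / se if se > 0 else (0.0 if d.mean() == 0 else np.inf)
        p_un = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        p_adj = 1.0 - _student_max_abs_cdf(abs(t), k, df) if np.isfinite(t) else 0.0
        rows.append(
            {
                "level": lev, "mean_diff": d.mean(), "t": float(t), "df": df,
                "p_unadjusted": p_un, "p_adjusted": float(min(1.0, p_adj)),
                "reject": bool(p_adj < alpha),
            }
        )
    return pd.DataFrame(rows)


def group_summary(
    data: pd.DataFrame,
    measures: Sequence[str],
    group: str = "group",
    condition: str = "condition",
) -> pd.DataFrame:
    """Group mean ± SEM per measure × group × condition."""
    rows = []
    for m in measures:
        agg = data.groupby([group, condition])[m].agg(["mean", "sem", "count"])
        for (g, c), r in agg.iterrows():
            rows.append(
                {
                    "measure": m, "group": g, "condition": c,
                    "mean": r["mean"], "sem": r["sem"], "n": int(r["count"]),
                }
            )
    return pd.DataFrame(rows)


def analyze_experiment(
    params: pd.DataFrame,
    breakpoints: pd.DataFrame | None = None,
    design: str = "deprivation",
    alpha: float = ALPHA_DEFAULT,
    control: str = "vehicle",
    dose_order: Sequence | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full statistical pipeline on per-rat parameter estimates.

    ``params`` has one row per rat×condition with columns rat_id, group,
    condition, t0, k, a, delta.  ``breakpoints`` (optional) is per-session
    or per-rat; session-level values are averaged per rat×condition first.
    ``design="deprivation"`` runs the 2×2 mixed ANOVA per measure with
    conditional t post hocs; ``design="dose"`` runs the repeated-measures
    ANOVA + linear contrast per measure with conditional Dunnett post hocs.

    Returns {"summary", "anova", "posthoc"} tables.
    """
    required = {"rat_id", "group", "condition", "t0", "k", "a", "delta"}
    missing = required - set(params.columns)
    if missing:
        raise ArgumentError(f"parameter table missing columns: {sorted(missing)}")
    measures = ["t0", "k", "a", "delta"]
    data = params.copy()
    if breakpoints is not None:
        bp = breakpoints.groupby(["rat_id", "group", "condition"], as_index=False)[
            "breakpoint"
        ].mean()
        data = data.merge(bp, on=["rat_id", "group", "condition"], how="left")
        if data["breakpoint"].isna().any():
            raise ArgumentError("breakpoints missing for some rat×condition cells")
        measures.append("breakpoint")

    anova_rows = []
    posthoc_rows = []
    for m in measures:
        sub = data[["rat_id", "group", "condition", m]].rename(columns={m: "value"})
        if design == "deprivation":
            table = mixed_anova_2x2(sub)
            table.insert(0, "measure", m)
            anova_rows.append(table)
            inter = table[table["effect"] == "group*condition"]
            if len(inter) and inter["p"].iloc[0] < alpha:
                posthoc_rows.extend(_deprivation_posthocs(sub, m))
        elif design == "dose":
            table, contrast = rm_anova_dose(sub, order=dose_order)
            table.insert(0, "measure", m)
            lin = pd.DataFrame(
                [
                    {
                        "measure": m, "effect": "linear_contrast",
                        "ss": contrast["ss"], "df1": contrast["df1"],
                        "df2": contrast["df2"], "ms": np.nan, "F": contrast["F"],
                        "p": contrast["p"], "eta_p2": contrast["eta_p2"],
                    }
                ]
            )
            anova_rows.append(pd.concat([table, lin], ignore_index=True))
            treat = table[table["effect"] == "condition"]
            if len(treat) and treat["p"].iloc[0] < alpha:
                dt = dunnett(sub, control=control, alpha=alpha)
                dt.insert(0, "measure", m)
                dt.insert(1, "comparison", dt.pop("level").map(lambda x: f"{x} vs {control}"))
                posthoc_rows.append(dt)
        else:
            raise ArgumentError(f"unknown design {design!r}")

    summary = group_summary(data, measures)
    anova = pd.concat(anova_rows, ignore_index=True)
    if design == "deprivation":
        posthoc = (
            pd.DataFrame(posthoc_rows)
            if posthoc_rows
            else pd.DataFrame(columns=["measure", "comparison", "test", "t", "df", "p"])
        )
    else:
        posthoc = (
            pd.concat(posthoc_rows, ignore_index=True)
            if posthoc_rows
            else pd.DataFrame(
                columns=["measure", "comparison", "mean_diff", "t", "df",
                         "p_unadjusted", "p_adjusted", "reject"]
            )
        )
    return {"summary": summary, "anova": anova, "posthoc": posthoc}


def _deprivation_posthocs(sub: pd.DataFrame, measure: str) -> list[dict]:
    """Student's t post hocs after a significant interaction: paired across
    conditions within each group, unpaired across groups within each
    condition."""
    rows = []
    conditions = list(pd.unique(sub["condition"]))
    groups = list(pd.unique(sub["group"]))
    for g in groups:
        gd = sub[sub["group"] == g].pivot_table(
            index="rat_id", columns="condition", values="value"
        ).dropna()
        for i in range(len(conditions)):
            for j in range(i + 1, len(conditions)):
                t, p = stats.ttest_rel(gd[conditions[i]], gd[conditions[j]])
                rows.append(
                    {
                        "measure": measure,
                        "comparison": f"{conditions[i]} vs {conditions[j]} in {g}",
                        "test": "paired t", "t": float(t), "df": len(gd) - 1,
                        "p": float(p),
                    }
                )
    for c in conditions:
        cd = sub[sub["condition"] == c]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                x = cd[cd["group"] == groups[i]]["value"]
                y = cd[cd["group"] == groups[j]]["value"]
                t, p = stats.ttest_ind(x, y)
                rows.append(
                    {
                        "measure": measure,
                        "comparison": f"{groups[i]} vs {groups[j]} under {c}",
                        "test": "unpaired t", "t": float(t),
                        "df": len(x) + len(y) - 2, "p": float(p),
                    }
                )
    return rows
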