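"""Group statistics and the chloroquine flux-assessment logic.

The unit of analysis is the islet.  Single-factor designs use one-way
ANOVA with Tukey HSD post hoc contrasts; group x treatment designs use
two-way ANOVA (type-II sums of squares) with Sidak-adjusted within-group
treatment contrasts; simple two-sample questions use the unpaired t test.
Autophagic flux is called *intact* for a group when the chloroquine arm
shows a significant increase of the marker density over the untreated arm
(Sidak-adjusted within the two-way model), and *impaired* otherwise:
a lysosomal blocker can only pile up autophagosomes/p62 if the degradation
pathway was running.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA_DEFAULT = 0.05


@dataclasses.dataclass(frozen=True)
class ComparisonTable:
    """ANOVA summary plus post hoc contrasts.

    ``omnibus`` has one row per model term (sum_sq, df, F, p); ``contrasts``
    one row per pairwise comparison (estimate = difference of means, the
    test statistic, unadjusted and adjusted p, and the adjustment method).
    """

    omnibus: pd.DataFrame
    contrasts: pd.DataFrame
    adjustment: str


@dataclasses.dataclass(frozen=True)
class FluxCall:
    group: str
    delta_puncta: float  # chloroquine-minus-baseline mean density
    p_adjusted: float
    call: str  # intact | impaired
    flag_degenerate: bool = False


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def sem(values) -> float:
    """Standard error of the mean (ddof=1)."""
    arr = _clean(values)
    if arr.size < 2:
        return float("nan")
    return float(np.std(arr, ddof=1) / np.sqrt(arr.size))


def sidak_adjust(p: float | np.ndarray, m: int) -> np.ndarray | float:
    """Sidak familywise adjustment: 1 - (1 - p)^m, capped at 1."""
    return np.minimum(1.0, 1.0 - (1.0 - np.asarray(p)) ** m)


def one_way_anova_tukey(
    frame: pd.DataFrame,
    value: str,
    factor: str,
    alpha: float = ALPHA_DEFAULT,
    posthoc: bool = True,
) -> ComparisonTable:
    """One-way ANOVA with all pairwise Tukey HSD contrasts.

    ``posthoc=False`` skips the Tukey table (empty contrasts frame), which
    is much faster when only the omnibus test is needed, e.g. in
    simulation loops.
    """
    data = frame[[value, factor]].dropna()
    groups = [g[value].to_numpy(dtype=float) for _, g in data.groupby(factor, observed=True)]
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two observations")

    grand = data[value].mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(data) - len(groups)
    if ss_within == 0:
        f_stat, p = (np.inf, 0.0) if ss_between > 0 else (0.0, 1.0)
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    omnibus = pd.DataFrame(
        {
            "term": [factor, "residual"],
            "sum_sq": [ss_between, ss_within],
            "df": [df_b, df_w],
            "F": [f_stat, np.nan],
            "p": [p, np.nan],
        }
    )

    if not posthoc:
        return ComparisonTable(omnibus=omnibus, contrasts=pd.DataFrame(), adjustment="tukey")

    hsd = pairwise_tukeyhsd(data[value].to_numpy(dtype=float), data[factor].to_numpy(), alpha=alpha)
    res = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    contrasts = pd.DataFrame(
        {
            "contrast": res["group2"].astype(str) + " - " + res["group1"].astype(str),
            "estimate": res["meandiff"].astype(float),
            "statistic": np.asarray(hsd.meandiffs) / np.asarray(hsd.std_pairs),
            "p_adj": res["p-adj"].astype(float),
            "method": "tukey",
        }
    )
    return ComparisonTable(omnibus=omnibus, contrasts=contrasts, adjustment="tukey")


def _two_way_fit(frame: pd.DataFrame, value: str, group: str, treatment: str):
    data = frame[[value, group, treatment]].dropna().copy()
    cells = data.groupby([group, treatment], observed=True).size()
    if (cells < 1).any() or cells.index.nlevels != 2:
        raise ValueError("two-way design has an empty cell")
    n_groups = data[group].nunique()
    n_treat = data[treatment].nunique()
    if n_groups < 2 or n_treat < 2:
        raise ValueError("both factors need at least two levels")
    model = smf.ols(f"Q('{value}') ~ C(Q('{group}')) * C(Q('{treatment}'))", data=data).fit()
    return data, model


def two_way_anova_sidak(
    frame: pd.DataFrame,
    value: str,
    group: str = "group",
    treatment: str = "treatment",
    baseline_level: str = "none",
    ss_type: int = 2,
) -> ComparisonTable:
    """Two-way ANOVA (main effects + interaction) with Sidak post hoc contrasts.

    The post hoc family is the within-group treatment comparison (e.g. CQ vs
    untreated inside each disease group): each contrast uses the pooled
    residual variance of the full factorial model, and p-values are Sidak
    adjusted over the number of groups.  Type-II sums of squares by default,
    which tolerates unbalanced islet counts.
    """
    data, model = _two_way_fit(frame, value, group, treatment)
    if model.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    degenerate = model.mse_resid <= 0 or not np.isfinite(model.mse_resid)
    if degenerate:
        omnibus = pd.DataFrame(
            {"term": ["residual"], "sum_sq": [0.0], "df": [model.df_resid], "F": [np.nan], "p": [np.nan]}
        )
    else:
        aov = sm.stats.anova_lm(model, typ=ss_type)
        omnibus = aov.reset_index().rename(
            columns={"index": "term", "PR(>F)": "p", "df": "df", "sum_sq": "sum_sq"}
        )

    mse = float(model.mse_resid)
    df_resid = float(model.df_resid)
    levels = sorted(data[group].unique())
    treat_levels = set(data[treatment].unique())
    others = sorted(treat_levels - {baseline_level})
    if baseline_level not in treat_levels or len(others) != 1:
        raise ValueError(
            f"expected exactly two treatment levels including {baseline_level!r}, got {sorted(treat_levels)}"
        )
    treated_level = others[0]

    rows = []
    m = len(levels)
    for g in levels:
        base = data.loc[(data[group] == g) & (data[treatment] == baseline_level), value]
        trt = data.loc[(data[group] == g) & (data[treatment] == treated_level), value]
        if len(base) == 0 or len(trt) == 0:
            raise ValueError(f"group {g!r} is missing one treatment arm")
        delta = float(trt.mean() - base.mean())
        if degenerate:
            t_stat = np.inf if delta != 0 else 0.0
            p_unadj = 0.0 if delta != 0 else 1.0
        else:
            se = np.sqrt(mse * (1.0 / len(base) + 1.0 / len(trt)))
            t_stat = delta / se
            p_unadj = float(2.0 * stats.t.sf(abs(t_stat), df_resid))
        rows.append(
            {
                "contrast": f"{g}: {treated_level} - {baseline_level}",
                "group": g,
                "estimate": delta,
                "statistic": t_stat,
                "p_unadj": p_unadj,
                "p_adj": float(sidak_adjust(p_unadj, m)),
                "method": "sidak",
            }
        )
    return ComparisonTable(omnibus=omnibus, contrasts=pd.DataFrame(rows), adjustment="sidak")


def unpaired_t(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided unpaired t test (pooled by default, Welch optional).

    Two constant samples with equal means return (0, 1) by convention.
    """
    a, b = _clean(a), _clean(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t_stat), float(p)


def fold_change(
    baseline: pd.DataFrame,
    treated: pd.DataFrame,
    value: str,
    group: str = "group",
    per_subject: bool = False,
) -> pd.DataFrame:
    """Fold change of each treated islet over its group's baseline mean.

    Returns one row per treated islet (``fold``) plus, merged in, the group
    summary columns ``fold_mean`` and ``fold_sem``.  A group with baseline
    mean 0 is flagged undefined (NaN fold) rather than dropped silently.
    With ``per_subject=True`` the baseline mean is taken per subject first
    and then averaged, weighting animals equally.
    """
    rows = []
    for g, treated_g in treated.groupby(group, observed=True):
        base_g = baseline.loc[baseline[group] == g, :]
        if len(base_g) == 0 or len(treated_g) == 0:
            raise ValueError(f"group {g!r} lacks a baseline or treated arm")
        if per_subject and "subject_id" in base_g.columns:
            base_mean = base_g.groupby("subject_id")[value].mean().mean()
        else:
            base_mean = base_g[value].mean()
        for _, rec in treated_g.iterrows():
            fold = rec[value] / base_mean if base_mean > 0 else np.nan
            rows.append({group: g, "value": rec[value], "baseline_mean": base_mean, "fold": fold})
    out = pd.DataFrame(rows)
    summary = out.groupby(group, observed=True)["fold"].agg(fold_mean="mean", fold_sem=sem)
    return out.merge(summary, on=group)


def fold_change_p62(baseline: pd.DataFrame, cq: pd.DataFrame, group: str = "group") -> pd.DataFrame:
    """p62 puncta-density fold change under chloroquine, per group."""
    return fold_change(baseline, cq, value="density_p62_per_um2", group=group)


def assess_flux(
    frame: pd.DataFrame,
    value: str,
    group: str = "group",
    treatment: str = "treatment",
    baseline_level: str = "none",
    alpha: float = ALPHA_DEFAULT,
) -> list[FluxCall]:
    """Call autophagic flux intact or impaired per group.

    A group is *intact* iff its chloroquine arm shows a Sidak-adjusted
    significant *increase* in the marker density over its untreated arm;
    anything else (no change, a decrease, or a non-significant change) is
    *impaired*.  Requires at least two islets per arm.  A degenerate fit
    (zero residual variance, e.g. all-zero densities) is flagged.
    """
    counts = frame.dropna(subset=[value]).groupby([group, treatment], observed=True).size()
    if (counts < 2).any():
        small = counts[counts < 2]
        raise ValueError(f"insufficient islets per arm: {small.to_dict()}")
    table = two_way_anova_sidak(
        frame, value, group=group, treatment=treatment, baseline_level=baseline_level
    )
    degenerate = bool(
        table.omnibus["F"].isna().all() or not np.isfinite(table.contrasts["statistic"]).all()
    )
    calls = []
    for _, row in table.contrasts.iterrows():
        intact = row["estimate"] > 0 and row["p_adj"] < alpha
        calls.append(
            FluxCall(
                group=row["group"],
                delta_puncta=float(row["estimate"]),
                p_adjusted=float(row["p_adj"]),
                call="intact" if intact else "impaired",
                flag_degenerate=degenerate,
            )
        )
    return calls


def group_summary(frame: pd.DataFrame, value: str, by: list[str]) -> pd.DataFrame:
    """Mean +/- SEM and n per group cell, excluding flagged-missing values."""
    return (
        frame.groupby(by, observed=True)[value]
        .agg(mean="mean", sem=sem, n="count")
        .reset_index()
    )
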