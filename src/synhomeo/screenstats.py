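"""Statistical layer for screen hit calling and group comparisons.

Covers the hit-calling volcano (one-way ANOVA with Tukey HSD against the
PhTX-treated wild-type reference), factorial genotype x condition ANOVA with
Tukey post hoc pairs, a normality/variance-gated two-group comparison, and
power-based minimum sample size for two-sample t designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TwoGroupResult",
    "hit_rate_percent",
    "volcano_screen",
    "twoway_php_test",
    "compare_two",
    "power_two_sample_t",
    "min_n_power",
]


def hit_rate_percent(n_flagged: int, n_total: int) -> int:
    """Screen hit rate as a whole percent (truncated, not rounded)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return int(100 * n_flagged / n_total)


def volcano_screen(
    table: pd.DataFrame,
    alpha_flag: float = 0.01,
    reference_line: str = "WT",
    reference_condition: str = "PhTX",
    modality: str = "EPSC",
) -> pd.DataFrame:
    """Call screen hits against the PhTX-treated wild-type reference.

    One pooled one-way ANOVA is fit over the evoked-amplitude groups of all
    lines plus the reference; each line is then compared to the reference
    with the Tukey HSD (Tukey-Kramer for unequal n) adjustment, i.e. the
    studentized-range distribution with the pooled error variance.

    Returns one row per line: ratio (line mean / reference mean),
    Tukey-adjusted p, and flag in {smaller, larger, ns} where a flag
    requires p_adj <= alpha_flag.
    """
    sub = table[table["modality"] == modality]
    ref_mask = (sub["line_id"] == reference_line) & (sub["condition"] == reference_condition)
    ref = sub.loc[ref_mask, "value"].to_numpy(dtype=float)
    if ref.size == 0:
        raise ValueError("reference group missing from table")
    lines = sorted(x for x in sub["line_id"].unique() if x != reference_line)
    groups = {li: sub.loc[sub["line_id"] == li, "value"].to_numpy(dtype=float) for li in lines}

    all_groups = [ref] + [groups[li] for li in lines]
    k = len(all_groups)
    ns = np.array([len(g) for g in all_groups])
    means = np.array([g.mean() for g in all_groups])
    df_err = int(ns.sum() - k)
    sse = sum(float(((g - g.mean()) ** 2).sum()) for g in all_groups)
    mse = sse / df_err

    line_ns = ns[1:]
    line_means = means[1:]
    se = np.sqrt(mse / 2.0 * (1.0 / line_ns + 1.0 / ref.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.abs(line_means - ref.mean()) / se
    p_adj = stats.studentized_range.sf(q, k, df_err)
    p_adj = np.clip(np.nan_to_num(p_adj, nan=1.0), 0.0, 1.0)

    ratio = line_means / ref.mean()
    flag = np.where(
        p_adj <= alpha_flag, np.where(ratio < 1.0, "smaller", "larger"), "ns"
    )
    return pd.DataFrame({"line_id": lines, "ratio": ratio, "p_adj": p_adj, "flag": flag})


def twoway_php_test(
    values, genotype, condition, alpha: float = 0.05
) -> dict:
    """Two-way genotype x condition ANOVA with Tukey post hoc pairs.

    Type-II sums of squares are used so unbalanced designs are handled
    sensibly. Returns the ANOVA table, the Tukey comparison frame over
    genotype:condition cells, and a degenerate flag (all observations
    equal -> p = 1 with warning).
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "genotype": pd.Categorical(genotype),
            "condition": pd.Categorical(condition),
        }
    )
    cells = df.groupby(["genotype", "condition"], observed=True)["value"].count()
    full = len(df["genotype"].cat.categories) * len(df["condition"].cat.categories)
    if len(cells) < full or (cells < 2).any():
        raise ValueError("every genotype x condition cell needs >= 2 observations")

    if np.ptp(df["value"].to_numpy()) == 0:
        warnings.warn("all observations identical: tests degenerate", RuntimeWarning, stacklevel=2)
        idx = ["C(genotype)", "C(condition)", "C(genotype):C(condition)", "Residual"]
        anova = pd.DataFrame({"F": [np.nan] * 4, "PR(>F)": [1.0, 1.0, 1.0, np.nan]}, index=idx)
        return {"anova": anova, "tukey": None, "degenerate": True}

    model = smf.ols("value ~ C(genotype) * C(condition)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    group = df["genotype"].astype(str) + ":" + df["condition"].astype(str)
    tukey = pairwise_tukeyhsd(df["value"].to_numpy(), group.to_numpy(), alpha=alpha)
    tukey_df = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    return {"anova": anova, "tukey": tukey_df, "degenerate": False}


@dataclass(frozen=True)
class TwoGroupResult:
    """Outcome of the gated two-group comparison."""

    test_used: str  # student_t | welch_t | mann_whitney
    p: float
    statistic: float
    normality_p: tuple  # Shapiro-Wilk p per group (None when undefined)
    levene_p: float | None
    notes: str = ""


def compare_two(x, y, alpha_gate: float = 0.05) -> TwoGroupResult:
    """Two-group comparison gated on normality and variance homogeneity.

    Shapiro-Wilk is run on each group; if either rejects at ``alpha_gate``
    (or is undefined for a zero-variance group) the Mann-Whitney U test is
    used. Otherwise Levene's test decides between Student's t (homogeneous
    variances) and Welch's t. All tests are two-sided. The Welch fallback
    when only variance homogeneity fails is a convention choice recorded in
    the result notes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs n >= 3")

    sw_p = []
    degenerate = False
    for g in (x, y):
        if np.ptp(g) == 0:
            sw_p.append(None)
            degenerate = True
        else:
            sw_p.append(float(stats.shapiro(g).pvalue))

    if degenerate:
        warnings.warn("zero-variance group: falling back to Mann-Whitney", RuntimeWarning, stacklevel=2)
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        return TwoGroupResult("mann_whitney", float(p), float(stat), tuple(sw_p), None,
                              notes="zero-variance group")
    levene_p = float(stats.levene(x, y).pvalue)
    if min(sw_p) < alpha_gate:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        return TwoGroupResult("mann_whitney", float(p), float(stat), tuple(sw_p), levene_p)
    if levene_p < alpha_gate:
        res = stats.ttest_ind(x, y, equal_var=False)
        return TwoGroupResult("welch_t", float(res.pvalue), float(res.statistic), tuple(sw_p),
                              levene_p, notes="Welch fallback: variance gate failed")
    res = stats.ttest_ind(x, y, equal_var=True)
    return TwoGroupResult("student_t", float(res.pvalue), float(res.statistic), tuple(sw_p), levene_p)


def power_two_sample_t(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test, n per group, effect size d.

    Evaluated from the noncentral t distribution with df = 2n - 2 and
    noncentrality d * sqrt(n / 2).
    """
    if n < 2:
        return 0.0
    df = 2 * n - 2
    nc = d * np.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def min_n_power(cohens_d: float, power: float = 0.8, alpha: float = 0.05) -> int:
    """Smallest per-group n for which the two-sample t-test reaches power.

    Searches upward from n = 2 (the smallest design with positive df).
    """
    if cohens_d <= 0:
        raise ValueError("cohens_d must be positive")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    n = 2
    while power_two_sample_t(n, cohens_d, alpha) < power:
        n += 1
        if n > 10**6:
            raise RuntimeError("sample size search did not converge")
    return n
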