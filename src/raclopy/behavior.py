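"""Mixed-design ANOVA, effect sizes, and screening for behavioral tables.

The training study's behavioral analyses are 2 (group: training vs
control) × 2 (time: pre vs post) split-plot ANOVAs on task scores, with
partial eta squared and Cohen's d as effect sizes, pooled-variance t tests
on baseline group differences (computable directly from printed summary
statistics), and a 3×IQR rule for removing extreme outliers before
analysis.

For a 2×2 split-plot design the sums of squares decompose exactly through
the per-subject sum and difference scores: the group effect is a
two-sample comparison of subject means, and the time and interaction
effects are two-sample comparisons of change scores — which is also what
makes the ANOVA well defined for (mildly) unbalanced groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectStats",
    "remove_extreme_outliers",
    "mixed_anova_2x2",
    "partial_eta_squared",
    "cohens_d_from_f",
    "two_sample_t_pooled",
]


@dataclass(frozen=True)
class EffectStats:
    """One ANOVA effect: F(df1, df2), p, and standardized effect sizes."""

    F: float
    df1: int
    df2: int
    p: float
    eta_sq_partial: float
    cohens_d: float
    ss_effect: float
    ss_error: float


def remove_extreme_outliers(values, factor: float = 3.0):
    """Drop values deviating at least ``factor`` × IQR beyond the quartiles.

    Quartiles use linear interpolation (the type-7 estimator).  Removal is
    single-pass: fences are computed once from all values.  Returns
    ``(kept_values, removed_indices)``.  A degenerate IQR of zero with
    non-constant data removes nothing (with a warning) rather than
    flagging every off-median value.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 4:
        raise ValueError("need at least 4 observations in a 1-D array")
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        if not np.all(arr == arr[0]):
            warnings.warn("IQR is zero for non-constant data; no outliers "
                          "removed", RuntimeWarning, stacklevel=2)
        return arr.copy(), np.array([], dtype=int)
    lo = q1 - factor * iqr
    hi = q3 + factor * iqr
    removed = np.where((arr < lo) | (arr > hi))[0]
    kept = np.delete(arr, removed)
    return kept, removed


def _f_effect(contrast: float, se2: float, ms_error: float, ss_scale: float,
              df2: int) -> EffectStats:
    F = contrast ** 2 / se2
    ss_effect = contrast ** 2 / ss_scale
    ss_error = ms_error * df2
    p = float(stats.f.sf(F, 1, df2))
    return EffectStats(F=float(F), df1=1, df2=df2, p=p,
                       eta_sq_partial=partial_eta_squared(F, 1, df2),
                       cohens_d=cohens_d_from_f(F, df2),
                       ss_effect=float(ss_effect), ss_error=float(ss_error))


def mixed_anova_2x2(table: pd.DataFrame,
                    subject: str = "subject",
                    group: str = "group",
                    time: str = "time",
                    score: str = "score") -> dict[str, EffectStats]:
    """Split-plot ANOVA for two groups × two repeated time points.

    Expects a long-format table with one row per (subject, time).  Every
    subject must have both time points and at least two subjects per group
    are required.  Returns effects keyed ``"group"``, ``"time"`` and
    ``"interaction"`` (Type III tests; identical to the classical sums of
    squares decomposition for balanced tables).
    """
    df = table[[subject, group, time, score]].dropna()
    times = sorted(df[time].unique())
    groups = sorted(df[group].unique())
    if len(times) != 2 or len(groups) != 2:
        raise ValueError("exactly two time points and two groups required")
    wide = df.pivot_table(index=[subject, group], columns=time,
                          values=score, aggfunc="mean")
    missing = wide[wide.isna().any(axis=1)].index.get_level_values(0).tolist()
    if missing:
        raise ValueError(f"subjects missing a time point: {missing}")
    wide = wide.reset_index()
    g1 = wide[wide[group] == groups[0]]
    g2 = wide[wide[group] == groups[1]]
    n1, n2 = len(g1), len(g2)
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 subjects per group")
    t0, t1 = times
    d1 = (g1[t1] - g1[t0]).to_numpy()      # change scores
    d2 = (g2[t1] - g2[t0]).to_numpy()
    m1 = ((g1[t0] + g1[t1]) / 2).to_numpy()  # subject means
    m2 = ((g2[t0] + g2[t1]) / 2).to_numpy()
    n = n1 + n2
    df2 = n - 2
    inv_n = 1.0 / n1 + 1.0 / n2

    # Within-subject error: pooled variance of change scores (the error SS
    # in the original metric is half the change-score SS for 2 time points).
    s2_d = (np.sum((d1 - d1.mean()) ** 2)
            + np.sum((d2 - d2.mean()) ** 2)) / df2
    ms_err_w = s2_d / 2.0
    # Between-subject error: pooled variance of subject means, times 2.
    s2_m = (np.sum((m1 - m1.mean()) ** 2)
            + np.sum((m2 - m2.mean()) ** 2)) / df2
    ms_err_b = 2.0 * s2_m

    eps = np.finfo(float).tiny
    effects = {
        "group": _f_effect(
            contrast=m1.mean() - m2.mean(),
            se2=max(s2_m * inv_n, eps),
            ms_error=ms_err_b, ss_scale=inv_n / 2.0, df2=df2),
        "time": _f_effect(
            contrast=(d1.mean() + d2.mean()) / 2.0,
            se2=max(s2_d * inv_n / 4.0, eps),
            ms_error=ms_err_w, ss_scale=inv_n / 2.0, df2=df2),
        "interaction": _f_effect(
            contrast=d1.mean() - d2.mean(),
            se2=max(s2_d * inv_n, eps),
            ms_error=ms_err_w, ss_scale=inv_n * 2.0, df2=df2),
    }
    return effects


def partial_eta_squared(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F statistic: F·df1 / (F·df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("F must be non-negative and dfs positive")
    return F * df1 / (F * df1 + df2)


def cohens_d_from_f(F: float, df_error: int) -> float:
    """Cohen's d for a one-df effect: d = 2·sqrt(F / df_error)."""
    if F < 0 or df_error <= 0:
        raise ValueError("F must be non-negative and df_error positive")
    return 2.0 * np.sqrt(F / df_error)


def two_sample_t_pooled(mean_a: float, sd_a: float, n_a: int,
                        mean_b: float, sd_b: float, n_b: int):
    """Pooled-variance independent-samples t from summary statistics.

    Accepts printed group means/SDs directly.  Returns ``(t, df, p)`` with
    ``df = n_a + n_b - 2`` and a two-sided p.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("SDs must be non-negative")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a ** 2 + (n_b - 1) * sd_b ** 2) / df
    if sp2 == 0:
        if mean_a == mean_b:
            return 0.0, df, 1.0
        raise ValueError("zero variance with unequal means: t is undefined")
    t = (mean_a - mean_b) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p
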