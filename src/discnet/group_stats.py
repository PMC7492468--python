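"""Group-difference statistics: two-way fixed-effects ANOVA with Tukey HSD.

The ANOVA uses Type III sums of squares with sum-to-zero contrasts (the
convention of the commercial packages common in this field, and the sensible
choice for the mildly unbalanced n = 11-12 cells that attrition produces);
Type II is available as an option.  Tukey's post-hoc test uses the
studentized-range distribution with the Tukey-Kramer correction for unequal
cell sizes.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import studentized_range
import statsmodels.api as sm
import statsmodels.formula.api as smf


class StatsError(ValueError):
    pass


@dataclass
class AnovaResult:
    factor_a: str
    factor_b: str
    table: pd.DataFrame       # term, sum_sq, df, F, p
    cell_stats: pd.DataFrame  # factor levels, n, mean, sd
    tukey: pd.DataFrame       # pair, mean difference, q, adjusted p
    mse: float
    df_error: float


def group_summary(df: pd.DataFrame, value: str, by) -> pd.DataFrame:
    """Per-group n (non-missing), mean, SD and missing count."""
    if isinstance(by, str):
        by = [by]
    recs = []
    for keys, g in df.groupby(by, dropna=False, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        v = g[value]
        recs.append({**dict(zip(by, keys)),
                     "n": int(v.notna().sum()),
                     "mean": v.mean(), "sd": v.std(ddof=1),
                     "n_missing": int(v.isna().sum())})
    return pd.DataFrame(recs)


def tukey_hsd(cell_means: dict, cell_ns: dict, mse: float,
              df_error: float) -> pd.DataFrame:
    """Tukey(-Kramer) pairwise comparisons from cell summaries.

    The adjusted p-value is ``P(Q >= q)`` under the studentized-range
    distribution with ``k`` groups and ``df_error`` error degrees of freedom,
    where ``q = |m_i - m_j| / sqrt(mse/2 * (1/n_i + 1/n_j))``.
    """
    if df_error <= 0:
        raise StatsError("df_error must be positive")
    cells = sorted(cell_means)
    if len(cells) < 2:
        raise StatsError("Tukey needs at least two cells")
    k = len(cells)
    recs = []
    for a, b in combinations(cells, 2):
        diff = cell_means[a] - cell_means[b]
        se = np.sqrt(mse / 2.0 * (1.0 / cell_ns[a] + 1.0 / cell_ns[b]))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(studentized_range.sf(q, k, df_error))
        recs.append(dict(group_a=a, group_b=b, mean_diff=diff, q=q, p_adj=p))
    return pd.DataFrame(recs)


def two_way_anova(df: pd.DataFrame, value: str, factor_a: str, factor_b: str,
                  ss_type: int = 3) -> AnovaResult:
    """Two-factor fixed-effects ANOVA with interaction, plus Tukey table.

    Requires at least two levels per factor and no empty cell.  Returns the
    full ANOVA table (Type III by default, on sum-to-zero contrasts), cell
    summaries, and all-pairs Tukey-Kramer comparisons over the ``a x b``
    cells.
    """
    d = df[[value, factor_a, factor_b]].dropna().copy()
    for f in (factor_a, factor_b):
        if d[f].nunique() < 2:
            raise StatsError(f"factor {f!r} needs >= 2 levels with data")
    counts = d.groupby([factor_a, factor_b], sort=True).size()
    full = pd.MultiIndex.from_product([d[factor_a].unique(), d[factor_b].unique()])
    for cell in full:
        if cell not in counts.index or counts[cell] == 0:
            raise StatsError(f"empty cell {cell} for {value!r}")
    if (counts >= 2).sum() < 1:
        raise StatsError("need at least one cell with >= 2 observations")

    d = d.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a, Sum) * C(_b, Sum)", data=d).fit()
    aov = sm.stats.anova_lm(model, typ=ss_type)
    aov = aov.rename(index={
        "C(_a, Sum)": factor_a, "C(_b, Sum)": factor_b,
        "C(_a, Sum):C(_b, Sum)": f"{factor_a}:{factor_b}",
        "Residual": "residual"})
    if "Intercept" in aov.index:
        aov = aov.drop(index="Intercept")
    table = (aov.reset_index().rename(columns={
        "index": "term", "sum_sq": "sum_sq", "F": "F", "PR(>F)": "p"}))

    mse = float(aov.loc["residual", "sum_sq"] / aov.loc["residual", "df"])
    df_error = float(aov.loc["residual", "df"])

    cell_stats = group_summary(
        d.rename(columns={"_a": factor_a, "_b": factor_b}), "_y",
        [factor_a, factor_b]).rename(columns={"_y": value})
    means = {(r[factor_a], r[factor_b]): r["mean"] for _, r in cell_stats.iterrows()}
    ns = {(r[factor_a], r[factor_b]): r["n"] for _, r in cell_stats.iterrows()}
    tukey = tukey_hsd(means, ns, mse, df_error)
    return AnovaResult(factor_a, factor_b, table, cell_stats, tukey, mse, df_error)
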