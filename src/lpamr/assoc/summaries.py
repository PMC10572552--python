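"""ANOVA and t-tests computed from group summary statistics (n, mean, SD).

Published baseline tables report groups as mean +/- SD; these routines
recover the exact one-way ANOVA F and two-sample t statistics from those
summaries alone, which equal the statistics on any raw dataset with the
same moments.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def summary_anova(groups: Sequence[GroupSummary]) -> tuple[float, int, int, float]:
    """One-way ANOVA from (n, mean, sd) summaries.

    Between-group SS from the group means about the grand mean; within-group
    SS from the group SDs. Returns ``(F, df1, df2, pval)``.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    n_total = ns.sum()
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds ** 2).sum())
    df1 = len(groups) - 1
    df2 = int(n_total) - len(groups)
    if ss_within == 0:
        return (0.0, df1, df2, 1.0) if ss_between == 0 else (np.inf, df1, df2, 0.0)
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


def summary_ttest(
    a: GroupSummary, b: GroupSummary, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test from summaries; pooled variance or Welch.

    Returns ``(t, df, pval)``. Welch uses the Satterthwaite df.
    """
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    if welch:
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    else:
        sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / (a.n + b.n - 2)
        se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = a.n + b.n - 2
    if se == 0:
        return (0.0, float(df), 1.0) if a.mean == b.mean else (np.inf, float(df), 0.0)
    t = (a.mean - b.mean) / se
    return float(t), float(df), float(2 * stats.t.sf(abs(t), df))
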