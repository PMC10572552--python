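"""Genotype-by-risk-stratum count tables and the association tests run on them.

Lp(a) risk strata follow the clinical convention: low < 9.4 mg/dL,
average 9.4-30 mg/dL, high > 30 mg/dL (hyperlipoproteinemia(a)).
Genotypes are AA / AG / GG for a biallelic A>G variant; because GG
homozygotes are typically rare, carrier analyses pool AG with GG.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPES = ("AA", "AG", "GG")
STRATA = ("low", "average", "high")

# Lp(a) mg/dL stratum bounds: low [0, 9.4), average [9.4, 30], high (30, inf)
LOW_UPPER = 9.4
AVERAGE_UPPER = 30.0


@dataclass(frozen=True)
class RiskCategory:
    label: str
    lower: float
    upper: float  # inclusive upper for "average", open elsewhere


RISK_CATEGORIES = {
    "low": RiskCategory("low", 0.0, LOW_UPPER),
    "average": RiskCategory("average", LOW_UPPER, AVERAGE_UPPER),
    "high": RiskCategory("high", AVERAGE_UPPER, math.inf),
}


def classify_lpa(lpa: float) -> str:
    """Map an Lp(a) level (mg/dL) to its risk stratum label.

    The average stratum is the closed interval [9.4, 30]; levels above
    30 mg/dL define hyperlipoproteinemia(a).
    """
    if lpa < 0:
        raise ValueError(f"Lp(a) level must be non-negative, got {lpa}")
    if lpa < LOW_UPPER:
        return "low"
    if lpa <= AVERAGE_UPPER:
        return "average"
    return "high"


class GenotypeCountTable:
    """3x3 table of genotype (AA/AG/GG) by Lp(a) risk stratum counts."""

    def __init__(self, counts) -> None:
        df = pd.DataFrame(counts, index=list(GENOTYPES), columns=list(STRATA))
        arr = df.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            df = df.astype(int)
        self.counts = df

    @classmethod
    def from_csv(cls, path) -> "GenotypeCountTable":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.str.strip()
        missing = [g for g in GENOTYPES if g not in df.index]
        if missing:
            raise ValueError(f"count table missing genotype rows: {missing}")
        return cls(df.loc[list(GENOTYPES), list(STRATA)])

    def to_csv(self, path) -> None:
        self.counts.rename_axis("genotype").to_csv(path)

    @property
    def stratum_n(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total_n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def genotype_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def carrier_table(self) -> pd.DataFrame:
        """2 x strata table of G-allele carriers (AG+GG) versus AA."""
        carriers = self.counts.loc["AG"] + self.counts.loc["GG"]
        return pd.DataFrame({"carrier": carriers, "AA": self.counts.loc["AA"]}).T

    def allele_table(self) -> pd.DataFrame:
        """2 x strata table of G versus A allele counts."""
        g = self.counts.loc["AG"] + 2 * self.counts.loc["GG"]
        a = 2 * self.counts.loc["AA"] + self.counts.loc["AG"]
        return pd.DataFrame({"G": g, "A": a}).T


def allele_stats(table: GenotypeCountTable) -> pd.DataFrame:
    """Per-stratum and overall allele counts, frequencies and carrier rates.

    The G (minor) allele count per stratum is AG + 2*GG and its frequency
    divides by twice the stratum size.
    """
    counts = table.counts
    strata = list(STRATA) + ["total"]
    rows = []
    totals = counts.sum(axis=1)
    for s in strata:
        col = totals if s == "total" else counts[s]
        n = int(col.sum())
        g = int(col["AG"] + 2 * col["GG"])
        carriers = int(col["AG"] + col["GG"])
        rows.append(
            {
                "stratum": s,
                "n": n,
                "g_count": g,
                "a_count": 2 * n - g,
                "g_freq": g / (2 * n) if n else float("nan"),
                "carrier_freq": carriers / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


def hwe_test(aa: int, ag: int, gg: int, method: str = "chisq") -> tuple[float, float]:
    """Hardy–Weinberg equilibrium test from genotype counts.

    ``chisq``: 1-df goodness of fit of observed counts against the
    p^2 / 2pq / q^2 expectation at the sample allele frequencies (no
    continuity correction). ``exact``: full enumeration over heterozygote
    counts compatible with the observed allele counts, summing the
    probabilities of outcomes no more probable than the observed one.

    Returns ``(statistic, pval)``; the statistic is NaN for the exact test.
    """
    if min(aa, ag, gg) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = aa + ag + gg
    if n < 1:
        raise ValueError("need at least one genotype")
    n_g = ag + 2 * gg
    n_a = 2 * n - n_g
    if method == "chisq":
        q = n_g / (2 * n)
        p = 1 - q
        expected = np.array([p * p, 2 * p * q, q * q]) * n
        if (expected == 0).any():  # monomorphic
            return 0.0, 1.0
        observed = np.array([aa, ag, gg])
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        return chi2, float(stats.chi2.sf(chi2, 1))
    if method == "exact":
        if n_g == 0 or n_a == 0:
            return float("nan"), 1.0
        rare = min(n_g, n_a)
        # P(het = h | allele counts) up to a constant; h has the parity of rare
        hs = np.arange(rare % 2, rare + 1, 2)
        logp = np.array(
            [
                -math.lgamma((rare - h) / 2 + 1)
                - math.lgamma(h + 1)
                - math.lgamma((2 * n - rare - h) / 2 + 1)
                + h * math.log(2)
                for h in hs
            ]
        )
        prob = np.exp(logp - logp.max())
        prob /= prob.sum()
        obs_het = ag
        p_obs = prob[hs == obs_het][0]
        pval = float(prob[prob <= p_obs + 1e-12].sum())
        return float("nan"), min(1.0, pval)
    raise ValueError(f"method must be 'chisq' or 'exact', got {method!r}")


def chi_square_independence(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No Yates continuity correction by default. Returns (statistic, df, pval).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    chi2, pval, df, _ = stats.chi2_contingency(arr, correction=yates)
    return float(chi2), int(df), float(pval)


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with Wald (Woolf) 95% confidence interval."""

    or_: float
    ci_low: float
    ci_high: float
    pval: float

    def __post_init__(self) -> None:
        if not 0 < self.ci_low <= self.or_ <= self.ci_high:
            raise ValueError("confidence interval must bracket the odds ratio")


def crude_or(
    table: GenotypeCountTable,
    stratum: str,
    reference: str = "low",
    haldane: bool = False,
) -> ORResult:
    """Crude carrier-vs-AA odds ratio of ``stratum`` membership versus ``reference``.

    Cross-product odds ratio of the 2x2 (carrier, AA) x (stratum, reference)
    table with a Woolf log-scale Wald 95% CI. ``haldane`` adds 0.5 to every
    cell (required when a cell is zero).
    """
    ct = table.carrier_table()
    a = float(ct.loc["carrier", stratum])
    b = float(ct.loc["AA", stratum])
    c = float(ct.loc["carrier", reference])
    d = float(ct.loc["AA", reference])
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        raise ValueError(
            "zero cell in the 2x2 table; pass haldane=True for a 0.5 correction"
        )
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    crit = stats.norm.ppf(0.975)
    return ORResult(
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - crit * se),
        ci_high=math.exp(log_or + crit * se),
        pval=float(2 * stats.norm.sf(abs(z))),
    )
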