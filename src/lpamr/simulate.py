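"""Synthetic cohorts and two-sample GWAS summary statistics with known truth.

Two generators make every pipeline stage testable without external data:

* :func:`gen_cohort` draws an individual-level cohort whose statistical
  structure mirrors a routine-health-exam population: Hardy-Weinberg
  genotypes at a configurable G-allele frequency, a three-category Lp(a)
  risk outcome shifted by carrier odds ratios, category-conditional
  log-normal Lp(a) levels, and independent clinical covariates.
* :func:`gen_two_sample_gwas` draws exposure and outcome GWAS
  summary-statistic panels under a known causal effect theta, with optional
  balanced or directional pleiotropy satisfying InSIDE, and returns the
  generating truth alongside.

All draws flow through one ``numpy.random.Generator`` seeded from the spec.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .assoc.lipids import friedewald_ldl
from .assoc.tables import RISK_CATEGORIES, classify_lpa
from .mr.records import SummaryStatRecord

# allele pairs that are unambiguous across strand flips
_NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass
class CohortSpec:
    """Generating parameters for a synthetic cohort.

    Defaults mirror a 614-person health-exam cohort: G-allele frequency
    6%, non-carrier risk-category probabilities (0.405, 0.392, 0.203) —
    the AA column of the observed genotype table — and carrier odds
    ratios (0.5, 0.4) for average/high risk versus low.
    """

    n: int = 614
    maf: float = 0.06
    baseline_probs: tuple[float, float, float] = (0.405, 0.392, 0.203)
    carrier_or: tuple[float, float] = (0.5, 0.4)
    # per-category log-normal (mu, sigma) of Lp(a) in mg/dL
    lpa_params: dict = field(
        default_factory=lambda: {
            "low": (1.6, 0.55),
            "average": (2.80, 0.35),
            "high": (3.74, 0.40),
        }
    )
    covariate_params: dict = field(
        default_factory=lambda: {
            "age": (46.0, 10.0),
            "bmi": (24.3, 3.4),
            "male": 0.535,
            "smoker": 0.25,
            "htn": 0.12,
            "dm": 0.025,
            "hdl": (55.0, 15.0),
            "tc_by_category": {
                "low": (192.0, 36.0),
                "average": (199.0, 37.0),
                "high": (207.0, 37.0),
            },
            "tg_by_category": {
                "low": (153.0, 148.0),
                "average": (139.0, 91.0),
                "high": (124.0, 83.0),
            },
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.maf < 1:
            raise ValueError("maf must lie strictly in (0, 1)")
        if abs(sum(self.baseline_probs) - 1.0) > 1e-8:
            raise ValueError("baseline_probs must sum to 1")
        if any(o <= 0 for o in self.carrier_or):
            raise ValueError("carrier odds ratios must be positive")


_CATEGORIES = ("low", "average", "high")


def _category_probs(baseline: np.ndarray, carrier_or: tuple[float, float]) -> np.ndarray:
    odds = baseline / baseline[0]
    odds = odds * np.array([1.0, carrier_or[0], carrier_or[1]])
    return odds / odds.sum()


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sample a log-normal restricted to [lo, hi)."""
    lo_z = -np.inf if lo <= 0 else (np.log(lo) - mu) / sigma
    hi_z = np.inf if np.isinf(hi) else (np.log(hi) - mu) / sigma
    mass = stats.norm.cdf(hi_z) - stats.norm.cdf(lo_z)
    if mass < 1e-6:
        raise ValueError(
            f"lpa_params ({mu}, {sigma}) put no mass in [{lo}, {hi})"
        )
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mu, sigma, size=max(16, int((size - filled) / mass * 1.3)))
        ok = draw[(draw >= lo) & (draw < hi)]
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw an individual-level cohort table from a :class:`CohortSpec`.

    Genotypes are Hardy-Weinberg at ``spec.maf``; the risk category comes
    from a three-category logit with carrier log-odds shifts
    ``log(carrier_or)``; Lp(a) is drawn from the category's log-normal
    restricted to the category bounds (so ``classify_lpa`` round-trips);
    covariates are independent given the category. Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    q = spec.maf
    genotype = rng.choice(
        np.array(["AA", "AG", "GG"]),
        size=spec.n,
        p=[(1 - q) ** 2, 2 * q * (1 - q), q ** 2],
    )
    carrier = genotype != "AA"
    base = np.asarray(spec.baseline_probs, dtype=float)
    p_carrier = _category_probs(base, spec.carrier_or)
    category = np.empty(spec.n, dtype=object)
    u = rng.random(spec.n)
    for mask, probs in ((~carrier, base), (carrier, p_carrier)):
        cum = np.cumsum(probs)
        category[mask] = np.array(_CATEGORIES, dtype=object)[
            np.searchsorted(cum, u[mask], side="right").clip(0, 2)
        ]
    lpa = np.empty(spec.n)
    for cat in _CATEGORIES:
        mask = category == cat
        if not mask.any():
            continue
        mu, sigma = spec.lpa_params[cat]
        rc = RISK_CATEGORIES[cat]
        lo = rc.lower
        hi = rc.upper if cat != "average" else rc.upper + 1e-9  # closed upper bound
        lpa[mask] = _truncated_lognormal(rng, mu, sigma, lo, hi, int(mask.sum()))
    cp = spec.covariate_params
    age = rng.normal(*cp["age"], size=spec.n)
    bmi = rng.normal(*cp["bmi"], size=spec.n)
    male = rng.random(spec.n) < cp["male"]
    smoker = rng.random(spec.n) < cp["smoker"]
    htn = rng.random(spec.n) < cp["htn"]
    dm = rng.random(spec.n) < cp["dm"]
    hdl = np.clip(rng.normal(*cp["hdl"], size=spec.n), 10, None)
    tc = np.empty(spec.n)
    tg = np.empty(spec.n)
    for cat in _CATEGORIES:
        mask = category == cat
        if not mask.any():
            continue
        m_tc, s_tc = cp["tc_by_category"][cat]
        tc[mask] = rng.normal(m_tc, s_tc, size=int(mask.sum()))
        m_tg, s_tg = cp["tg_by_category"][cat]
        # log-normal with matched mean and SD
        sigma2 = np.log1p((s_tg / m_tg) ** 2)
        mu = np.log(m_tg) - sigma2 / 2
        tg[mask] = rng.lognormal(mu, np.sqrt(sigma2), size=int(mask.sum()))
    tc = np.clip(tc, 80, None)
    ldl = np.array([friedewald_ldl(t, h, g).ldl for t, h, g in zip(tc, hdl, tg)])
    df = pd.DataFrame(
        {
            "age": np.round(age, 1),
            "sex": np.where(male, "M", "F"),
            "smoker": smoker.astype(int),
            "htn": htn.astype(int),
            "dm": dm.astype(int),
            "bmi": np.round(bmi, 1),
            "tc": np.round(tc, 1),
            "hdl": np.round(hdl, 1),
            "tg": np.round(tg, 1),
            "ldl": np.round(ldl, 1),
            "lpa": lpa,
            "genotype": genotype,
            "carrier": carrier.astype(int),
            "category": category.astype(str),
        }
    )
    assert all(classify_lpa(v) == c for v, c in zip(df.lpa, df.category))
    return df


def irnt(values, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offset.

    Maps value ranks r (ties averaged) to ``Phi^-1((r - 0.375) / (n + 0.25))``,
    yielding an approximately standard-normal margin while preserving order.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("irnt needs at least two values")
    if np.ptp(x) == 0:
        raise ValueError("irnt undefined for a constant vector")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (x.size + 1 - 2 * offset))


@dataclass
class GwasSimSpec:
    """Generating parameters for two-sample GWAS summary statistics.

    Default panel sizes follow a two-sample design with a modest exposure
    GWAS (n = 3290) and a larger outcome GWAS (n = 27,386). The exposure
    effect-size range is calibrated so that, under the allele-frequency
    standard error ``(2 maf (1-maf) n)**-0.5``, instruments reach z of
    roughly 5-16 — the instrument strength of a genome-wide-significant
    panel (p <= 5e-7).
    """

    L: int = 6
    theta: float = 0.07
    maf_range: tuple[float, float] = (0.2, 0.5)
    exposure_beta_range: tuple[float, float] = (0.16, 0.5)
    pleiotropy: Literal["none", "balanced", "directional"] = "none"
    pleiotropy_mean: float = 0.01
    pleiotropy_sd: float = 0.005
    n_exp: int = 3290
    n_out: int = 27386
    swap_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 3:
            raise ValueError("L must be at least 3")
        if self.n_exp < 100 or self.n_out < 100:
            raise ValueError("GWAS sample sizes must be at least 100")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")


@dataclass(frozen=True)
class GwasTruth:
    theta: float
    beta_exp_true: np.ndarray
    direct_effects: np.ndarray


def gen_two_sample_gwas(
    spec: GwasSimSpec,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], GwasTruth]:
    """Draw exposure and outcome summary-statistic panels with known truth.

    Per SNP: minor-allele frequency uniform on ``maf_range``; true exposure
    effect uniform on ``exposure_beta_range``, expressed on the canonical
    exposure-increasing allele; estimated betas are the truth plus normal
    noise at SE ``(2 maf (1-maf) n)**-0.5``. The true outcome effect is
    ``theta * beta_exp_true`` plus a direct (pleiotropic) effect per mode —
    zero, N(0, sd) balanced, or N(mean, sd) directional — drawn
    independently of the exposure effect (InSIDE). Directionality is
    defined relative to the exposure-increasing allele, the orientation
    under which the Egger intercept estimates the mean direct effect.

    Orientation randomness lives entirely in the allele *presentation*:
    each exposure record is reported on either allele with equal
    probability, and each outcome record disagrees with its exposure
    record's presentation with probability ``swap_prob``, so harmonization
    is exercised without changing the underlying effects.
    """
    rng = np.random.default_rng(spec.seed)
    maf = rng.uniform(*spec.maf_range, size=spec.L)
    beta_true = rng.uniform(*spec.exposure_beta_range, size=spec.L)
    if spec.pleiotropy == "none":
        alpha = np.zeros(spec.L)
    elif spec.pleiotropy == "balanced":
        alpha = rng.normal(0.0, spec.pleiotropy_sd, size=spec.L)
    else:
        alpha = rng.normal(spec.pleiotropy_mean, spec.pleiotropy_sd, size=spec.L)
    se_exp = (2 * maf * (1 - maf) * spec.n_exp) ** -0.5
    se_out = (2 * maf * (1 - maf) * spec.n_out) ** -0.5
    beta_exp = rng.normal(beta_true, se_exp)
    out_true = spec.theta * beta_true + alpha
    beta_out = rng.normal(out_true, se_out)
    pairs = [_NON_PALINDROMIC_PAIRS[i] for i in rng.integers(0, len(_NON_PALINDROMIC_PAIRS), spec.L)]
    exp_swapped = rng.random(spec.L) < 0.5
    out_disagrees = rng.random(spec.L) < spec.swap_prob
    exposure, outcome = [], []
    for j in range(spec.L):
        ea, oa = pairs[j]
        snp = f"rs{90000 + j}"

        def present(beta: float, se: float, n: int, trait: str, swapped: bool):
            b, e, o, f = beta, ea, oa, maf[j]
            if swapped:
                b, e, o, f = -b, oa, ea, 1 - maf[j]
            z = b / se
            return SummaryStatRecord(
                snp_id=snp, effect_allele=e, other_allele=o,
                beta=float(b), se=float(se),
                pval=float(2 * stats.norm.sf(abs(z))),
                eaf=float(f), n=n, trait=trait,
            )

        exposure.append(
            present(beta_exp[j], se_exp[j], spec.n_exp, "exposure", exp_swapped[j])
        )
        outcome.append(
            present(beta_out[j], se_out[j], spec.n_out, "outcome",
                    exp_swapped[j] ^ out_disagrees[j])
        )
    return exposure, outcome, GwasTruth(spec.theta, beta_true, alpha)
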