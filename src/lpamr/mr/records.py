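"""Domain records for two-sample Mendelian randomization on GWAS summary statistics.

A *summary-statistic record* carries one SNP's association with one trait
(per-allele beta, SE, p-value, allele pair). A *harmonized instrument* pairs
the exposure and outcome records for a SNP on a common effect allele and
carries the per-SNP Wald ratio and its inverse-variance weight.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous allele pairs (A/T or C/G)."""
    return COMPLEMENT[a1] == a2


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait from a GWAS summary-statistics panel.

    Parameters
    ----------
    snp_id : str
        rsID of the variant.
    effect_allele, other_allele : str
        Single-base alleles; ``beta`` is per copy of ``effect_allele``.
    beta : float
        Per-effect-allele regression coefficient in the trait's units.
    se : float
        Standard error of ``beta``; must be positive.
    pval : float
        Two-sided association p-value.
    eaf : float, optional
        Effect-allele frequency in [0, 1].
    n : int, optional
        GWAS sample size.
    trait : str
        Trait label (e.g. ``"PCSK9"`` or ``"Lp(a)_irnt"``).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None
    trait: str = ""

    def __post_init__(self) -> None:
        ea, oa = self.effect_allele.upper(), self.other_allele.upper()
        if ea not in VALID_BASES or oa not in VALID_BASES:
            raise ValueError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if ea == oa:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical ({ea})")
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not 0.0 <= self.pval <= 1.0:
            raise ValueError(f"{self.snp_id}: pval must lie in [0, 1], got {self.pval}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.snp_id}: eaf must lie in [0, 1], got {self.eaf}")

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)

    def flipped(self) -> "SummaryStatRecord":
        """Same association expressed on the opposite effect allele."""
        return SummaryStatRecord(
            snp_id=self.snp_id,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            se=self.se,
            pval=self.pval,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            n=self.n,
            trait=self.trait,
        )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure/outcome coefficient pair for one SNP on a common effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    flipped: bool = False
    eaf_exp: float | None = None
    eaf_out: float | None = None

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError(f"{self.snp_id}: standard errors must be positive")
        if self.beta_exp == 0:
            raise ValueError(f"{self.snp_id}: beta_exp = 0, Wald ratio undefined")

    @property
    def wald_ratio(self) -> float:
        return self.beta_out / self.beta_exp

    @property
    def wald_se(self) -> float:
        """First-order delta-method SE of the Wald ratio."""
        return self.se_out / abs(self.beta_exp)

    @property
    def weight(self) -> float:
        """Inverse-variance weight, ``wald_se ** -2``."""
        return self.wald_se ** -2


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate from one MR method."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    inference_df: int | str = "normal"

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")
        if not 0.0 <= self.pval <= 1.0:
            raise ValueError(f"pval outside [0, 1]: {self.pval}")

    @property
    def ci(self) -> tuple[float, float]:
        """Wald 95% confidence interval on the causal effect."""
        from scipy import stats

        if self.inference_df == "normal":
            crit = stats.norm.ppf(0.975)
        else:
            crit = stats.t.ppf(0.975, self.inference_df)
        return (self.beta - crit * self.se, self.beta + crit * self.se)


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope plus the directional-pleiotropy intercept."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.intercept_pval <= 1.0:
            raise ValueError("intercept_pval outside [0, 1]")


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q (about the IVW fit) or Rücker's Q' (about the Egger fit)."""

    q: float
    df: int
    pval: float
    about: str = "ivw"

    def __post_init__(self) -> None:
        if self.q < -1e-12:
            raise ValueError("Q must be non-negative")

    @property
    def i2(self) -> float:
        """Higgins I², floored at zero."""
        if self.q <= 0:
            return 0.0
        return max(0.0, (self.q - self.df) / self.q)


@dataclass
class LDMatrix:
    """Square symmetric matrix of pairwise LD r² values with unit diagonal."""

    snp_ids: list[str]
    r2: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 must be {k}x{k}, got {self.r2.shape}")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]} not present in LD matrix") from None
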