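"""Two-sample MR estimators over harmonized instruments.

All estimators work from per-SNP Wald ratios r_j = beta_out_j / beta_exp_j
with first-order SEs se_out_j / |beta_exp_j| and inverse-variance weights
w_j = wald_se_j ** -2.

Conventions:

* IVW point estimate: sum(w r) / sum(w), identical to a weighted regression
  of outcome betas on exposure betas through the origin with weights
  se_out ** -2. Fixed-effect SE (sum w)^-1/2; multiplicative random-effects
  SE multiplies by max(1, sqrt(Q / (L - 1))) — never deflated below the
  fixed-effect SE. Inference on the standard normal.
* MR-Egger: instruments oriented so beta_exp >= 0, then weighted least
  squares of beta_out on beta_exp with intercept, weights se_out ** -2.
  Coefficient SEs use the same multiplicative floor (residual scale never
  below 1); inference on t with L - 2 df. A non-zero intercept signals
  directional pleiotropy.
* Weighted median: interpolate the standardized weighted cumulative
  distribution of ordered ratios at 0.5; SE by parametric bootstrap.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .records import EggerResult, HarmonizedInstrument, HeterogeneityResult, MREstimate


def _ratios_weights(insts: Sequence[HarmonizedInstrument]):
    r = np.array([i.wald_ratio for i in insts])
    w = np.array([i.weight for i in insts])
    return r, w


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate: outcome beta over exposure beta."""
    beta = inst.wald_ratio
    se = inst.wald_se
    z = beta / se
    return MREstimate(
        method="wald",
        beta=beta,
        se=se,
        pval=float(2 * stats.norm.sf(abs(z))),
        n_snps=1,
        inference_df="normal",
    )


def ivw(insts: Sequence[HarmonizedInstrument], mode: str = "mre") -> MREstimate:
    """Inverse-variance-weighted combination of Wald ratios.

    Parameters
    ----------
    insts : sequence of HarmonizedInstrument
        At least two instruments.
    mode : {"fixed", "mre"}
        ``fixed`` uses the fixed-effect SE ``(sum w)**-0.5``; ``mre``
        (multiplicative random effects, the default) inflates it by
        ``max(1, sqrt(Q / (L - 1)))``.
    """
    if mode not in ("fixed", "mre"):
        raise ValueError(f"mode must be 'fixed' or 'mre', got {mode!r}")
    L = len(insts)
    if L < 2:
        raise ValueError("ivw requires at least 2 instruments")
    r, w = _ratios_weights(insts)
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if mode == "mre":
        q = float(np.sum(w * (r - beta) ** 2))
        se = se_fixed * max(1.0, np.sqrt(q / (L - 1)))
    else:
        se = se_fixed
    z = beta / se
    return MREstimate(
        method=f"ivw_{mode}",
        beta=beta,
        se=se,
        pval=float(2 * stats.norm.sf(abs(z))),
        n_snps=L,
        inference_df="normal",
    )


def egger(insts: Sequence[HarmonizedInstrument]) -> EggerResult:
    """MR-Egger regression: pleiotropy-robust slope and intercept test.

    The slope is a consistent causal estimate under InSIDE even with
    directional pleiotropy; the intercept estimates the average direct
    (pleiotropic) effect per SNP.
    """
    L = len(insts)
    if L < 3:
        raise ValueError("egger requires at least 3 instruments")
    be = np.array([i.beta_exp for i in insts])
    bo = np.array([i.beta_out for i in insts])
    so = np.array([i.se_out for i in insts])
    # orient to non-negative exposure effects; the intercept is
    # orientation-dependent so this convention must be fixed
    sign = np.where(be < 0, -1.0, 1.0)
    be, bo = be * sign, bo * sign
    if np.ptp(be) == 0:
        raise ValueError("egger slope unidentifiable: zero spread in exposure betas")
    w = so ** -2
    X = np.column_stack([np.ones(L), be])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * bo))
    resid = bo - X @ coef
    sigma2 = float(np.sum(w * resid ** 2) / (L - 2))
    cov_unit = np.linalg.inv(xtwx)
    # multiplicative residual scale, floored at 1 (never below fixed-effect SE)
    scale = max(1.0, np.sqrt(sigma2))
    se_int, se_slope = np.sqrt(np.diag(cov_unit)) * scale
    df = L - 2
    slope_p = float(2 * stats.t.sf(abs(coef[1] / se_slope), df))
    int_p = float(2 * stats.t.sf(abs(coef[0] / se_int), df))
    slope = MREstimate(
        method="egger_slope",
        beta=float(coef[1]),
        se=float(se_slope),
        pval=slope_p,
        n_snps=L,
        inference_df=df,
    )
    return EggerResult(
        slope=slope,
        intercept=float(coef[0]),
        intercept_se=float(se_int),
        intercept_pval=int_p,
    )


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates.

    Ratios are ordered ascending; with normalized weights the standardized
    cumulative weight at position j is p_j = (S_j - w_j / 2) / S_L, and the
    estimate interpolates the ratio linearly at p = 0.5.
    """
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    p = np.cumsum(w) - w / 2
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def weighted_median(
    insts: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Consistent when instruments carrying at least half of the weight are
    valid. The SE is the standard deviation of the estimate over ``n_boot``
    replicates that resample each exposure and outcome beta from a normal
    distribution centred on its estimate with its reported SE.
    """
    L = len(insts)
    if L < 3:
        raise ValueError("weighted_median requires at least 3 instruments")
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if seed is None:
        raise ValueError("weighted_median requires an explicit bootstrap seed")
    r, w = _ratios_weights(insts)
    beta = weighted_median_point(r, w)
    rng = np.random.default_rng(seed)
    be = np.array([i.beta_exp for i in insts])
    se_e = np.array([i.se_exp for i in insts])
    bo = np.array([i.beta_out for i in insts])
    so = np.array([i.se_out for i in insts])
    boots = np.empty(n_boot)
    for b in range(n_boot):
        be_b = rng.normal(be, se_e)
        bo_b = rng.normal(bo, so)
        # guard against a resampled exposure beta crossing zero
        be_b = np.where(be_b == 0, np.finfo(float).tiny, be_b)
        r_b = bo_b / be_b
        w_b = (so / np.abs(be_b)) ** -2
        boots[b] = weighted_median_point(r_b, w_b)
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny
    z = beta / se
    return MREstimate(
        method="weighted_median",
        beta=beta,
        se=se,
        pval=float(2 * stats.norm.sf(abs(z))),
        n_snps=L,
        inference_df="normal",
    )


def cochran_q(
    insts: Sequence[HarmonizedInstrument], about: str = "ivw"
) -> HeterogeneityResult:
    """Heterogeneity of the ratio estimates about the IVW or Egger fit.

    ``about="ivw"`` gives Cochran's Q = sum w_j (r_j - beta_IVW)^2 on L - 1
    df; ``about="egger"`` gives Rücker's Q' — the weighted residual sum of
    squares of the Egger fit — on L - 2 df.
    """
    L = len(insts)
    if about == "ivw":
        if L < 2:
            raise ValueError("cochran_q requires at least 2 instruments")
        r, w = _ratios_weights(insts)
        beta = np.sum(w * r) / np.sum(w)
        q = float(np.sum(w * (r - beta) ** 2))
        df = L - 1
    elif about == "egger":
        if L < 3:
            raise ValueError("Rücker's Q' requires at least 3 instruments")
        be = np.array([i.beta_exp for i in insts])
        bo = np.array([i.beta_out for i in insts])
        so = np.array([i.se_out for i in insts])
        sign = np.where(be < 0, -1.0, 1.0)
        be, bo = be * sign, bo * sign
        w = so ** -2
        X = np.column_stack([np.ones(L), be])
        coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * bo))
        resid = bo - X @ coef
        q = float(np.sum(w * resid ** 2))
        df = L - 2
    else:
        raise ValueError(f"about must be 'ivw' or 'egger', got {about!r}")
    pval = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q=q, df=df, pval=pval, about=about)
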