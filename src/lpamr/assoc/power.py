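"""Monte-Carlo power for the carrier effect in a binary logistic model.

Simulates cohorts with a binary genetic exposure (G-allele carrier) and a
binary outcome (risk-category membership) whose marginal prevalence and
carrier odds ratio are fixed, then estimates the rejection rate of the
two-sided Wald test on the carrier log-odds coefficient. With a single
binary covariate the logistic model is saturated, so the Wald statistic is
the 2x2 log cross-product odds ratio over its Woolf standard error.
"""
from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import optimize, stats


class PowerResult(NamedTuple):
    power: float
    mc_se: float
    reps: int


def _baseline_prob(carrier_freq: float, prevalence: float, or_: float) -> float:
    """Non-carrier outcome probability giving the requested marginal prevalence."""

    def marginal(p0: float) -> float:
        odds1 = or_ * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        return (1 - carrier_freq) * p0 + carrier_freq * p1 - prevalence

    return float(optimize.brentq(marginal, 1e-9, 1 - 1e-9))


def power_simulation(
    n: int,
    carrier_freq: float,
    outcome_prev: float,
    or_: float,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed: int | None = None,
) -> PowerResult:
    """Monte-Carlo power of the alpha-level two-sided carrier Wald test.

    Parameters
    ----------
    n : int
        Cohort size per replicate.
    carrier_freq : float
        Carrier (exposure) frequency in (0, 1).
    outcome_prev : float
        Marginal outcome prevalence in (0, 1).
    or_ : float
        Carrier odds ratio on the outcome.
    reps : int
        Monte-Carlo replicates (>= 100).
    seed : int
        Seed for the replicate generator.

    Returns
    -------
    PowerResult
        Estimated power with its binomial Monte-Carlo standard error.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    if not 0 < carrier_freq < 1:
        raise ValueError("carrier_freq must lie strictly in (0, 1)")
    if not 0 < outcome_prev < 1:
        raise ValueError("outcome prevalence must lie strictly in (0, 1)")
    if or_ <= 0:
        raise ValueError("odds ratio must be positive")
    p0 = _baseline_prob(carrier_freq, outcome_prev, or_)
    odds1 = or_ * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    rng = np.random.default_rng(seed)
    n_car = rng.binomial(n, carrier_freq, size=reps)
    n_non = n - n_car
    a = rng.binomial(n_car, p1)  # carrier cases
    c = rng.binomial(n_non, p0)  # non-carrier cases
    b, d = n_car - a, n_non - c
    cells = np.stack([a, b, c, d]).astype(float)
    # Haldane correction where any cell is empty
    zero = (cells == 0).any(axis=0)
    cells[:, zero] += 0.5
    a_, b_, c_, d_ = cells
    log_or = np.log(a_ * d_ / (b_ * c_))
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    crit = stats.norm.ppf(1 - alpha / 2)
    reject = np.abs(log_or / se) > crit
    power = float(reject.mean())
    mc_se = float(np.sqrt(power * (1 - power) / reps))
    return PowerResult(power=power, mc_se=mc_se, reps=reps)
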