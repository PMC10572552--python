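"""Model/results interface for two-sample MR.

`TwoSampleMR` is constructed from harmonized instruments (or directly from
exposure and outcome summary-statistic panels); `fit()` runs the estimator
battery and returns an `MRResults` carrying per-method estimates, the
heterogeneity statistics and the Egger pleiotropy test, with a text
`summary()` and forest/scatter plots.
"""
from __future__ import annotations

from typing import Sequence

import pandas as pd

from . import estimators
from .harmonize import harmonize
from .records import (
    EggerResult,
    HarmonizedInstrument,
    HeterogeneityResult,
    MREstimate,
    SummaryStatRecord,
)


class TwoSampleMR:
    """Two-sample Mendelian randomization model on summary statistics.

    Parameters
    ----------
    instruments : sequence of HarmonizedInstrument
        Harmonized exposure/outcome pairs (see :func:`lpamr.mr.harmonize`).
    exposure_name, outcome_name : str
        Trait labels used in summaries and plots.
    """

    def __init__(
        self,
        instruments: Sequence[HarmonizedInstrument],
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> None:
        if len(instruments) < 2:
            raise ValueError("TwoSampleMR requires at least 2 instruments")
        self.instruments = list(instruments)
        self.exposure_name = exposure_name
        self.outcome_name = outcome_name

    @classmethod
    def from_summary_stats(
        cls,
        exposure: Sequence[SummaryStatRecord],
        outcome: Sequence[SummaryStatRecord],
        palindromic_policy: str = "drop",
    ) -> "TwoSampleMR":
        """Harmonize two summary-statistic panels and build the model."""
        insts = harmonize(exposure, outcome, palindromic_policy=palindromic_policy)
        exp_name = exposure[0].trait or "exposure"
        out_name = outcome[0].trait or "outcome"
        return cls(insts, exposure_name=exp_name, outcome_name=out_name)

    def fit(
        self,
        ivw_mode: str = "mre",
        n_boot: int = 1000,
        seed: int | None = None,
    ) -> "MRResults":
        """Run IVW, MR-Egger and (with >= 3 SNPs) weighted-median estimators.

        ``seed`` drives the weighted-median parametric bootstrap and is
        required when that estimator runs.
        """
        L = len(self.instruments)
        wald = [estimators.wald_ratio(i) for i in self.instruments]
        est: dict[str, MREstimate] = {}
        est["ivw"] = estimators.ivw(self.instruments, mode=ivw_mode)
        egger_res = None
        q_egger = None
        if L >= 3:
            egger_res = estimators.egger(self.instruments)
            est["egger_slope"] = egger_res.slope
            est["weighted_median"] = estimators.weighted_median(
                self.instruments, n_boot=n_boot, seed=seed
            )
            q_egger = estimators.cochran_q(self.instruments, about="egger")
        q_ivw = estimators.cochran_q(self.instruments, about="ivw")
        return MRResults(
            model=self,
            estimates=est,
            wald_ratios=wald,
            egger=egger_res,
            heterogeneity=q_ivw,
            heterogeneity_egger=q_egger,
        )


class MRResults:
    """Fitted two-sample MR estimates and diagnostics."""

    _method_labels = {
        "ivw": "Inverse-variance weighted",
        "egger_slope": "MR-Egger",
        "weighted_median": "Weighted median",
    }

    def __init__(
        self,
        model: TwoSampleMR,
        estimates: dict[str, MREstimate],
        wald_ratios: list[MREstimate],
        egger: EggerResult | None,
        heterogeneity: HeterogeneityResult,
        heterogeneity_egger: HeterogeneityResult | None,
    ) -> None:
        self.model = model
        self.estimates = estimates
        self.wald_ratios = wald_ratios
        self.egger = egger
        self.heterogeneity = heterogeneity
        self.heterogeneity_egger = heterogeneity_egger

    def to_frame(self) -> pd.DataFrame:
        """Per-method estimates as a tidy table (Q attached where defined)."""
        rows = []
        for key, e in self.estimates.items():
            q = p_q = None
            if key == "ivw":
                q, p_q = self.heterogeneity.q, self.heterogeneity.pval
            elif key == "egger_slope" and self.heterogeneity_egger is not None:
                q, p_q = self.heterogeneity_egger.q, self.heterogeneity_egger.pval
            rows.append(
                {
                    "method": self._method_labels.get(key, key),
                    "n_snps": e.n_snps,
                    "beta": e.beta,
                    "se": e.se,
                    "pval": e.pval,
                    "q": q,
                    "q_pval": p_q,
                }
            )
        return pd.DataFrame(rows)

    def instruments_frame(self) -> pd.DataFrame:
        """Per-SNP harmonized coefficients and Wald ratios."""
        rows = []
        for inst, w in zip(self.model.instruments, self.wald_ratios):
            rows.append(
                {
                    "snp": inst.snp_id,
                    "beta_exp": inst.beta_exp,
                    "se_exp": inst.se_exp,
                    "beta_out": inst.beta_out,
                    "se_out": inst.se_out,
                    "flipped": inst.flipped,
                    "wald_beta": w.beta,
                    "wald_se": w.se,
                    "wald_pval": w.pval,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary of the causal-effect estimates."""
        lines = [
            "Two-sample Mendelian randomization",
            f"  exposure: {self.model.exposure_name}",
            f"  outcome:  {self.model.outcome_name}",
            f"  instruments: {len(self.model.instruments)}",
            "",
            f"{'Method':<28}{'nSNP':>5}{'beta':>10}{'SE':>9}{'p':>12}",
        ]
        for key, e in self.estimates.items():
            lines.append(
                f"{self._method_labels.get(key, key):<28}{e.n_snps:>5}"
                f"{e.beta:>10.4f}{e.se:>9.4f}{e.pval:>12.4g}"
            )
        h = self.heterogeneity
        lines.append("")
        lines.append(
            f"Cochran's Q = {h.q:.3f} on {h.df} df, p = {h.pval:.4f} (I2 = {h.i2:.1%})"
        )
        if self.heterogeneity_egger is not None:
            he = self.heterogeneity_egger
            lines.append(
                f"Rucker's Q' = {he.q:.3f} on {he.df} df, p = {he.pval:.4f}"
            )
        if self.egger is not None:
            lines.append(
                f"Egger intercept = {self.egger.intercept:.4f} "
                f"(SE {self.egger.intercept_se:.4f}, p = {self.egger.intercept_pval:.4f})"
            )
        return "\n".join(lines)

    def plot_forest(self, path=None):
        from ..plots import forest_plot

        return forest_plot(self, path=path)

    def plot_scatter(self, path=None):
        from ..plots import scatter_plot

        return scatter_plot(self, path=path)
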