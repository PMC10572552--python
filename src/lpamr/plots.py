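"""Forest and exposure-vs-outcome scatter plots for fitted MR results."""
from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def forest_plot(results, path=None):
    """Per-SNP Wald ratios with 95% CIs plus the combined estimates."""
    insts = results.model.instruments
    labels = [i.snp_id for i in insts] + [""] + [
        results._method_labels.get(k, k) for k in results.estimates
    ]
    betas = [w.beta for w in results.wald_ratios] + [np.nan] + [
        e.beta for e in results.estimates.values()
    ]
    ses = [w.se for w in results.wald_ratios] + [np.nan] + [
        e.se for e in results.estimates.values()
    ]
    y = np.arange(len(labels))[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.45 * len(labels) + 1))
    ax.errorbar(betas, y, xerr=1.96 * np.asarray(ses), fmt="o", color="navy", capsize=3)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(labels)
    ax.set_xlabel(
        f"effect of {results.model.exposure_name} on {results.model.outcome_name}"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def scatter_plot(results, path=None):
    """Exposure betas vs outcome betas with the fitted method slopes."""
    insts = results.model.instruments
    be = np.array([i.beta_exp for i in insts])
    bo = np.array([i.beta_out for i in insts])
    se_e = np.array([i.se_exp for i in insts])
    se_o = np.array([i.se_out for i in insts])
    sign = np.where(be < 0, -1.0, 1.0)
    be, bo = be * sign, bo * sign
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.errorbar(be, bo, xerr=se_e, yerr=se_o, fmt="o", color="black", capsize=2, lw=0.8)
    xs = np.linspace(0, be.max() * 1.05, 50)
    colors = {"ivw": "tab:blue", "weighted_median": "tab:green", "egger_slope": "navy"}
    for key, est in results.estimates.items():
        intercept = results.egger.intercept if key == "egger_slope" and results.egger else 0.0
        ax.plot(xs, intercept + est.beta * xs, label=results._method_labels.get(key, key),
                color=colors.get(key, "grey"))
    ax.axhline(0, color="grey", lw=0.6, ls=":")
    ax.set_xlabel(f"SNP effect on {results.model.exposure_name}")
    ax.set_ylabel(f"SNP effect on {results.model.outcome_name}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
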