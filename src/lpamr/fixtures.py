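"""Bundled reference inputs: the published summary tables as data files.

The exposure panel is a plasma-PCSK9 GWAS (six PCSK9-locus instruments,
n = 3290); the outcome panel is the UK Biobank inverse-rank-normalised
Lp(a) GWAS (ukb-d-30790_irnt, n = 27,386). The genotype count table and
baseline group summaries come from a 614-person health-exam cohort
stratified by Lp(a) risk category. Files are checksum-pinned so the
reproduction path always runs on byte-identical inputs through the real
readers.
"""
from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .assoc.summaries import GroupSummary
from .assoc.tables import GenotypeCountTable
from .io import read_summary_stats
from .mr.records import SummaryStatRecord

_CHECKSUMS = {
    "pcsk9_exposure.tsv": "8cf98b2c735952fe6ae74cdebdf1aeb5ad8695d9b73ef7da6b20637df0d8bfd6",
    "lpa_outcome.tsv": "ad71d2d2bfd303758c89ab46da67ccbc00f5fabb3df108e684705d743db593ec",
    "genotype_counts.csv": "e1ad008559976ecaa7281a55e8ddf9cd018fd73f2304e44564cc8843c7da8337",
    "baseline_summaries.tsv": "7d5865b05c36d18318ceb89626fbc9f8cf83c53e589e073c54306e4f01703200",
}

#: the six PCSK9-level instruments plus the E670G association SNP
SNP_SET = (
    "rs11206510",
    "rs11591147",
    "rs2479409",
    "rs45448095",
    "rs499718",
    "rs557435",
    "rs505151",
)


def fixture_path(name: str):
    """Checksum-verified path to a bundled data file."""
    if name not in _CHECKSUMS:
        raise KeyError(f"unknown fixture {name!r}")
    path = resources.files("lpamr.data") / name
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(f"fixture {name} failed its checksum: {digest}")
    return path


def exposure_panel() -> list[SummaryStatRecord]:
    """Plasma PCSK9 exposure GWAS coefficients for the six instruments."""
    return read_summary_stats(fixture_path("pcsk9_exposure.tsv"), trait="PCSK9")


def outcome_panel() -> list[SummaryStatRecord]:
    """irnt Lp(a) outcome GWAS coefficients for the six instruments."""
    return read_summary_stats(fixture_path("lpa_outcome.tsv"), trait="Lp(a)_irnt")


def genotype_counts() -> GenotypeCountTable:
    """E670G genotype by Lp(a) risk-stratum counts (n = 614)."""
    return GenotypeCountTable.from_csv(fixture_path("genotype_counts.csv"))


def baseline_summaries() -> dict[str, dict[str, GroupSummary]]:
    """Per-trait, per-stratum (n, mean, SD) baseline summaries."""
    df = pd.read_csv(fixture_path("baseline_summaries.tsv"), sep="\t")
    out: dict[str, dict[str, GroupSummary]] = {}
    for trait, grp in df.groupby("trait", sort=False):
        out[trait] = {
            row.stratum: GroupSummary(n=int(row.n), mean=float(row["mean"]), sd=float(row.sd))
            for _, row in grp.iterrows()
        }
    return out
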