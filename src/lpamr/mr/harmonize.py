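"""Allele harmonization, instrument selection and instrument-strength summaries.

Harmonization joins exposure and outcome summary-statistic panels on a common
effect allele: where the outcome panel reports the opposite allele the outcome
beta is negated; strand-complement labelling (A<->T, C<->G) is resolved before
comparison; strand-ambiguous (palindromic) SNPs are handled per policy.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .records import (
    COMPLEMENT,
    HarmonizedInstrument,
    LDMatrix,
    SummaryStatRecord,
)

logger = logging.getLogger("lpamr")

PALINDROMIC_POLICIES = ("drop", "keep", "resolve-by-eaf")


class HarmonizationError(ValueError):
    pass


def _complement_pair(ea: str, oa: str) -> tuple[str, str]:
    return COMPLEMENT[ea], COMPLEMENT[oa]


def _orient_outcome(
    exp: SummaryStatRecord, out: SummaryStatRecord
) -> tuple[SummaryStatRecord, bool] | None:
    """Express ``out`` on ``exp``'s effect allele; None if alleles are incompatible."""
    e = (exp.effect_allele, exp.other_allele)
    o = (out.effect_allele, out.other_allele)
    if o == e:
        return out, False
    if (o[1], o[0]) == e:
        return out.flipped(), True
    # try strand relabelling
    oc = _complement_pair(*o)
    if oc == e:
        return out, False
    if (oc[1], oc[0]) == e:
        return out.flipped(), True
    return None


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    palindromic_policy: str = "drop",
) -> list[HarmonizedInstrument]:
    """Join exposure and outcome panels into harmonized instruments.

    Parameters
    ----------
    exposure, outcome : sequence of SummaryStatRecord
        Panels keyed by rsID; one record per SNP.
    palindromic_policy : {"drop", "keep", "resolve-by-eaf"}
        How to treat strand-ambiguous A/T and C/G SNPs. ``drop`` excludes
        them; ``keep`` harmonizes assuming both panels report the same
        strand; ``resolve-by-eaf`` flips the outcome record when the two
        effect-allele frequencies fall on opposite sides of 0.5 (requires
        eaf on both records).

    Returns
    -------
    list of HarmonizedInstrument
        One instrument per SNP present in both panels with compatible
        alleles, in exposure-panel order. Incompatible or dropped SNPs are
        logged and excluded.
    """
    if palindromic_policy not in PALINDROMIC_POLICIES:
        raise ValueError(
            f"palindromic_policy must be one of {PALINDROMIC_POLICIES}, "
            f"got {palindromic_policy!r}"
        )
    out_by_id: dict[str, SummaryStatRecord] = {}
    for rec in outcome:
        if rec.snp_id in out_by_id:
            raise HarmonizationError(f"duplicate outcome record for {rec.snp_id}")
    out_by_id = {rec.snp_id: rec for rec in outcome}
    seen: set[str] = set()
    instruments: list[HarmonizedInstrument] = []
    for exp in exposure:
        if exp.snp_id in seen:
            raise HarmonizationError(f"duplicate exposure record for {exp.snp_id}")
        seen.add(exp.snp_id)
        out = out_by_id.get(exp.snp_id)
        if out is None:
            logger.info("harmonize: %s absent from outcome panel, excluded", exp.snp_id)
            continue
        if exp.palindromic:
            if palindromic_policy == "drop":
                logger.info("harmonize: %s palindromic, dropped by policy", exp.snp_id)
                continue
            if palindromic_policy == "resolve-by-eaf":
                if exp.eaf is None or out.eaf is None:
                    raise HarmonizationError(
                        f"{exp.snp_id}: palindromic SNP cannot be resolved by EAF "
                        "because the frequency is missing"
                    )
                # same side of 0.5 -> same allele is the effect allele on both panels
                flip = (exp.eaf - 0.5) * (out.eaf - 0.5) < 0
                oriented = (out.flipped(), True) if flip else (out, False)
            else:  # keep: trust the labels, strand-complement match impossible
                oriented = _orient_outcome(exp, out)
        else:
            oriented = _orient_outcome(exp, out)
        if oriented is None:
            logger.warning(
                "harmonize: %s alleles incompatible (%s/%s vs %s/%s), excluded",
                exp.snp_id,
                exp.effect_allele,
                exp.other_allele,
                out.effect_allele,
                out.other_allele,
            )
            continue
        out_rec, flipped = oriented
        instruments.append(
            HarmonizedInstrument(
                snp_id=exp.snp_id,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=out_rec.beta,
                se_out=out_rec.se,
                flipped=flipped,
                eaf_exp=exp.eaf,
                eaf_out=out_rec.eaf,
            )
        )
    if not instruments:
        raise HarmonizationError(
            "no SNP could be harmonized: empty exposure/outcome intersection"
        )
    return instruments


def select_instruments(
    records: Sequence[SummaryStatRecord],
    p_threshold: float = 5e-7,
    ld: LDMatrix | None = None,
    r2_max: float = 0.5,
    replicated: Iterable[str] | None = None,
) -> list[SummaryStatRecord]:
    """Select independent instruments by significance and greedy LD pruning.

    Candidates with ``pval <= p_threshold`` (and, if given, rsID in
    ``replicated``) are visited by ascending p-value (ties broken by rsID);
    a candidate is kept only if its r² with every already-kept SNP is below
    ``r2_max``.
    """
    replicated_set = set(replicated) if replicated is not None else None
    candidates = [r for r in records if r.pval <= p_threshold]
    if replicated_set is not None:
        candidates = [r for r in candidates if r.snp_id in replicated_set]
    if ld is not None:
        missing = [r.snp_id for r in candidates if r.snp_id not in ld._index]
        if missing:
            raise KeyError(f"SNP(s) missing from LD matrix: {', '.join(missing)}")
    candidates.sort(key=lambda r: (r.pval, r.snp_id))
    kept: list[SummaryStatRecord] = []
    for rec in candidates:
        if ld is not None and any(
            ld.lookup(rec.snp_id, k.snp_id) >= r2_max for k in kept
        ):
            logger.info("select_instruments: %s pruned for LD", rec.snp_id)
            continue
        kept.append(rec)
    return kept


def variance_explained(
    records: Sequence[SummaryStatRecord], phenotype_variance: float = 1.0
) -> float:
    """Proportion of phenotype variance explained by the instruments.

    Computed as ``sum_j 2 * eaf_j * (1 - eaf_j) * beta_j**2`` divided by the
    phenotype variance (1 for standardized traits). This additive
    approximation ignores LD between the variants.
    """
    total = 0.0
    for rec in records:
        if rec.eaf is None:
            raise ValueError(f"{rec.snp_id}: eaf required for variance_explained")
        total += 2.0 * rec.eaf * (1.0 - rec.eaf) * rec.beta ** 2
    return total / phenotype_variance
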