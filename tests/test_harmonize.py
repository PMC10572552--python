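"""Allele harmonization, instrument selection and variance explained."""
import numpy as np
import pytest

from lpamr.mr import (
    HarmonizationError,
    LDMatrix,
    SummaryStatRecord,
    harmonize,
    select_instruments,
    variance_explained,
)


def rec(snp, ea, oa, beta, se=0.01, pval=1e-8, eaf=None):
    return SummaryStatRecord(snp_id=snp, effect_allele=ea, other_allele=oa,
                             beta=beta, se=se, pval=pval, eaf=eaf)


class TestHarmonize:
    def test_bundled_panels_join_without_flips(self, exposure_panel, outcome_panel):
        insts = harmonize(exposure_panel, outcome_panel)
        assert len(insts) == 6
        assert not any(i.flipped for i in insts)
        assert insts[0].snp_id == "rs11206510"

    def test_swapped_outcome_alleles_are_flipped_back(self):
        exp = [rec("rs1", "T", "C", -0.05)]
        out_fwd = [rec("rs1", "T", "C", -0.004)]
        out_swp = [rec("rs1", "C", "T", 0.004)]
        fwd = harmonize(exp, out_fwd)[0]
        swp = harmonize(exp, out_swp)[0]
        assert swp.flipped and not fwd.flipped
        assert swp.beta_out == pytest.approx(fwd.beta_out)
        assert swp.wald_ratio == pytest.approx(fwd.wald_ratio)

    def test_strand_complement_labels_resolved(self):
        exp = [rec("rs1", "T", "C", -0.05)]
        out = [rec("rs1", "A", "G", -0.004)]  # same variant on the other strand
        inst = harmonize(exp, out)[0]
        assert not inst.flipped
        assert inst.beta_out == -0.004
        out_swapped = [rec("rs1", "G", "A", 0.004)]
        inst2 = harmonize(exp, out_swapped)[0]
        assert inst2.flipped and inst2.beta_out == pytest.approx(-0.004)

    def test_palindromic_policies(self):
        exp = [rec("rs1", "A", "T", 0.1, eaf=0.1), rec("rs2", "A", "C", 0.1)]
        out = [rec("rs1", "A", "T", 0.01, eaf=0.85), rec("rs2", "A", "C", 0.01)]
        dropped = harmonize(exp, out, palindromic_policy="drop")
        assert [i.snp_id for i in dropped] == ["rs2"]
        kept = harmonize(exp, out, palindromic_policy="keep")
        assert len(kept) == 2 and not kept[0].flipped
        resolved = harmonize(exp, out, palindromic_policy="resolve-by-eaf")
        rs1 = next(i for i in resolved if i.snp_id == "rs1")
        assert rs1.flipped and rs1.beta_out == pytest.approx(-0.01)

    def test_resolve_by_eaf_missing_frequency_names_snp(self):
        exp = [rec("rs9", "A", "T", 0.1)]
        out = [rec("rs9", "A", "T", 0.01, eaf=0.2)]
        with pytest.raises(HarmonizationError, match="rs9"):
            harmonize(exp, out, palindromic_policy="resolve-by-eaf")

    def test_incompatible_alleles_excluded(self):
        exp = [rec("rs1", "A", "C", 0.1), rec("rs2", "A", "G", 0.1)]
        out = [rec("rs1", "A", "C", 0.01), rec("rs2", "A", "C", 0.01)]
        insts = harmonize(exp, out)
        assert [i.snp_id for i in insts] == ["rs1"]

    def test_empty_intersection_raises(self):
        with pytest.raises(HarmonizationError, match="intersection"):
            harmonize([rec("rs1", "A", "C", 0.1)], [rec("rs2", "A", "C", 0.1)])

    def test_double_harmonization_is_identity(self, exposure_panel, outcome_panel):
        once = harmonize(exposure_panel, outcome_panel)
        # re-expressing the outcome on the harmonized effect allele changes nothing
        out2 = [
            SummaryStatRecord(
                snp_id=i.snp_id, effect_allele=e.effect_allele, other_allele=e.other_allele,
                beta=i.beta_out, se=i.se_out, pval=0.5,
            )
            for i, e in zip(once, exposure_panel)
        ]
        twice = harmonize(exposure_panel, out2)
        for a, b in zip(once, twice):
            assert a.beta_out == pytest.approx(b.beta_out)
            assert not b.flipped


def _greedy_oracle(records, ld, r2_max):
    """Independent restatement of the greedy pruning rule."""
    cands = sorted(records, key=lambda r: (r.pval, r.snp_id))
    kept = []
    for c in cands:
        if all(ld.lookup(c.snp_id, k.snp_id) < r2_max for k in kept):
            kept.append(c)
    return [k.snp_id for k in kept]


class TestSelectInstruments:
    def test_bundled_panel_all_retained_below_ld_threshold(self, exposure_panel, rng):
        ids = [r.snp_id for r in exposure_panel]
        k = len(ids)
        base = rng.uniform(0.0, 0.45, size=(k, k))
        r2 = (base + base.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(snp_ids=ids, r2=r2)
        kept = select_instruments(exposure_panel, p_threshold=5e-7, ld=ld, r2_max=0.5)
        assert sorted(r.snp_id for r in kept) == sorted(ids)

    def test_high_ld_pair_keeps_smaller_p(self):
        a = rec("rsA", "A", "C", 0.1, pval=1e-10)
        b = rec("rsB", "A", "C", 0.1, pval=1e-8)
        ld = LDMatrix(["rsA", "rsB"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        kept = select_instruments([b, a], ld=ld, r2_max=0.5)
        assert [r.snp_id for r in kept] == ["rsA"]

    def test_matches_greedy_oracle_on_random_candidates(self, rng):
        n = 10
        ids = [f"rs{i:02d}" for i in range(n)]
        recs = [rec(s, "A", "G", 0.1, pval=float(rng.uniform(0, 4e-7))) for s in ids]
        base = rng.uniform(0, 1, size=(n, n))
        r2 = (base + base.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(ids, r2)
        kept = select_instruments(recs, ld=ld, r2_max=0.5)
        assert [r.snp_id for r in kept] == _greedy_oracle(recs, ld, 0.5)

    def test_missing_snp_in_ld_is_named(self):
        ld = LDMatrix(["rsA"], np.array([[1.0]]))
        with pytest.raises(KeyError, match="rsB"):
            select_instruments([rec("rsB", "A", "C", 0.1)], ld=ld)

    def test_replicated_filter(self):
        recs = [rec("rsA", "A", "C", 0.1), rec("rsB", "A", "C", 0.1)]
        kept = select_instruments(recs, replicated={"rsA"})
        assert [r.snp_id for r in kept] == ["rsA"]


class TestVarianceExplained:
    def test_single_snp_arithmetic(self):
        assert variance_explained([rec("rs1", "A", "C", 0.2, eaf=0.5)]) == pytest.approx(0.02)

    def test_zero_betas(self):
        recs = [rec(f"rs{i}", "A", "C", 0.0, eaf=0.3) for i in range(3)]
        assert variance_explained(recs) == 0.0

    def test_three_snp_term_sum(self):
        triples = [(0.1, 0.25), (0.2, 0.4), (0.05, 0.1)]
        recs = [rec(f"rs{i}", "A", "C", b, eaf=f) for i, (b, f) in enumerate(triples)]
        expected = sum(2 * f * (1 - f) * b**2 for b, f in triples)
        assert variance_explained(recs) == pytest.approx(expected)

    def test_missing_eaf_raises(self):
        with pytest.raises(ValueError, match="eaf"):
            variance_explained([rec("rs1", "A", "C", 0.1)])
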