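"""MR estimators against hand-computed oracles and degenerate cases."""
import numpy as np
import pytest
from scipy import stats

from lpamr.mr import (
    HarmonizedInstrument,
    cochran_q,
    egger,
    ivw,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)


def inst(snp, be, se_e, bo, so, **kw):
    return HarmonizedInstrument(snp_id=snp, beta_exp=be, se_exp=se_e,
                                beta_out=bo, se_out=so, **kw)


def make_ratio_insts(ratios, wald_ses, se_exp=0.01):
    """Instruments with beta_exp = 1 so the ratio and weight are explicit."""
    return [
        inst(f"s{i}", 1.0, se_exp, r, s)
        for i, (r, s) in enumerate(zip(ratios, wald_ses))
    ]


class TestWaldRatio:
    @pytest.mark.parametrize(
        "snp,expected_beta,expected_se",
        [("rs11591147", 0.116, 0.032), ("rs499718", 0.042, 0.056),
         ("rs11206510", 0.068, 0.068), ("rs2479409", 0.060, 0.054)],
    )
    def test_published_per_snp_ratios(self, six_instruments, snp, expected_beta, expected_se):
        est = wald_ratio(next(i for i in six_instruments if i.snp_id == snp))
        # the published inputs are rounded to 3 decimals, so the recomputed
        # ratio can differ from the printed one by up to a printed ulp
        assert est.beta == pytest.approx(expected_beta, rel=0.02, abs=1e-3)
        assert est.se == pytest.approx(expected_se, rel=0.02, abs=1e-3)

    def test_zero_outcome_beta_gives_zero_ratio(self):
        est = wald_ratio(inst("s", -0.3, 0.02, 0.0, 0.01))
        assert est.beta == 0.0 and est.pval == pytest.approx(1.0)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError, match="Wald ratio"):
            inst("s", 0.0, 0.02, 0.01, 0.01)


class TestIVW:
    def test_three_term_arithmetic_oracle(self):
        ratios, ses = [0.05, 0.10, -0.02], [0.02, 0.05, 0.04]
        insts = make_ratio_insts(ratios, ses)
        w = [1 / s**2 for s in ses]
        expected = sum(wi * ri for wi, ri in zip(w, ratios)) / sum(w)
        est = ivw(insts, mode="fixed")
        assert est.beta == pytest.approx(expected, rel=1e-12)
        assert est.se == pytest.approx(sum(w) ** -0.5, rel=1e-12)

    def test_equals_origin_regression(self, six_instruments):
        # weighted regression of beta_out on beta_exp through the origin
        be = np.array([i.beta_exp for i in six_instruments])
        bo = np.array([i.beta_out for i in six_instruments])
        w = np.array([i.se_out**-2 for i in six_instruments])
        slope = np.sum(w * be * bo) / np.sum(w * be**2)
        assert ivw(six_instruments).beta == pytest.approx(slope, rel=1e-12)

    def test_identical_ratios_degenerate(self):
        insts = make_ratio_insts([0.07] * 3, [0.02, 0.03, 0.04])
        fixed, mre = ivw(insts, "fixed"), ivw(insts, "mre")
        assert mre.beta == pytest.approx(0.07)
        assert mre.se == pytest.approx(fixed.se)  # Q = 0, floor active
        assert cochran_q(insts).q == pytest.approx(0.0, abs=1e-12)

    def test_mre_se_never_below_fixed(self, six_instruments, hand_instruments):
        for insts in (six_instruments, hand_instruments):
            assert ivw(insts, "mre").se >= ivw(insts, "fixed").se - 1e-15

    def test_sign_flip_invariance(self, six_instruments):
        flipped = [
            inst(i.snp_id, -i.beta_exp, i.se_exp, -i.beta_out, i.se_out)
            for i in six_instruments
        ]
        assert ivw(flipped).beta == pytest.approx(ivw(six_instruments).beta, rel=1e-12)

    def test_too_few_instruments(self, six_instruments):
        with pytest.raises(ValueError, match="at least 2"):
            ivw(six_instruments[:1])


class TestEgger:
    def test_wls_normal_equation_oracle(self, hand_instruments):
        be = np.array([abs(i.beta_exp) for i in hand_instruments])
        bo = np.array([i.beta_out * (1 if i.beta_exp > 0 else -1) for i in hand_instruments])
        w = np.array([i.se_out**-2 for i in hand_instruments])
        # closed-form 2x2 weighted normal equations
        sw, swx = w.sum(), (w * be).sum()
        swxx, swy, swxy = (w * be * be).sum(), (w * bo).sum(), (w * be * bo).sum()
        det = sw * swxx - swx**2
        slope = (sw * swxy - swx * swy) / det
        intercept = (swxx * swy - swx * swxy) / det
        res = egger(hand_instruments)
        assert res.slope.beta == pytest.approx(slope, rel=1e-10)
        assert res.intercept == pytest.approx(intercept, rel=1e-10)

    def test_exact_linear_relation_recovers_theta_with_zero_intercept(self):
        theta = 0.07
        be = [0.1, 0.2, 0.3, 0.4]
        insts = [inst(f"s{i}", b, 0.01, theta * b, 0.01) for i, b in enumerate(be)]
        res = egger(insts)
        assert res.slope.beta == pytest.approx(theta, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_slope_se_floor_matches_unit_scale(self):
        # exact fit -> residual scale 0 -> SE floored at the fixed-effect value
        insts = [inst(f"s{i}", b, 0.01, 0.05 * b, 0.01) for i, b in enumerate([0.1, 0.2, 0.3])]
        res = egger(insts)
        be = np.array([0.1, 0.2, 0.3])
        w = np.full(3, 0.01**-2.0)
        X = np.column_stack([np.ones(3), be])
        cov = np.linalg.inv(X.T @ (w[:, None] * X))
        assert res.slope.se == pytest.approx(np.sqrt(cov[1, 1]))

    def test_inference_uses_t_distribution(self, six_instruments):
        res = egger(six_instruments)
        t = res.slope.beta / res.slope.se
        assert res.slope.pval == pytest.approx(2 * stats.t.sf(abs(t), 4), rel=1e-12)
        assert res.slope.inference_df == 4

    def test_errors(self, six_instruments):
        with pytest.raises(ValueError, match="at least 3"):
            egger(six_instruments[:2])
        same = [inst(f"s{i}", 0.2, 0.01, 0.01 * i, 0.01) for i in range(3)]
        with pytest.raises(ValueError, match="spread"):
            egger(same)


class TestWeightedMedian:
    def test_cumulative_weight_walk_oracle(self):
        ratios = [0.02, 0.05, 0.07, 0.11, 0.30]
        weights = [1.0, 2.0, 4.0, 2.0, 1.0]
        total = sum(weights)
        cum, ps = 0.0, []
        for w in weights:
            ps.append((cum + w / 2) / total)
            cum += w
        # 0.5 falls between ps[2] and ps[3]: interpolate ratios[2]..ratios[3]
        expected = ratios[2] + (ratios[3] - ratios[2]) * (0.5 - ps[2]) / (ps[3] - ps[2])
        got = weighted_median_point(np.array(ratios), np.array(weights))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_equal_ratios_and_small_bootstrap_se(self):
        insts = make_ratio_insts([0.08] * 4, [0.001] * 4, se_exp=1e-5)
        est = weighted_median(insts, n_boot=200, seed=7)
        assert est.beta == pytest.approx(0.08)
        assert est.se < 0.01

    def test_equal_weights_match_simple_median(self, rng):
        ratios = rng.normal(0.1, 0.05, size=7)
        got = weighted_median_point(ratios, np.ones(7))
        # with odd n and equal weights p_j brackets 0.5 at the middle ratio
        assert got == pytest.approx(np.median(ratios))

    def test_estimate_within_ratio_range(self, six_instruments):
        est = weighted_median(six_instruments, n_boot=100, seed=3)
        ratios = [i.wald_ratio for i in six_instruments]
        assert min(ratios) <= est.beta <= max(ratios)

    def test_bootstrap_reproducible_from_seed(self, six_instruments):
        a = weighted_median(six_instruments, n_boot=100, seed=11)
        b = weighted_median(six_instruments, n_boot=100, seed=11)
        assert a.se == b.se

    def test_errors(self, six_instruments):
        with pytest.raises(ValueError, match="at least 3"):
            weighted_median(six_instruments[:2], seed=1)
        with pytest.raises(ValueError, match="n_boot"):
            weighted_median(six_instruments, n_boot=1, seed=1)
        with pytest.raises(ValueError, match="seed"):
            weighted_median(six_instruments)


class TestCochranQ:
    def test_brute_force_definition(self, six_instruments):
        r = np.array([i.wald_ratio for i in six_instruments])
        w = np.array([i.weight for i in six_instruments])
        b = (w * r).sum() / w.sum()
        expected = sum(wi * (ri - b) ** 2 for wi, ri in zip(w, r))
        res = cochran_q(six_instruments)
        assert res.q == pytest.approx(expected, rel=1e-12)
        assert res.df == 5

    def test_reorder_invariance(self, six_instruments, rng):
        perm = list(rng.permutation(len(six_instruments)))
        shuffled = [six_instruments[i] for i in perm]
        assert cochran_q(shuffled).q == pytest.approx(cochran_q(six_instruments).q)

    def test_identical_ratios_q_zero_p_one(self):
        insts = make_ratio_insts([0.05] * 3, [0.01, 0.02, 0.03])
        res = cochran_q(insts)
        assert res.q == pytest.approx(0.0, abs=1e-12)
        assert res.pval == pytest.approx(1.0)
        assert res.i2 == 0.0

    def test_rucker_q_about_egger_fit(self, six_instruments):
        res = cochran_q(six_instruments, about="egger")
        assert res.df == 4
        # residual Q' of the Egger fit is never above the IVW Q
        assert res.q <= cochran_q(six_instruments).q + 1e-12
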