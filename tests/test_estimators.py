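"""Estimator suite: Wald ratio, IVW, weighted median, Egger, radial, LOO."""

import dataclasses
import math

import numpy as np
import pytest
import statsmodels.api as sm

from mrpipe.estimators import (
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    radial_ivw,
    remove_outliers_and_reestimate,
    wald_ratio,
    weighted_median,
)

from conftest import make_instrument, random_instruments


def collinear(ratio=0.5, n=3, sy=0.01):
    return [
        make_instrument(
            snp_id=f"rs{j + 1}",
            beta_exposure=0.1 * (j + 1),
            beta_outcome=ratio * 0.1 * (j + 1),
            se_outcome=sy,
        )
        for j in range(n)
    ]


class TestWaldRatio:
    def test_arithmetic(self):
        e = wald_ratio(make_instrument(beta_exposure=0.1, beta_outcome=0.05, se_outcome=0.01))
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.1)
        assert e.n_snp == 1

    def test_null_outcome(self):
        e = wald_ratio(make_instrument(beta_outcome=0.0))
        assert e.beta == 0.0 and e.pvalue == 1.0

    def test_zero_exposure_raises(self):
        with pytest.raises(ValueError):
            wald_ratio(make_instrument(beta_exposure=0.0))

    def test_second_order_se_larger(self):
        inst = make_instrument(beta_exposure=0.1, se_exposure=0.05, beta_outcome=0.05)
        assert wald_ratio(inst, second_order=True).se > wald_ratio(inst).se

    def test_estimate_invariants(self):
        e = wald_ratio(make_instrument())
        assert e.ci_low <= e.beta <= e.ci_high
        assert e.odds_ratio == pytest.approx(math.exp(e.beta), abs=1e-12)
        assert e.or_ci_low == pytest.approx(math.exp(e.ci_low))


class TestIVW:
    def test_three_point_derived_example(self):
        est, het = ivw(collinear(ratio=0.5), model="fixed")
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert het.Q == pytest.approx(0.0, abs=1e-18)
        assert est.se == pytest.approx(1.0 / math.sqrt(1400.0))

    def test_single_instrument_reduces_to_wald(self):
        inst = make_instrument(beta_exposure=0.2, beta_outcome=0.07, se_outcome=0.02)
        est, het = ivw([inst], model="random")
        wald = wald_ratio(inst)
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)
        assert (het.Q, het.df) == (0.0, 0)

    def test_collinear_random_equals_fixed(self):
        est_f, _ = ivw(collinear(), model="fixed")
        est_r, _ = ivw(collinear(), model="random")
        assert est_r.se == pytest.approx(est_f.se)

    def test_matches_wls_oracle(self, rng):
        """Point estimate and fixed SE equal a weighted least-squares solve."""
        for _ in range(20):
            insts = random_instruments(rng, 10, beta=0.3, het_sd=0.5)
            bx = np.array([h.beta_exposure for h in insts])
            by = np.array([h.beta_outcome for h in insts])
            sy = np.array([h.se_outcome for h in insts])
            fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
            est, het = ivw(insts, model="fixed")
            assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
            # statsmodels scales by residual variance; undo to get the
            # fixed-effect (known-variance) SE
            se_fixed = float(fit.bse[0]) / math.sqrt(fit.scale)
            assert est.se == pytest.approx(se_fixed, abs=1e-10)
            resid_q = float(np.sum((by - fit.params[0] * bx) ** 2 / sy**2))
            assert het.Q == pytest.approx(resid_q, abs=1e-8)

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(20):
            insts = random_instruments(rng, 8, het_sd=rng.uniform(0, 1))
            est_f, het = ivw(insts, model="fixed")
            est_r, _ = ivw(insts, model="random")
            assert est_r.se >= est_f.se - 1e-15
            if het.Q <= het.df:
                assert est_r.se == pytest.approx(est_f.se)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ivw([])


class TestCochranQ:
    def test_identical_ratios(self):
        het = cochran_q(collinear(ratio=0.5), beta_ref=0.5)
        assert het.Q == pytest.approx(0.0, abs=1e-18) and het.pvalue == pytest.approx(1.0)

    def test_two_term_hand_expansion(self):
        # w * bx^2 = 1 for each (bx=0.1, sy=0.1); ratios 0 and 1, ref 0.5
        insts = [
            make_instrument(snp_id="rs1", beta_exposure=0.1, beta_outcome=0.0, se_outcome=0.1),
            make_instrument(snp_id="rs2", beta_exposure=0.1, beta_outcome=0.1, se_outcome=0.1),
        ]
        het = cochran_q(insts, beta_ref=0.5)
        assert het.Q == pytest.approx(0.5) and het.df == 1

    def test_monotone_in_residual(self):
        insts = collinear(ratio=0.5, n=4)
        base = cochran_q(insts, beta_ref=0.5).Q
        bumped = [dataclasses.replace(insts[0], beta_outcome=insts[0].beta_outcome + 0.05)] + insts[1:]
        assert cochran_q(bumped, beta_ref=0.5).Q > base

    def test_fewer_than_two_raises(self):
        with pytest.raises(ValueError):
            cochran_q(collinear()[:1], beta_ref=0.5)


class TestWeightedMedian:
    def test_equal_weights_is_median(self):
        insts = [
            make_instrument(snp_id=f"rs{j}", beta_exposure=0.1, beta_outcome=0.1 * r, se_outcome=0.01)
            for j, r in enumerate([0.1, 0.5, 0.9])
        ]
        e = weighted_median(insts, n_boot=100, seed=1)
        assert e.beta == pytest.approx(0.5)

    def test_equal_weights_matches_sample_median_odd_n(self, rng):
        ratios = rng.uniform(-1, 1, size=7)
        insts = [
            make_instrument(snp_id=f"rs{j}", beta_exposure=0.1, beta_outcome=0.1 * r, se_outcome=0.01)
            for j, r in enumerate(ratios)
        ]
        e = weighted_median(insts, n_boot=50, seed=1)
        assert e.beta == pytest.approx(float(np.median(ratios)))

    def test_dominant_instrument_controls_estimate(self):
        # rs1 holds > 50% of total weight, so the estimate stays within
        # interpolation distance of its ratio
        insts = [
            make_instrument(snp_id="rs1", beta_exposure=0.4, beta_outcome=0.12, se_outcome=0.005),
            make_instrument(snp_id="rs2", beta_exposure=0.05, beta_outcome=0.05, se_outcome=0.05),
            make_instrument(snp_id="rs3", beta_exposure=0.05, beta_outcome=0.06, se_outcome=0.05),
        ]
        ratios = sorted([0.12 / 0.4, 1.0, 1.2])
        e = weighted_median(insts, n_boot=50, seed=1)
        # dominant ratio is 0.3; the next ratio up is 1.0
        assert abs(e.beta - 0.3) < abs(1.0 - 0.3)

    def test_order_invariance(self, rng):
        insts = random_instruments(rng, 6, het_sd=0.3)
        e1 = weighted_median(insts, n_boot=200, seed=9)
        e2 = weighted_median(insts[::-1], n_boot=200, seed=9)
        assert e1.beta == pytest.approx(e2.beta, abs=1e-14)

    def test_bootstrap_seed_reproducible(self, rng):
        insts = random_instruments(rng, 5, het_sd=0.2)
        assert weighted_median(insts, seed=3).se == weighted_median(insts, seed=3).se

    def test_fewer_than_three_raises(self):
        with pytest.raises(ValueError):
            weighted_median(collinear()[:2])


class TestEgger:
    def test_exact_fit_recovered(self):
        insts = [
            make_instrument(
                snp_id=f"rs{j}",
                beta_exposure=bx,
                beta_outcome=0.02 + 0.5 * bx,
                se_outcome=0.01,
            )
            for j, bx in enumerate([0.1, 0.2, 0.3, 0.4])
        ]
        res = egger(insts)
        assert res.intercept == pytest.approx(0.02, abs=1e-12)
        assert res.slope.beta == pytest.approx(0.5, abs=1e-12)

    def test_zero_intercept_slope_equals_ivw(self):
        insts = collinear(ratio=0.7, n=5)
        res = egger(insts)
        est, _ = ivw(insts, model="fixed")
        assert res.slope.beta == pytest.approx(est.beta, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_wls_oracle(self, rng):
        for _ in range(20):
            insts = random_instruments(rng, 10, beta=0.4, het_sd=0.6)
            bx = np.array([h.beta_exposure for h in insts])
            by = np.array([h.beta_outcome for h in insts])
            sy = np.array([h.se_outcome for h in insts])
            flip = np.where(bx < 0, -1.0, 1.0)
            x, y = bx * flip, by * flip
            fit = sm.WLS(y, sm.add_constant(x), weights=1 / sy**2).fit()
            res = egger(insts)
            assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert res.slope.beta == pytest.approx(fit.params[1], abs=1e-10)
            # statsmodels uses the estimated scale; ours floors it at 1
            n = len(insts)
            qp = float(np.sum((y - fit.params[0] - fit.params[1] * x) ** 2 / sy**2))
            unscaled = np.asarray(fit.bse) / math.sqrt(fit.scale)
            expected = unscaled * max(1.0, math.sqrt(qp / (n - 2)))
            assert res.intercept_se == pytest.approx(expected[0], abs=1e-10)
            assert res.slope.se == pytest.approx(expected[1], abs=1e-10)

    def test_orientation_invariance(self, rng):
        insts = random_instruments(rng, 6, het_sd=0.4)
        negated = [
            dataclasses.replace(
                insts[0], beta_exposure=-insts[0].beta_exposure,
                beta_outcome=-insts[0].beta_outcome,
            )
        ] + insts[1:]
        r1, r2 = egger(insts), egger(negated)
        assert r1.slope.beta == pytest.approx(r2.slope.beta, abs=1e-14)
        assert r1.intercept == pytest.approx(r2.intercept, abs=1e-14)

    def test_requires_three_and_variance(self):
        with pytest.raises(ValueError):
            egger(collinear()[:2])
        constant_bx = [
            make_instrument(snp_id=f"rs{j}", beta_exposure=0.1, beta_outcome=0.01 * j)
            for j in range(4)
        ]
        with pytest.raises(ValueError, match="singular"):
            egger(constant_bx)


class TestRadial:
    def test_homogeneous_no_outliers(self):
        res = radial_ivw(collinear(ratio=0.5, n=4))
        assert all(q == pytest.approx(0.0, abs=1e-18) for q in res.q_contribution)
        assert not any(res.is_outlier)

    def test_slope_identical_to_ivw(self, rng):
        for _ in range(30):
            insts = random_instruments(rng, 12, het_sd=0.5)
            res = radial_ivw(insts)
            est, _ = ivw(insts, model="fixed")
            assert res.estimate.beta == pytest.approx(est.beta, abs=1e-10)

    def test_q_contributions_sum_to_q(self, rng):
        insts = random_instruments(rng, 10, het_sd=0.4)
        res = radial_ivw(insts)
        _, het = ivw(insts, model="fixed")
        # radial Q with first-order weights equals the IVW Cochran Q
        assert res.Q == pytest.approx(het.Q, abs=1e-8)

    def test_displaced_instrument_flagged(self, rng):
        insts = collinear(ratio=0.5, n=10, sy=0.01)
        bad = dataclasses.replace(
            insts[0],
            # shift the ratio by ~10 SE of the ratio (se_y / bx = 0.1)
            beta_outcome=insts[0].beta_outcome + 10 * insts[0].se_outcome,
        )
        res = radial_ivw([bad] + insts[1:])
        assert res.is_outlier[0]
        assert sum(res.is_outlier) == 1


class TestOutlierRemovalAndLOO:
    def test_no_outliers_identity(self):
        insts = collinear(ratio=0.5, n=5)
        res = radial_ivw(insts)
        est, _ = remove_outliers_and_reestimate(insts, res)
        full, _ = ivw(insts, model="random")
        assert est.beta == pytest.approx(full.beta)

    def test_removal_improves_truth_recovery_and_decreases_q(self):
        insts = collinear(ratio=0.5, n=10)
        contaminated = [
            dataclasses.replace(insts[0], beta_outcome=insts[0].beta_outcome + 0.2)
        ] + insts[1:]
        radial = radial_ivw(contaminated)
        pre, pre_het = ivw(contaminated, model="random")
        post, post_het = remove_outliers_and_reestimate(contaminated, radial)
        assert abs(post.beta - 0.5) < abs(pre.beta - 0.5)
        assert post_het.Q < pre_het.Q

    def test_all_flagged_raises(self):
        insts = [
            make_instrument(snp_id="rs1", beta_exposure=0.3, beta_outcome=0.5, se_outcome=0.001),
            make_instrument(snp_id="rs2", beta_exposure=0.3, beta_outcome=-0.5, se_outcome=0.001),
        ]
        radial = radial_ivw(insts)
        assert all(radial.is_outlier)
        with pytest.raises(ValueError):
            remove_outliers_and_reestimate(insts, radial)

    def test_loo_cardinality_and_homogeneous_case(self):
        insts = collinear(ratio=0.5, n=5)
        results = leave_one_out(insts)
        assert len(results) == 5
        assert all(est.n_snp == 4 for _, est in results)
        assert all(est.beta == pytest.approx(0.5) for _, est in results)

    def test_loo_excluding_planted_outlier_deviates_most(self):
        insts = collinear(ratio=0.5, n=8)
        contaminated = [
            dataclasses.replace(insts[0], beta_outcome=insts[0].beta_outcome + 0.1)
        ] + insts[1:]
        full, _ = ivw(contaminated, model="random")
        results = leave_one_out(contaminated)
        deviations = {sid: abs(est.beta - full.beta) for sid, est in results}
        assert max(deviations, key=deviations.get) == "rs1"


class TestGlobalProperties:
    def test_scale_equivariance(self, rng):
        insts = random_instruments(rng, 7, het_sd=0.3)
        c = 2.5
        scaled = [
            dataclasses.replace(
                h, beta_exposure=c * h.beta_exposure, se_exposure=c * h.se_exposure
            )
            for h in insts
        ]
        for model in ("fixed", "random"):
            assert ivw(scaled, model)[0].beta == pytest.approx(
                ivw(insts, model)[0].beta / c
            )
        assert egger(scaled).slope.beta == pytest.approx(egger(insts).slope.beta / c)
        assert weighted_median(scaled, n_boot=10, seed=1).beta == pytest.approx(
            weighted_median(insts, n_boot=10, seed=1).beta / c
        )

    def test_reorder_and_flip_invariance(self, rng):
        insts = random_instruments(rng, 9, het_sd=0.4)
        perm = [insts[i] for i in rng.permutation(len(insts))]
        flipped = [
            dataclasses.replace(
                h, beta_exposure=-h.beta_exposure, beta_outcome=-h.beta_outcome
            )
            for h in perm
        ]
        assert ivw(flipped)[0].beta == pytest.approx(ivw(insts)[0].beta)
        assert radial_ivw(flipped).estimate.beta == pytest.approx(
            radial_ivw(insts).estimate.beta
        )
        assert egger(flipped).slope.beta == pytest.approx(egger(insts).slope.beta)
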