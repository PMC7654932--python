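import math

import numpy as np
import pytest
from scipy import stats

import statsmodels.api as sm

from mrvalve.estimators import (
    funnel_data,
    ivw_random_effects,
    leave_one_out,
    mr_egger,
    wald_ratios,
    weighted_median,
    weighted_median_estimate,
)
from mrvalve.synthetic import SynthConfig, simulate_two_sample
from mrvalve.harmonize import harmonize, orient_positive_exposure

from conftest import make_hset


def random_hset(rng, J):
    bx = rng.uniform(0.03, 0.3, J)
    sx = rng.uniform(0.003, 0.01, J)
    sy = rng.uniform(0.01, 0.08, J)
    by = 0.3 * bx + sy * rng.standard_normal(J)
    return make_hset(bx, sx, by, sy)


class TestWaldRatios:
    def test_arithmetic(self):
        h = make_hset([0.2], [0.01], [0.1], [0.05])
        r = wald_ratios(h)
        assert r["ratio"].iloc[0] == pytest.approx(0.5)
        assert r["se"].iloc[0] == pytest.approx(0.25)

    def test_zero_outcome_gives_zero_ratio(self):
        h = make_hset([0.2], [0.01], [0.0], [0.05])
        assert wald_ratios(h)["ratio"].iloc[0] == 0.0

    def test_elementwise_recomputation(self):
        rng = np.random.default_rng(1)
        h = random_hset(rng, 3)
        r = wald_ratios(h)
        bx, sx, by, sy = h.arrays()
        np.testing.assert_allclose(r["ratio"], by / bx, rtol=1e-15)
        np.testing.assert_allclose(r["se"], sy / np.abs(bx), rtol=1e-15)

    def test_empty_set_raises(self):
        h = make_hset([0.1], [0.01], [0.1], [0.05]).subset([])
        with pytest.raises(ValueError):
            wald_ratios(h)


class TestIVW:
    def test_homogeneous_ratios_zero_q(self):
        h = make_hset([0.1, 0.2], [0.01, 0.01], [0.05, 0.10], [0.02, 0.03])
        f = ivw_random_effects(h)
        assert f.beta == pytest.approx(0.5)
        assert f.extras["Q"] == pytest.approx(0.0, abs=1e-24)
        # no inflation below df
        w = np.array([0.1, 0.2]) ** 2 / np.array([0.02, 0.03]) ** 2
        assert f.se == pytest.approx(w.sum() ** -0.5)

    def test_single_variant_reduces_to_wald_ratio(self):
        h = make_hset([0.2], [0.01], [0.1], [0.05])
        f = ivw_random_effects(h)
        assert f.beta == pytest.approx(0.5)
        assert f.se == pytest.approx(0.25)
        assert f.extras.get("single_variant")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_wls_through_origin_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = random_hset(rng, 5 + seed)
        bx, sx, by, sy = h.arrays()
        fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        mine = ivw_random_effects(h)
        assert mine.beta == pytest.approx(fit.params[0], rel=1e-10)
        # fixed-effect SE: statsmodels scales by sigma-hat; undo it
        se_fixed = fit.bse[0] / np.sqrt(fit.scale)
        q = float(fit.ssr)  # weighted RSS at the WLS solution
        J = len(h)
        expect_se = se_fixed * max(1.0, math.sqrt(q / (J - 1)))
        assert mine.se == pytest.approx(expect_se, rel=1e-10)
        assert mine.extras["Q"] == pytest.approx(q, rel=1e-10)
        assert mine.extras["Q_p"] == pytest.approx(stats.chi2.sf(q, J - 1), rel=1e-10)

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        h = random_hset(rng, 8)
        perm = h.data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        import dataclasses

        h2 = dataclasses.replace(h, data=perm)
        a, b = ivw_random_effects(h), ivw_random_effects(h2)
        assert a.beta == pytest.approx(b.beta, rel=1e-14)
        assert a.se == pytest.approx(b.se, rel=1e-14)

    def test_or_triplet_consistent(self, simple_hset):
        f = ivw_random_effects(simple_hset)
        assert f.or_ == pytest.approx(math.exp(f.beta))
        assert f.ci_low <= f.beta <= f.ci_high


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.1 + 0.4 * bx
        h = make_hset(bx, [0.01] * 3, by, [0.02, 0.03, 0.04])
        f = mr_egger(h)
        assert f.extras["intercept"] == pytest.approx(0.1, rel=1e-12)
        assert f.beta == pytest.approx(0.4, rel=1e-12)
        assert f.extras["rss_w"] == pytest.approx(0.0, abs=1e-20)

    def test_too_few_variants_not_applicable(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        f = mr_egger(h)
        assert not f.applicable

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_wls_with_intercept_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        h = random_hset(rng, 10)
        bx, sx, by, sy = h.arrays()
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
        mine = mr_egger(h)
        assert mine.extras["intercept"] == pytest.approx(fit.params[0], rel=1e-10)
        assert mine.beta == pytest.approx(fit.params[1], rel=1e-10)
        J = len(h)
        infl_ratio = max(1.0, fit.ssr / (J - 2)) / fit.scale  # scale = ssr/(J-2)
        assert mine.se == pytest.approx(fit.bse[1] * math.sqrt(infl_ratio), rel=1e-10)
        assert mine.extras["intercept_se"] == pytest.approx(
            fit.bse[0] * math.sqrt(infl_ratio), rel=1e-10
        )

    def test_balanced_pleiotropy_intercept_near_zero(self):
        # with zero-mean pleiotropy the intercept is centred on 0
        ints = []
        for rep in range(500):
            rng = np.random.default_rng(10_000 + rep)
            J = 50
            bx = np.abs(rng.standard_normal(J)) * 0.1 + 0.02
            sy = np.full(J, 0.04)
            alpha = 0.05 * rng.standard_normal(J)  # balanced
            by = 0.3 * bx + alpha + sy * rng.standard_normal(J)
            h = make_hset(bx, np.full(J, 0.005), by, sy)
            ints.append(mr_egger(h).extras["intercept"])
        mean = np.mean(ints)
        mcse = np.std(ints, ddof=1) / math.sqrt(len(ints))
        assert abs(mean) < 3 * mcse

    def test_directional_pleiotropy_intercept_recovered(self):
        # InSIDE holds, every variant pleiotropic with mean 0.05
        mu = 0.05
        ints = []
        for rep in range(300):
            rng = np.random.default_rng(20_000 + rep)
            J = 50
            bx = np.abs(rng.standard_normal(J)) * 0.1 + 0.02
            sy = np.full(J, 0.04)
            alpha = mu + 0.02 * rng.standard_normal(J)
            by = 0.3 * bx + alpha + sy * rng.standard_normal(J)
            h = make_hset(bx, np.full(J, 0.005), by, sy)
            ints.append(mr_egger(h).extras["intercept"])
        mean = np.mean(ints)
        mcse = np.std(ints, ddof=1) / math.sqrt(len(ints))
        assert abs(mean - mu) < 3 * mcse


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        est = weighted_median_estimate(np.array([1.0, 2.0, 3.0]), np.ones(3))
        assert est == pytest.approx(2.0)

    def test_degenerate_weight_concentration(self):
        r = np.array([0.1, 0.7, 2.0])
        w = np.array([1e-9, 1.0, 1e-9])
        assert weighted_median_estimate(r, w) == pytest.approx(0.7, abs=1e-6)

    def test_four_variant_interpolation_oracle(self):
        # hand-traced cumulative-midpoint interpolation
        r = np.array([1.0, 2.0, 4.0, 8.0])
        w = np.array([0.1, 0.2, 0.3, 0.4])
        # s = [0.05, 0.20, 0.45, 0.80]; 0.5 sits between s3=0.45 and s4=0.80
        expected = 4.0 + (0.5 - 0.45) / (0.80 - 0.45) * (8.0 - 4.0)
        assert weighted_median_estimate(r, w) == pytest.approx(expected, rel=1e-12)

    def test_zero_total_weight_raises(self):
        with pytest.raises(ValueError):
            weighted_median_estimate(np.array([1.0]), np.array([0.0]))

    def test_bootstrap_reproducible_and_order_invariant(self, simple_hset):
        import dataclasses

        a = weighted_median(simple_hset, n_boot=200, seed=7)
        b = weighted_median(simple_hset, n_boot=200, seed=7)
        assert (a.beta, a.se) == (b.beta, b.se)
        perm = simple_hset.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        c = weighted_median(
            dataclasses.replace(simple_hset, data=perm), n_boot=200, seed=7
        )
        assert c.beta == pytest.approx(a.beta, rel=1e-12)


class TestLeaveOneOut:
    def test_homogeneous_all_equal_full(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_hset(bx, [0.01] * 3, 0.5 * bx, [0.02] * 3)
        full = ivw_random_effects(h).beta
        for _, fit in leave_one_out(h):
            assert fit.beta == pytest.approx(full, rel=1e-12)

    def test_each_entry_matches_subset_recomputation(self, simple_hset):
        for vid, fit in leave_one_out(simple_hset):
            sub = simple_hset.drop([vid])
            ref = ivw_random_effects(sub)
            assert fit.beta == pytest.approx(ref.beta, rel=1e-14)
            assert fit.se == pytest.approx(ref.se, rel=1e-14)

    def test_gross_outlier_most_influential(self):
        rng = np.random.default_rng(9)
        J = 10
        bx = rng.uniform(0.1, 0.3, J)
        sy = np.full(J, 0.02)
        by = 0.5 * bx
        by[4] += 0.5  # gross outlier
        h = make_hset(bx, np.full(J, 0.005), by, sy)
        full = ivw_random_effects(h).beta
        deltas = {vid: abs(fit.beta - full) for vid, fit in leave_one_out(h)}
        assert max(deltas, key=deltas.get) == "rs4"


class TestFunnel:
    def test_precision_definition(self):
        h = make_hset([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.1, 0.2], [0.02, 0.04, 0.05])
        f = funnel_data(h)
        bx, sx, by, sy = h.arrays()
        np.testing.assert_allclose(f["precision"], np.abs(bx) / sy, rtol=1e-14)
        assert len(f) == 3

    def test_single_variant_single_row(self):
        h = make_hset([0.1], [0.01], [0.05], [0.02])
        assert len(funnel_data(h)) == 1

    def test_symmetric_set_uncorrelated(self):
        cfg = SynthConfig(n_variants=200, true_beta=0.3, seed=77)
        exp, out, _ = simulate_two_sample(cfg)
        h = orient_positive_exposure(harmonize(exp, out))
        f = funnel_data(h)
        corr = np.corrcoef(f["ratio"], f["precision"])[0, 1]
        assert abs(corr) < 0.2


class TestNullCalibrationSmall:
    def test_ivw_mean_unbiased_under_null(self):
        # quick null sanity at reduced size; the full calibration lives in
        # the acceptance suite
        est = []
        for rep in range(200):
            cfg = SynthConfig(n_variants=30, true_beta=0.0, seed=40_000 + rep)
            exp, out, _ = simulate_two_sample(cfg)
            h = orient_positive_exposure(harmonize(exp, out))
            est.append(ivw_random_effects(h).beta)
        mean = np.mean(est)
        mcse = np.std(est, ddof=1) / math.sqrt(len(est))
        assert abs(mean) < 3 * mcse
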