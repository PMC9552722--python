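"""IVW, weighted-median and MR-Egger estimators and the OR transform."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from conftest import make_variant, random_variants
from tsmr.estimators import (
    EstimationError,
    egger,
    ivw,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)
from tsmr.harmonize import orient_to_positive_exposure


def _arrays(variants):
    bx = np.array([v.beta_exp for v in variants])
    by = np.array([v.beta_out for v in variants])
    sy = np.array([v.se_out for v in variants])
    return bx, by, sy


class TestWaldRatio:
    def test_fixture_variant_first_order(self, fixture_variants):
        v = next(v for v in fixture_variants if v.snp_id == "rs17279437")
        r = wald_ratio(v)
        assert math.isclose(r.theta, -0.067 / 0.059, rel_tol=1e-12)
        assert math.isclose(r.se_theta, 0.023 / 0.059, rel_tol=1e-12)
        assert math.isclose(r.weight, r.se_theta**-2, rel_tol=1e-12)

    def test_zero_outcome_beta_gives_zero_ratio(self):
        v = make_variant(beta_out=0.0)
        assert wald_ratio(v, "first_order").theta == 0.0
        assert wald_ratio(v, "second_order").theta == 0.0

    def test_zero_exposure_beta_is_an_error(self):
        with pytest.raises(EstimationError, match="beta_exp"):
            wald_ratio(make_variant(beta_exp=0.0))

    def test_second_order_se_dominates_first_order(self):
        rng = np.random.default_rng(3)
        for v in random_variants(rng, 20):
            assert (
                wald_ratio(v, "second_order").se_theta
                >= wald_ratio(v, "first_order").se_theta
            )


class TestIVW:
    def test_fixture_estimate(self, fixture_variants):
        est = ivw(fixture_variants)
        assert math.isclose(est.beta, -0.6301164414042683, rel_tol=1e-10)
        assert math.isclose(est.se, 0.21895117043733078, rel_tol=1e-10)
        assert math.isclose(est.meta["se_fixed"], 0.2034594009292361, rel_tol=1e-10)
        assert est.nsnp == 4
        assert est.pval < 0.01
        assert math.isclose(est.or_, math.exp(est.beta), rel_tol=1e-12)

    def test_equals_zero_intercept_wls_oracle(self):
        """With first-order weights, IVW is the weighted zero-intercept
        regression of outcome on exposure betas (weights 1/se_out^2)."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            variants = random_variants(rng, 6)
            bx, by, sy = _arrays(variants)
            fit = sm.WLS(by, bx, weights=sy**-2).fit()
            assert math.isclose(ivw(variants).beta, fit.params[0], rel_tol=1e-10)

    def test_identical_ratios_are_degenerate(self):
        variants = [
            make_variant(snp_id=f"rs{i}", beta_exp=b, beta_out=-0.5 * b)
            for i, b in enumerate((0.02, 0.04, 0.06))
        ]
        est = ivw(variants)
        assert math.isclose(est.beta, -0.5, rel_tol=1e-12)
        assert est.meta["q"] == pytest.approx(0.0, abs=1e-20)
        assert est.se == est.meta["se_fixed"]

    def test_beta_within_ratio_range_and_permutation_invariant(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            variants = random_variants(rng, 7)
            est = ivw(variants)
            thetas = [v.wald_ratio for v in variants]
            assert min(thetas) <= est.beta <= max(thetas)
            rng.shuffle(variants)
            assert math.isclose(ivw(variants).beta, est.beta, rel_tol=1e-12)

    def test_joint_sign_flip_invariance(self):
        rng = np.random.default_rng(9)
        variants = random_variants(rng, 6)
        flipped = [
            make_variant(
                snp_id=v.snp_id, beta_exp=-v.beta_exp, se_exp=v.se_exp,
                beta_out=-v.beta_out, se_out=v.se_out,
            )
            if i % 2
            else v
            for i, v in enumerate(variants)
        ]
        assert math.isclose(ivw(flipped).beta, ivw(variants).beta, rel_tol=1e-12)

    def test_random_effects_se_never_below_fixed(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            variants = random_variants(rng, 6)
            est = ivw(variants)
            assert est.se >= est.meta["se_fixed"] - 1e-15

    def test_requires_two_variants(self):
        with pytest.raises(EstimationError):
            ivw([make_variant()])


class TestWeightedMedian:
    def test_fixture_point_estimate_and_reproducible_se(self, fixture_variants):
        est = weighted_median(fixture_variants, n_boot=1000, seed=20220)
        assert math.isclose(est.beta, -0.6029894905065453, rel_tol=1e-10)
        again = weighted_median(fixture_variants, n_boot=1000, seed=20220)
        assert est.se == again.se  # same seed, same bootstrap

    def test_equal_weights_reduce_to_ordinary_interpolated_median(self):
        theta = np.array([-1.0, -0.4, 0.1, 0.5, 2.0])
        w = np.ones(5)
        # s = (2j-1)/10 -> crossing 0.5 exactly at the middle ratio
        assert weighted_median_point(theta, w) == pytest.approx(0.1)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            theta = np.sort(rng.normal(0, 1, size=6))
            w = rng.uniform(0.5, 3.0, size=6)
            assert weighted_median_point(theta, w) == pytest.approx(
                _grid_oracle(theta, w), abs=1e-8
            )

    def test_identical_ratios_give_that_ratio_with_small_positive_se(self):
        variants = [
            make_variant(snp_id=f"rs{i}", beta_exp=b, beta_out=0.3 * b, se_out=0.001)
            for i, b in enumerate((0.03, 0.05, 0.07, 0.04))
        ]
        est = weighted_median(variants, seed=1)
        assert math.isclose(est.beta, 0.3, rel_tol=1e-9)
        assert 0 < est.se < 0.05

    def test_minimum_inputs_enforced(self):
        variants = [make_variant(snp_id=f"rs{i}") for i in range(3)]
        with pytest.raises(EstimationError, match="n_boot"):
            weighted_median(variants, n_boot=50)
        with pytest.raises(EstimationError):
            weighted_median(variants[:2])


def _grid_oracle(theta, w, refinements=3):
    """Locate the s = 0.5 crossing of the cumulative-weight curve by
    dense grid search with successive refinement."""
    order = np.argsort(theta)
    t, p = np.asarray(theta, float)[order], np.asarray(w, float)[order]
    p = p / p.sum()
    s = np.cumsum(p) - p / 2
    lo, hi = t.min(), t.max()
    best = lo
    for _ in range(refinements):
        grid = np.linspace(lo, hi, 20001)
        vals = np.interp(grid, t, s)
        best = grid[np.argmin(np.abs(vals - 0.5))]
        span = (hi - lo) / 20000 * 4
        lo, hi = best - span, best + span
    return float(best)


class TestEgger:
    def test_fixture_intercept_and_slope(self, fixture_variants):
        fit = egger(fixture_variants)
        assert math.isclose(fit.intercept, 0.04424741729086073, rel_tol=1e-10)
        assert math.isclose(fit.intercept_se, 0.024681876383401902, rel_tol=1e-10)
        assert math.isclose(fit.intercept_pval, 0.21488664308782757, rel_tol=1e-10)
        assert fit.df == 2
        assert fit.slope.method == "Egger_slope"

    def test_matches_statsmodels_wls_oracle_both_scale_branches(self):
        rng = np.random.default_rng(23)
        for noise in (1e-4, 0.05):  # tiny noise -> scale<1; large -> scale>1
            bx = rng.uniform(0.02, 0.08, size=8)
            by = 0.01 - 0.6 * bx + rng.normal(0, noise, size=8)
            variants = [
                make_variant(snp_id=f"rs{i}", beta_exp=float(bx[i]),
                             beta_out=float(by[i]), se_out=0.013)
                for i in range(8)
            ]
            fit = egger(variants)
            w = np.full(8, 0.013**-2)
            X = sm.add_constant(bx)
            sm_fit = sm.WLS(by, X, weights=w).fit()
            assert fit.intercept == pytest.approx(sm_fit.params[0], rel=1e-9)
            assert fit.slope.beta == pytest.approx(sm_fit.params[1], rel=1e-9)
            if fit.residual_scale > 1:
                # statsmodels always scales by the residual variance
                assert fit.intercept_se == pytest.approx(sm_fit.bse[0], rel=1e-9)
                assert fit.slope.se == pytest.approx(sm_fit.bse[1], rel=1e-9)
            else:
                unscaled = np.sqrt(np.diag(sm_fit.normalized_cov_params))
                assert fit.intercept_se == pytest.approx(unscaled[0], rel=1e-9)
                assert fit.slope.se == pytest.approx(unscaled[1], rel=1e-9)

    def test_zero_pleiotropy_intercept_shrinks_toward_zero(self):
        from tsmr import harmonize, simulate
        from tsmr.simulate import SimConfig

        ds = simulate(SimConfig(n_snps=60, theta=-0.6, seed=42))
        fit = egger(harmonize(ds.exposure, ds.outcome))
        assert abs(fit.intercept) < 3.5 * fit.intercept_se

    def test_orientation_applied_internally(self, fixture_variants):
        pre_oriented = orient_to_positive_exposure(fixture_variants)
        fit_a = egger(fixture_variants)
        fit_b = egger(pre_oriented)
        assert fit_a.intercept == pytest.approx(fit_b.intercept, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        same = [make_variant(snp_id=f"rs{i}", beta_exp=0.05) for i in range(4)]
        with pytest.raises(EstimationError, match="variance"):
            egger(same)
        with pytest.raises(EstimationError):
            egger([make_variant(), make_variant(snp_id="rs2")])


class TestOddsRatioTransform:
    @pytest.mark.parametrize(
        "beta,se,expected",
        [
            (-0.644, 0.213, (0.525, 0.346, 0.798)),
            (-0.609, 0.244, (0.544, 0.337, 0.878)),
        ],
    )
    def test_published_rows_reproduced_at_printed_precision(self, beta, se, expected):
        # published CIs were computed from unrounded (beta, se), so the
        # transform of the 3-dp inputs may differ by one unit in the last
        # printed digit (e.g. 0.7973 vs printed 0.798)
        got = to_odds_ratio(beta, se)
        for g, e in zip(got, expected):
            assert abs(g - e) <= 1.05e-3

    def test_null_beta_symmetric_about_one(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.5)
        assert or_ == 1.0
        assert math.isclose(lo * hi, 1.0, rel_tol=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            to_odds_ratio(0.1, 0.0)
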