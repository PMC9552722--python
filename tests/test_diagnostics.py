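"""Cochran's Q, Egger intercept test, RSS pleiotropy test, sensitivity tables."""

import math

import numpy as np
import pytest

from conftest import make_variant, random_variants
from tsmr.diagnostics import (
    EggerInterceptTest,
    cochran_q,
    egger_intercept_test,
    leave_one_out,
    mr_presso,
    single_snp_table,
)
from tsmr.estimators import EstimationError, egger, ivw
from tsmr.harmonize import harmonize
from tsmr.simulate import SimConfig, scenario_battery, simulate


class TestCochranQ:
    def test_fixture_ivw_q(self, fixture_variants):
        het = cochran_q(fixture_variants, "ivw_fixed")
        assert het.q == pytest.approx(3.4742436637536454, rel=1e-10)
        assert het.q_df == 3
        assert 0.3 < het.q_pval < 0.4

    def test_fixture_egger_q(self, fixture_variants):
        het = cochran_q(fixture_variants, "egger")
        assert het.q == pytest.approx(0.2604387788927247, rel=1e-10)
        assert het.q_df == 2
        assert het.q_pval == pytest.approx(0.878, abs=0.01)

    def test_identical_ratios_give_zero_q(self):
        variants = [
            make_variant(snp_id=f"rs{i}", beta_exp=b, beta_out=0.7 * b)
            for i, b in enumerate((0.02, 0.05, 0.08))
        ]
        het = cochran_q(variants, "ivw_fixed")
        assert het.q == pytest.approx(0.0, abs=1e-18)
        assert het.q_pval == pytest.approx(1.0)

    def test_ivw_q_equals_zero_intercept_weighted_rss(self):
        """Algebraic identity: Q about the fixed-effect IVW estimate equals
        the weighted RSS of the zero-intercept regression of beta_out on
        beta_exp with weights 1/se_out^2."""
        rng = np.random.default_rng(31)
        for _ in range(10):
            variants = random_variants(rng, 6)
            bx = np.array([v.beta_exp for v in variants])
            by = np.array([v.beta_out for v in variants])
            w = np.array([v.se_out**-2 for v in variants])
            slope = np.sum(w * bx * by) / np.sum(w * bx * bx)
            rss = np.sum(w * (by - slope * bx) ** 2)
            assert cochran_q(variants, "ivw_fixed").q == pytest.approx(rss, abs=1e-10)

    def test_invariance_under_permutation_and_joint_sign_flip(self):
        rng = np.random.default_rng(37)
        variants = random_variants(rng, 8)
        q0 = cochran_q(variants, "ivw_fixed").q
        rng.shuffle(variants)
        flipped = [
            make_variant(
                snp_id=v.snp_id, beta_exp=-v.beta_exp, se_exp=v.se_exp,
                beta_out=-v.beta_out, se_out=v.se_out,
            )
            for v in variants
        ]
        assert cochran_q(flipped, "ivw_fixed").q == pytest.approx(q0, rel=1e-12)

    def test_insufficient_variants(self):
        with pytest.raises(EstimationError):
            cochran_q([make_variant()], "ivw_fixed")
        with pytest.raises(EstimationError):
            cochran_q([make_variant(), make_variant(snp_id="rs2")], "egger")


class TestEggerInterceptTest:
    def test_fixture_verdict_no_pleiotropy(self, fixture_variants):
        res = egger_intercept_test(egger(fixture_variants))
        assert isinstance(res, EggerInterceptTest)
        assert res.pval == pytest.approx(0.215, abs=0.005)
        assert res.verdict == "no significant pleiotropy"

    def test_zero_intercept_is_never_significant(self):
        from tsmr.estimators import EggerFit, MREstimate

        fit = EggerFit(
            slope=MREstimate.build("Egger_slope", 5, -0.5, 0.2, 0.01),
            intercept=0.0, intercept_se=0.01, intercept_pval=1.0,
            df=3, residual_scale=1.0,
        )
        assert egger_intercept_test(fit).pval == 1.0
        assert egger_intercept_test(fit).verdict == "no significant pleiotropy"

    def test_strong_directional_pleiotropy_flips_verdict_in_majority(self):
        cfg = SimConfig(
            n_snps=30, theta=-0.6, gamma_sd=0.02,
            pleiotropy_mode="directional", alpha_mean=0.05, alpha_sd=0.02,
        )
        hits = 0
        for i in range(40):
            ds = simulate(cfg, seed=9_000 + i)
            res = egger_intercept_test(egger(harmonize(ds.exposure, ds.outcome)))
            hits += res.verdict == "significant directional pleiotropy"
        assert hits > 20


class TestPressoStyleRssTest:
    def test_fixture_not_significant_no_outliers(self, fixture_variants):
        res = mr_presso(fixture_variants, n_sim=1000, seed=7)
        assert res.global_pval > 0.05
        assert res.outliers == []
        assert res.outlier_pvals is None
        assert res.corrected_estimate is None

    def test_perfect_fit_limit_pvalue_near_one(self):
        variants = [
            make_variant(snp_id=f"rs{i}", beta_exp=b, beta_out=-0.6 * b,
                         se_exp=1e-5, se_out=0.01)
            for i, b in enumerate((0.03, -0.03, 0.05, -0.05, 0.07, -0.07))
        ]
        res = mr_presso(variants, n_sim=500, seed=3)
        assert res.global_pval > 0.9

    def test_planted_outlier_flagged_and_corrected_toward_truth(self):
        cfg = scenario_battery()["single-outlier"]
        ds = simulate(cfg, seed=1)
        hd = harmonize(ds.exposure, ds.outcome)
        res = mr_presso(hd, n_sim=1000, seed=1)
        outlier_id = ds.exposure.snp_ids[cfg.outlier_index]
        assert res.global_pval < 0.05
        assert res.outliers == [outlier_id]
        uncorrected = ivw(hd).beta
        assert abs(res.corrected_estimate.beta - cfg.theta) < abs(uncorrected - cfg.theta)
        assert res.distortion_pval is not None

    def test_determinism_given_seed(self, fixture_variants):
        a = mr_presso(fixture_variants, n_sim=500, seed=11)
        b = mr_presso(fixture_variants, n_sim=500, seed=11)
        assert a.global_pval == b.global_pval and a.rss_obs == b.rss_obs

    def test_preconditions(self, fixture_variants):
        with pytest.raises(EstimationError):
            mr_presso(fixture_variants[:3])
        with pytest.raises(EstimationError):
            mr_presso(fixture_variants, n_sim=50)


class TestLeaveOneOut:
    def test_fixture_rows_all_negative(self, fixture_variants):
        table = leave_one_out(fixture_variants)
        assert len(table) == 4
        assert set(table["label"]) == {v.snp_id for v in fixture_variants}
        assert (table["beta"] < 0).all()

    def test_rows_equal_subset_ivw_oracle(self, fixture_variants):
        table = leave_one_out(fixture_variants).set_index("label")
        for left_out in fixture_variants:
            subset = [v for v in fixture_variants if v.snp_id != left_out.snp_id]
            expected = ivw(subset)
            assert table.loc[left_out.snp_id, "beta"] == pytest.approx(expected.beta, rel=1e-12)
            assert table.loc[left_out.snp_id, "se"] == pytest.approx(expected.se, rel=1e-12)

    def test_identical_ratios_rows_equal_full_estimate(self):
        variants = [
            make_variant(snp_id=f"rs{i}", beta_exp=b, beta_out=-0.4 * b)
            for i, b in enumerate((0.02, 0.04, 0.06, 0.08))
        ]
        table = leave_one_out(variants)
        assert np.allclose(table["beta"], ivw(variants).beta)

    def test_gross_outlier_removal_row_is_extreme(self):
        rng = np.random.default_rng(43)
        variants = [
            make_variant(snp_id=f"rs{i}", beta_exp=0.05, beta_out=-0.03 + rng.normal(0, 1e-4))
            for i in range(6)
        ]
        variants.append(make_variant(snp_id="rs_out", beta_exp=0.05, beta_out=0.2))
        table = leave_one_out(variants).set_index("label")
        most_negative = table["beta"].idxmin()
        assert most_negative == "rs_out"  # removing the outlier drops beta the most


class TestSingleSnpTable:
    def test_fixture_wald_rows_and_summaries(self, fixture_variants):
        table = single_snp_table(fixture_variants, seed=1)
        row = table.set_index("label").loc["rs17279437"]
        assert row["beta"] == pytest.approx(-1.1355932203389831, rel=1e-10)
        assert row["se"] == pytest.approx(0.3898305084745763, rel=1e-10)
        labels = list(table["label"])
        assert labels[-2:] == ["All - IVW", "All - Weighted median"]
        assert len(table) == 6

    def test_single_variant_suppresses_summary_rows(self):
        table = single_snp_table([make_variant()])
        assert len(table) == 1 and table.loc[0, "nsnp"] == 1

    def test_row_order_is_deterministic(self, fixture_variants):
        a = single_snp_table(fixture_variants, seed=1)
        b = single_snp_table(list(reversed(fixture_variants)), seed=1)
        assert list(a["label"]) == list(b["label"])
        assert np.allclose(a["beta"], b["beta"])
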