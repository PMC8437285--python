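"""Summary-statistic MR estimators against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mrcea.mr import RegressionSpec
from mrcea.summary_mr import (
    SummarySet,
    cochran_q,
    egger_estimate,
    ivw_estimate,
    median_and_mode_estimates,
    per_snp_summaries,
    weighted_median,
)
from mrcea.synth import GeneratorConfig, generate_cohort

from conftest import light_spec


def make_summary(bx, sx, by, sy):
    return SummarySet(
        pd.DataFrame(
            {
                "snp": [f"s{i}" for i in range(len(bx))],
                "beta_exp": bx,
                "se_exp": sx,
                "beta_out": by,
                "se_out": sy,
            }
        )
    )


@pytest.fixture()
def random_summary():
    rng = np.random.default_rng(8)
    L = 30
    bx = np.abs(rng.normal(0.1, 0.03, L))
    by = 0.5 * bx + rng.normal(0, 0.01, L)
    return make_summary(bx, np.full(L, 0.01), by, rng.uniform(0.005, 0.02, L))


class TestPerSnpSummaries:
    def test_matches_per_snp_ols_loop_oracle(self):
        cfg = GeneratorConfig(n_individuals=1500, seed=31, n_snps=8)
        c = generate_cohort(cfg)
        data = c.analysis_table()
        spec = light_spec("qalys_per_year")
        s = per_snp_summaries(data, c.dosages, c.snp_ids, spec)
        for j, snp in enumerate(c.snp_ids):
            X = sm.add_constant(
                np.column_stack([c.dosages[:, j], data["age"], data["sex"]]), prepend=False
            )
            fx = sm.OLS(data["bmi"].to_numpy(), X).fit()
            fy = sm.OLS(data["qalys_per_year"].to_numpy(), X).fit()
            row = s.table[s.table["snp"] == snp].iloc[0]
            assert row["beta_exp"] == pytest.approx(fx.params[0], rel=1e-8)
            assert row["se_exp"] == pytest.approx(fx.bse[0], rel=1e-8)
            assert row["beta_out"] == pytest.approx(fy.params[0], rel=1e-8)
            assert row["se_out"] == pytest.approx(fy.bse[0], rel=1e-8)

    def test_monomorphic_snp_excluded(self):
        cfg = GeneratorConfig(n_individuals=400, seed=33, n_snps=3)
        c = generate_cohort(cfg)
        c.dosages[:, 1] = 2  # force monomorphic
        data = c.analysis_table()
        with pytest.warns(UserWarning, match="monomorphic"):
            s = per_snp_summaries(data, c.dosages, c.snp_ids, light_spec("qalys_per_year"))
        assert len(s) == 2

    def test_null_outcome_z_scores_standard_normal(self):
        cfg = GeneratorConfig(
            n_individuals=20_000, seed=35,
            true_qaly_effect=0.0, confounder_effect_qaly=0.0,
        )
        c = generate_cohort(cfg)
        s = per_snp_summaries(c.analysis_table(), c.dosages, c.snp_ids, light_spec("qalys_per_year"))
        z = (s.table["beta_out"] / s.table["se_out"]).to_numpy()
        assert abs(z.mean()) < 3 / np.sqrt(len(z))
        assert abs(z.std(ddof=1) - 1.0) < 0.35


class TestIvw:
    def test_single_snp_is_wald_ratio(self):
        s = make_summary([0.2], [0.01], [0.05], [0.01])
        assert ivw_estimate(s).beta == pytest.approx(0.25)

    def test_shared_ratio_recovered_with_zero_q(self):
        bx = np.array([0.1, 0.2, 0.3])
        s = make_summary(bx, [0.01] * 3, 0.7 * bx, [0.01, 0.02, 0.03])
        est = ivw_estimate(s)
        assert est.beta == pytest.approx(0.7, abs=1e-12)
        q, df, p = cochran_q(s, est.beta)
        assert q == pytest.approx(0.0, abs=1e-18)
        assert df == 2

    def test_matches_weighted_least_squares_oracle(self, random_summary):
        t = random_summary.table
        w = 1 / t["se_out"] ** 2
        oracle = (w * t["beta_exp"] * t["beta_out"]).sum() / (w * t["beta_exp"] ** 2).sum()
        assert ivw_estimate(random_summary).beta == pytest.approx(oracle, rel=1e-12)

    def test_scale_equivariance(self, random_summary):
        base = ivw_estimate(random_summary).beta
        t = random_summary.table.copy()
        t[["beta_exp", "se_exp"]] *= 3.0
        assert ivw_estimate(SummarySet(t)).beta == pytest.approx(base / 3.0, rel=1e-12)


class TestEgger:
    def test_exact_line_recovery(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.02 + 0.6 * bx
        res = egger_estimate(make_summary(bx, [0.01] * 4, by, [0.01] * 4))
        assert res.slope.beta == pytest.approx(0.6, abs=1e-10)
        assert res.intercept == pytest.approx(0.02, abs=1e-10)

    def test_constant_pleiotropy_shifts_intercept_not_slope(self, random_summary):
        base = egger_estimate(random_summary)
        t = random_summary.table.copy()
        t["beta_out"] += 0.05
        shifted = egger_estimate(SummarySet(t))
        assert shifted.intercept == pytest.approx(base.intercept + 0.05, abs=1e-10)
        assert shifted.slope.beta == pytest.approx(base.slope.beta, abs=1e-10)

    def test_zero_intercept_regression_reproduces_ivw(self, random_summary):
        """Forcing the Egger intercept to zero is exactly the IVW slope."""
        t = random_summary.table
        w = (1 / t["se_out"] ** 2).to_numpy()
        X = t["beta_exp"].to_numpy()[:, None]
        y = t["beta_out"].to_numpy()
        through_origin = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * y))[0]
        assert through_origin == pytest.approx(ivw_estimate(random_summary).beta, rel=1e-12)

    def test_null_pleiotropy_intercept_not_significant(self):
        """No pleiotropy in the generator: the intercept z stays inside
        +-1.96 in at least 90% of replicates."""
        inside = 0
        reps = 40
        for rep in range(reps):
            cfg = GeneratorConfig(n_individuals=10_000, seed=900 + rep)
            c = generate_cohort(cfg)
            s = per_snp_summaries(c.analysis_table(), c.dosages, c.snp_ids, light_spec("qalys_per_year"))
            res = egger_estimate(s)
            inside += abs(res.intercept / res.intercept_se) < 1.96
        assert inside >= 0.9 * reps

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError, match="3"):
            egger_estimate(make_summary([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.01] * 2))


class TestMedianAndModes:
    def test_equal_weight_median(self):
        assert weighted_median(np.array([1.0, 2.0, 3.0]), np.ones(3)) == pytest.approx(2.0)

    def test_identical_ratios_all_estimators_agree(self):
        bx = np.array([0.1, 0.2, 0.4])
        s = make_summary(bx, [0.01] * 3, 0.5 * bx, [0.01] * 3)
        res = median_and_mode_estimates(s, n_boot=50, seed=1)
        for est in (res.weighted_median, res.simple_mode, res.weighted_mode):
            assert est.beta == pytest.approx(0.5, abs=0.02)
        assert ivw_estimate(s).beta == pytest.approx(0.5, abs=1e-12)

    def test_breakdown_resistance_of_weighted_median(self):
        """60% valid instruments with ratio r: median stays near r while
        IVW is dragged far toward the corrupted cluster."""
        rng = np.random.default_rng(12)
        L = 50
        bx = np.abs(rng.normal(0.15, 0.03, L))
        se = np.full(L, 0.004)
        by = 0.5 * bx + rng.normal(0, se)
        by[:20] += 0.08  # 40% corrupted by large pleiotropy
        s = make_summary(bx, [0.01] * L, by, se)
        res = median_and_mode_estimates(s, n_boot=200, seed=2)
        ivw_bias = abs(ivw_estimate(s).beta - 0.5)
        wm_bias = abs(res.weighted_median.beta - 0.5)
        assert wm_bias < 0.05  # stays inside the valid cluster
        assert wm_bias < ivw_bias / 3

    def test_nonpositive_bandwidth_rejected(self, random_summary):
        with pytest.raises(ValueError, match="bandwidth"):
            median_and_mode_estimates(random_summary, mode_bandwidth=0.0)


class TestCochranQ:
    def test_chi_square_mean_under_homogeneity(self):
        rng = np.random.default_rng(3)
        L, reps = 20, 400
        qs = []
        for _ in range(reps):
            bx = np.abs(rng.normal(0.2, 0.02, L))
            se = np.full(L, 0.01)
            by = 0.4 * bx + rng.normal(0, se)
            s = make_summary(bx, [0.005] * L, by, se)
            qs.append(cochran_q(s, ivw_estimate(s).beta)[0])
        # E[Q] = L - 1 under homogeneity; MC error ~ sqrt(2(L-1)/reps)
        assert np.mean(qs) == pytest.approx(L - 1, abs=5 * np.sqrt(2 * (L - 1) / reps))

    def test_heterogeneity_increases_rejection(self):
        rng = np.random.default_rng(4)
        L, reps = 20, 150
        rejections = 0
        for _ in range(reps):
            bx = np.abs(rng.normal(0.2, 0.02, L))
            se = np.full(L, 0.01)
            ratios = 0.4 + rng.normal(0, 0.15, L)  # genuinely heterogeneous
            by = ratios * bx + rng.normal(0, se)
            s = make_summary(bx, [0.005] * L, by, se)
            rejections += cochran_q(s, ivw_estimate(s).beta)[2] < 0.05
        assert rejections / reps > 0.5  # far above the 5% nominal rate
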