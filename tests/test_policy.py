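"""Policy engine: BMI changes, curve integration, discounting, NMB,
aggregation and Monte-Carlo uncertainty."""

import numpy as np
import pandas as pd
import pytest

from mrcea.nonlinear import DoseResponseCurve
from mrcea.policy import (
    EconomicConfig,
    Intervention,
    PopulationDistribution,
    aggregate_population,
    bariatric_surgery,
    bmi_cap_counterfactual,
    bmi_change,
    discount_stream,
    effect_integral,
    hfss_promotion_restriction,
    net_monetary_benefit,
    propagate_uncertainty,
    run_policy,
    synthetic_population_england_wales,
)


def flat_curve(beta, se=0.0, domain=(15.0, 60.0)):
    pieces = pd.DataFrame(
        {"lo": [domain[0]], "hi": [domain[1]], "mean_bmi": [27.0], "beta": [beta], "se": [se]}
    )
    return DoseResponseCurve(
        coefs=np.array([beta]), cov=np.array([[se**2]]), pieces=pieces, domain=domain
    )


def two_piece_curve(b1, b2):
    pieces = pd.DataFrame(
        {"lo": [25.0, 30.0], "hi": [30.0, 45.0], "mean_bmi": [27.0, 33.0], "beta": [b1, b2], "se": [0.0, 0.0]}
    )
    return DoseResponseCurve(
        coefs=np.array([0.0]), cov=np.zeros((1, 1)), pieces=pieces, domain=(25.0, 45.0)
    )


class TestBmiChange:
    def test_surgery_fraction(self):
        iv = bariatric_surgery()
        assert bmi_change(40.0, iv) == pytest.approx(-10.0)
        assert bmi_change(30.0, iv) == 0.0  # below the 35 eligibility threshold

    def test_calorie_reduction_arithmetic(self):
        iv = hfss_promotion_restriction(calories_per_day=12.0)
        # 12 kcal x 0.042 kg/kcal = 0.504 kg; at 1.70 m: -0.504/1.7^2
        assert bmi_change(30.0, iv, height=1.70) == pytest.approx(-0.1744, abs=2e-4)

    def test_calorie_without_height_rejected(self):
        with pytest.raises(ValueError, match="height"):
            bmi_change(30.0, hfss_promotion_restriction())

    def test_cap_ineligible_below_threshold(self):
        iv = bmi_cap_counterfactual(25.0)
        assert bmi_change(24.0, iv) == 0.0
        assert bmi_change(32.0, iv) == pytest.approx(-7.0)

    def test_distribution_shift_identity_is_null(self):
        pop = synthetic_population_england_wales(2017)
        iv = Intervention(kind="distribution_shift", target_distribution=pop)
        delta = bmi_change(np.array([22.0, 30.0, 41.0]), iv, source=pop)
        np.testing.assert_allclose(delta, 0.0, atol=1e-9)

    def test_distribution_shift_2017_to_1993_lowers_bmi(self):
        pop17 = synthetic_population_england_wales(2017)
        pop93 = synthetic_population_england_wales(1993)
        iv = Intervention(kind="distribution_shift", target_distribution=pop93)
        delta = bmi_change(np.array([27.0, 35.0]), iv, source=pop17)
        assert (delta < 0).all()


class TestEffectIntegral:
    def test_flat_curve_linear(self):
        curve = flat_curve(-0.006)
        assert effect_integral(32.0, -5.0, curve) == pytest.approx(0.03)

    def test_piecewise_step_integral_by_hand(self):
        # effects b1 on [25,30), b2 on [30,45); traversal 32 -> 27
        b1, b2 = -0.004, -0.007
        curve = two_piece_curve(b1, b2)
        expected = -(2 * b2 + 3 * b1)
        assert effect_integral(32.0, -5.0, curve, form="piecewise") == pytest.approx(expected)

    def test_cubic_matches_riemann_sum_oracle(self):
        coefs = np.array([0.01, -0.002, 3e-5, 1e-6])
        curve = DoseResponseCurve(
            coefs=coefs, cov=np.zeros((4, 4)),
            pieces=pd.DataFrame({"lo": [18.0], "hi": [45.0], "mean_bmi": [27.0], "beta": [0.0], "se": [0.0]}),
            domain=(18.0, 45.0),
        )
        grid = np.linspace(28.0, 41.0, 200_001)
        riemann = np.trapezoid(np.polynomial.polynomial.polyval(grid, coefs), grid)
        assert curve.integrate_effect(28.0, 41.0) == pytest.approx(riemann, abs=1e-6)

    def test_outside_domain_rejected_unless_extended(self):
        curve = flat_curve(-0.006, domain=(20.0, 40.0))
        with pytest.raises(ValueError, match="domain"):
            curve.integrate_effect(38.0, 45.0)
        # constant boundary extension
        assert curve.integrate_effect(38.0, 45.0, extend=True) == pytest.approx(-0.042)


class TestDiscounting:
    def test_zero_rate(self):
        assert discount_stream(np.ones(20), 0.0) == pytest.approx(20.0)

    def test_annuity_closed_form_end_of_year(self):
        pv = discount_stream(np.ones(20), 0.035, timing="end_of_year")
        assert pv == pytest.approx((1 - 1.035**-20) / 0.035, abs=1e-10)

    def test_first_year_undiscounted_convention(self):
        pv = discount_stream(np.ones(20), 0.035, timing="first_year_undiscounted")
        assert pv == pytest.approx(1.035 * (1 - 1.035**-20) / 0.035, abs=1e-10)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_stream([1.0], -0.01)


class TestNmb:
    def test_worked_surgery_example(self):
        # per-person over 20 years: +0.92 QALYs, costs fall by 5,096,
        # intervention costs 9,549, threshold 20,000/QALY
        nmb = net_monetary_benefit(0.92, -5096.0, 9549.0, 20_000.0)
        assert nmb == pytest.approx(0.92 * 20_000 + 5096 - 9549)

    def test_zero_effects_lose_the_intervention_cost(self):
        assert net_monetary_benefit(0.0, 0.0, 9549.0, 20_000.0) == -9549.0


class TestAggregation:
    def test_single_bin(self):
        out = aggregate_population(np.array([5.0]), np.array([2.0]))
        assert out["total"] == 10.0 and out["per_person"] == 5.0

    def test_uniform_value_scales_with_population(self):
        v = np.full(7, 3.3)
        c = np.array([10.0, 0, 5, 2, 8, 1, 4])
        out = aggregate_population(v, c)
        assert out["total"] == pytest.approx(3.3 * c.sum())

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=30)
        c = rng.integers(0, 100, 30).astype(float)
        eligible = rng.random(30) < 0.6
        out = aggregate_population(np.where(eligible, v, 0.0), c, eligible)
        total = sum(vv * cc for vv, cc, e in zip(v, c, eligible) if e)
        assert out["total"] == pytest.approx(total)
        assert out["per_person"] == pytest.approx(total / c[eligible].sum())

    def test_misaligned_bins_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            aggregate_population(np.ones(3), np.ones(4))


@pytest.fixture(scope="module")
def curves():
    return {"qaly": flat_curve(-0.0065, se=0.0008), "cost": flat_curve(42.23, se=4.7)}


@pytest.fixture(scope="module")
def population():
    return synthetic_population_england_wales(2017)


class TestRunPolicy:
    def test_surgery_nmb_identity_and_signs(self, curves, population):
        econ = EconomicConfig()
        res = run_policy(bariatric_surgery(), curves, population, econ)
        assert res.delta_qaly_per_person > 0  # lowering BMI gains QALYs
        assert res.delta_cost_per_person < 0  # and saves costs
        res.check_identity(econ.lambda_per_qaly, 9549.0)
        assert res.n_eligible == pytest.approx(population.count_above(35.0), rel=0.05)

    def test_deeper_reduction_never_decreases_qalys(self, curves, population):
        econ = EconomicConfig()
        shallow = run_policy(
            Intervention(kind="multiplicative_bmi_reduction", fraction=0.15,
                         eligibility_min_bmi=35.0, horizon_years=20, cost_per_person=9549.0),
            curves, population, econ,
        )
        deep = run_policy(bariatric_surgery(), curves, population, econ)
        assert deep.delta_qaly_per_person >= shallow.delta_qaly_per_person

    def test_flat_curve_run_matches_closed_form(self, population):
        """One-year cap scenario on a flat curve has an exact expectation."""
        cs = {"qaly": flat_curve(-0.0065), "cost": flat_curve(42.23)}
        econ = EconomicConfig()
        res = run_policy(bmi_cap_counterfactual(25.0), cs, population, econ)
        bins = population.bins
        mids = population.midpoints()
        above = mids >= 25.0
        excess = np.where(above, mids - 25.0, 0.0)
        counts = bins["count"].to_numpy()
        expect_qaly = (excess * 0.0065 * counts).sum() / counts[above].sum()
        assert res.delta_qaly_per_person == pytest.approx(expect_qaly, rel=1e-9)

    def test_zero_uncertainty_gives_degenerate_intervals(self, population):
        cs = {"qaly": flat_curve(-0.0065), "cost": flat_curve(42.23)}
        econ = EconomicConfig(mc_draws=120, seed=1)
        iv = Intervention(kind="cap_at_threshold", cap=25.0, eligibility_min_bmi=25.0)
        res = propagate_uncertainty(iv, cs, population, econ)
        lo, hi = res.intervals["nmb_per_person"]
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_mc_interval_matches_normal_theory_for_linear_pipeline(self, population):
        """Single normal parameter, linear map: percentile CI = +-1.96 SE."""
        se = 0.0008
        cs = {"qaly": flat_curve(-0.0065, se=se), "cost": flat_curve(0.0)}
        econ = EconomicConfig(mc_draws=4000, seed=7)
        iv = Intervention(kind="cap_at_threshold", cap=25.0, eligibility_min_bmi=25.0)
        res = propagate_uncertainty(iv, cs, population, econ)
        lo, hi = res.intervals["delta_qaly_per_person"]
        centre = res.delta_qaly_per_person
        scale = abs(centre) / 0.0065 * se  # linear in the drawn coefficient
        assert hi - lo == pytest.approx(2 * 1.96 * scale, rel=0.08)

    def test_mc_convergence_in_draw_count(self, curves, population):
        econ_a = EconomicConfig(mc_draws=1000, seed=3)
        econ_b = EconomicConfig(mc_draws=4000, seed=4)
        iv = bmi_cap_counterfactual(25.0)
        res_a = propagate_uncertainty(iv, curves, population, econ_a)
        res_b = propagate_uncertainty(iv, curves, population, econ_b)
        lo_a, hi_a = res_a.intervals["delta_cost_per_person"]
        lo_b, hi_b = res_b.intervals["delta_cost_per_person"]
        width = hi_a - lo_a
        assert abs(lo_a - lo_b) < 0.15 * width
        assert abs(hi_a - hi_b) < 0.15 * width

    def test_few_draws_warns(self, curves, population):
        econ = EconomicConfig(mc_draws=50, seed=2)
        with pytest.warns(UserWarning, match="draws"):
            propagate_uncertainty(bmi_cap_counterfactual(25.0), curves, population, econ)


class TestPopulationDistribution:
    def test_synthetic_totals(self):
        pop = synthetic_population_england_wales(2017)
        assert pop.total == pytest.approx(21_742_497, rel=1e-6)
        # the published shares: ~12.6% above 35, ~72% above 25
        assert pop.count_above(35.0) / pop.total == pytest.approx(0.126, abs=0.05)
        assert pop.count_above(25.0) / pop.total == pytest.approx(0.72, abs=0.08)

    def test_negative_counts_rejected(self):
        bins = pd.DataFrame(
            {"age_band": ["40-49"], "bmi_lo": [20.0], "bmi_hi": [25.0], "count": [-1.0]}
        )
        with pytest.raises(ValueError, match="negative"):
            PopulationDistribution(bins)

    def test_1993_distribution_is_leaner(self):
        p93 = synthetic_population_england_wales(1993)
        p17 = synthetic_population_england_wales(2017)
        assert p93.count_above(30.0) / p93.total < p17.count_above(30.0) / p17.total
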