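"""Financial-risk-protection metrics: CRRA premiums and the two counting estimators."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecea import (
    FrpConfig,
    GambleSpec,
    IncomeModel,
    catastrophic_cases,
    catastrophic_cases_averted,
    certainty_equivalent,
    insurance_value_population,
    poverty_cases,
    poverty_cases_averted,
    risk_premium,
)

# frozen oracle values: direct evaluation of the CRRA certainty equivalent
# [p (y-c)^(1-r) + (1-p) y^(1-r)]^(1/(1-r)) at y=1000, c=100, p=0.1, r=3
CE_REFERENCE = 988.4739856290504
PREMIUM_REFERENCE = 1.5260143709496106


class TestCertaintyEquivalent:
    def test_no_risk(self):
        assert certainty_equivalent(GambleSpec(1000, 0.0, 100)) == 1000

    def test_certain_loss(self):
        assert certainty_equivalent(GambleSpec(1000, 1.0, 100)) == 900

    def test_reference_value(self):
        g = GambleSpec(income=1000, event_probability=0.1, cost=100, risk_aversion=3)
        assert certainty_equivalent(g) == pytest.approx(CE_REFERENCE, rel=1e-12)

    def test_log_utility_limit(self):
        # r = 1 uses exp(p ln(y-c) + (1-p) ln y); check against direct evaluation
        g = GambleSpec(1000, 0.1, 100, risk_aversion=1.0)
        assert certainty_equivalent(g) == pytest.approx(
            np.exp(0.1 * np.log(900) + 0.9 * np.log(1000)), rel=1e-12
        )

    def test_income_below_cost_is_domain_error(self):
        with pytest.raises(ValueError, match="net income"):
            GambleSpec(income=90, event_probability=0.1, cost=100)


class TestRiskPremium:
    def test_costless_gamble_is_exactly_zero(self):
        assert risk_premium(GambleSpec(1000, 0.5, 0.0)) == 0.0

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_probability_is_exactly_zero(self, p):
        assert risk_premium(GambleSpec(1000, p, 100)) == 0.0

    def test_reference_value(self):
        g = GambleSpec(1000, 0.1, 100, risk_aversion=3)
        assert g.expected_income == 990
        assert risk_premium(g) == pytest.approx(PREMIUM_REFERENCE, rel=1e-10)

    def test_strictly_increasing_in_risk_aversion(self):
        prems = [risk_premium(GambleSpec(1000, 0.1, 100, r)) for r in (1, 2, 3, 4)]
        assert all(a < b for a, b in zip(prems, prems[1:]))

    def test_strictly_increasing_in_cost(self):
        prems = [risk_premium(GambleSpec(1000, 0.1, c, 3)) for c in (50, 100, 200, 400)]
        assert all(a < b for a, b in zip(prems, prems[1:]))

    def test_log_limit_is_bracketed_by_power_form(self):
        # continuity of CRRA at r -> 1: the log-form premium lies between the
        # power-form premiums at r = 1 -/+ 1e-4 (premium increases in r)
        lo = risk_premium(GambleSpec(1000, 0.1, 100, 1 - 1e-4))
        mid = risk_premium(GambleSpec(1000, 0.1, 100, 1.0))
        hi = risk_premium(GambleSpec(1000, 0.1, 100, 1 + 1e-4))
        assert lo < mid < hi

    @settings(max_examples=300, derandomize=True)
    @given(
        y=st.floats(10.0, 1e6),
        p=st.floats(1e-4, 1.0),
        cost_frac=st.floats(1e-4, 0.99),
        r=st.floats(0.1, 10.0),
    )
    def test_nonnegative_everywhere(self, y, p, cost_frac, r):
        g = GambleSpec(income=y, event_probability=p, cost=cost_frac * y, risk_aversion=r)
        prem = risk_premium(g)
        assert prem >= 0.0
        assert np.isfinite(prem)


class TestCatastrophicCounting:
    def test_direct_inequality(self):
        # c=100 against y=300 at a 10% threshold: 100 > 30, catastrophic
        assert catastrophic_cases([300.0], [1.0], 100.0, 0.1) == 1.0
        # boundary is strict: cost exactly at threshold is not a case
        assert catastrophic_cases([1000.0], [1.0], 100.0, 0.1) == 0.0

    def test_zero_cost_never_catastrophic(self):
        assert catastrophic_cases([300.0, 500.0], [1.0, 1.0], 0.0, 0.4) == 0.0

    def test_land_enumeration(self, land):
        # Th=0.4: even the poorest quintile's 100 <= 300*0.4, no cases;
        # Th=0.1: every paying case (8,000 in total) is catastrophic
        frp40 = FrpConfig(metric="catastrophic", threshold=0.4)
        frp10 = FrpConfig(metric="catastrophic", threshold=0.1)
        pol = land.primary_policy
        assert catastrophic_cases_averted(land.strata, pol, frp40).total == 0.0
        out = catastrophic_cases_averted(land.strata, pol, frp10)
        assert out.total == pytest.approx(8000.0)
        np.testing.assert_allclose(out.per_stratum, [3200, 2400, 1600, 800, 0])

    def test_zero_crowd_out_averts_nothing(self, land):
        pol = copy.deepcopy(land.primary_policy)
        pol.crowd_out = 0.0
        frp = FrpConfig(metric="catastrophic", threshold=0.1)
        assert catastrophic_cases_averted(land.strata, pol, frp).total == 0.0

    def test_gamma_income_matches_monte_carlo(self, land):
        # middle quintile income as Gamma(mean 640, Gini 0.3); oracle: 200,000
        # draws through the same strict threshold rule
        strata = copy.deepcopy(land.strata)
        model = IncomeModel.gamma_from_mean_gini(640.0, 0.3)
        strata[2].income_dist = model
        frp = FrpConfig(metric="catastrophic", threshold=0.2)
        out = catastrophic_cases_averted(strata, land.primary_policy, frp)

        draws = model.sample(200_000, np.random.default_rng(11))
        paying = strata[2].caseload * strata[2].care_seeking
        mc = paying * np.mean(100.0 > draws * 0.2)
        assert out.per_stratum[2] == pytest.approx(mc, rel=0.01)


class TestPovertyCounting:
    def test_land_printed_count_with_documented_affected_fraction(self, land):
        # only the middle quintile (y=640 > 600 > 640-100) crosses the line;
        # 0.8 x 4,000 cases = 3,200, the canonical worked-example count
        out = poverty_cases_averted(land.strata, land.primary_policy, land.frp)
        np.testing.assert_allclose(out.per_stratum, [0, 0, 3200, 0, 0])
        assert out.total == 3200.0

    def test_alternative_paying_fraction_reading(self, land):
        out = poverty_cases_averted(
            land.strata, land.primary_policy, land.frp, affected_fraction=0.40
        )
        assert out.total == pytest.approx(1600.0)

    def test_zero_cost_averts_nothing(self, land):
        strata = copy.deepcopy(land.strata)
        for s in strata:
            s.c_dm = 0.0
        out = poverty_cases_averted(strata, land.primary_policy, land.frp)
        assert out.total == 0.0

    def test_already_poor_never_counted(self):
        # income below the line before payment: not an impoverishment case
        assert poverty_cases([500.0], [1.0], 100.0, 600.0) == 0.0
        # strictness: landing exactly on the line is not a case
        assert poverty_cases([700.0], [1.0], 100.0, 600.0) == 0.0

    def test_gamma_income_matches_monte_carlo(self, land):
        strata = copy.deepcopy(land.strata)
        model = IncomeModel.gamma_from_mean_gini(640.0, 0.3)
        strata[2].income_dist = model
        out = poverty_cases_averted(strata, land.primary_policy, land.frp)

        draws = model.sample(200_000, np.random.default_rng(13))
        affected = strata[2].caseload * 0.8
        mc = affected * np.mean((draws > 600.0) & (draws - 100.0 < 600.0))
        assert out.per_stratum[2] == pytest.approx(mc, rel=0.01)


class TestInsuranceValue:
    def test_land_point_incomes_match_per_stratum_oracle(self, land):
        frp = FrpConfig(metric="insurance", poverty_line=600.0, risk_aversion=3.0)
        out = insurance_value_population(land.strata, land.primary_policy, frp)
        oracle = [
            s.population * risk_premium(
                GambleSpec(s.income, s.incidence * s.care_seeking, s.oop_cost, 3.0)
            ) if s.incidence > 0 else 0.0
            for s in land.strata
        ]
        np.testing.assert_allclose(out.per_stratum, oracle, rtol=1e-10)
        assert out.total == pytest.approx(449797.03, rel=1e-6)

    def test_zero_crowd_out_is_zero(self, land):
        pol = copy.deepcopy(land.primary_policy)
        pol.crowd_out = 0.0
        frp = FrpConfig(metric="insurance", risk_aversion=3.0)
        out = insurance_value_population(land.strata, pol, frp)
        np.testing.assert_allclose(out.per_stratum, np.zeros(5), atol=1e-12)

    def test_coverage_convention_is_partial(self, land):
        frp = FrpConfig(metric="insurance", risk_aversion=3.0)
        full = insurance_value_population(land.strata, land.primary_policy, frp)
        partial = insurance_value_population(
            land.strata, land.primary_policy, frp, convention="coverage"
        )
        assert 0 < partial.total < full.total

    def test_prevention_mode_adds_value(self, land):
        # with partial crowd-out a residual gamble remains; reducing its
        # probability by Eff x dCov must increase the premium reduction
        pol = copy.deepcopy(land.primary_policy)
        pol.crowd_out = 0.5
        frp = FrpConfig(metric="insurance", risk_aversion=3.0)
        base = insurance_value_population(land.strata, pol, frp)
        prev = insurance_value_population(land.strata, pol, frp, prevention=True)
        assert prev.total > base.total

    def test_cost_above_grid_income_propagates_stratum_context(self, land):
        strata = copy.deepcopy(land.strata)
        strata[0].c_dm = 400.0  # exceeds the poorest income of 300
        frp = FrpConfig(metric="insurance", risk_aversion=3.0)
        with pytest.raises(ValueError, match="Q1"):
            insurance_value_population(strata, land.primary_policy, frp)


class TestCrowdOutMonotonicity:
    @pytest.mark.parametrize("metric", ["catastrophic", "poverty", "insurance"])
    def test_benefit_weakly_increases_with_crowd_out(self, land, metric):
        frp = FrpConfig(
            metric=metric, threshold=0.1, poverty_line=600.0,
            risk_aversion=3.0, poverty_affected_fraction=0.8,
        )
        totals = []
        for co in (0.0, 0.3, 0.6, 1.0):
            pol = copy.deepcopy(land.primary_policy)
            pol.crowd_out = co
            if metric == "catastrophic":
                out = catastrophic_cases_averted(land.strata, pol, frp)
            elif metric == "poverty":
                out = poverty_cases_averted(land.strata, pol, frp)
            else:
                out = insurance_value_population(land.strata, pol, frp)
            totals.append(out.total)
        assert all(a <= b + 1e-12 for a, b in zip(totals, totals[1:]))
        assert totals[-1] > totals[0]
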