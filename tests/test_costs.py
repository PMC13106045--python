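"""Premix arithmetic, annualisation, and cost-model identities."""

import pytest
from scipy import optimize

from fortisim import (
    CompoundSpec,
    ConfigurationError,
    CostParameters,
    FortificationProgram,
    IntegrityError,
    StandardEntry,
    annualise,
    fortified_tonnage,
    government_cost,
    industry_cost,
    premix_cost_per_tonne,
    scenario_costs,
)

NO_MARKUPS = CostParameters(
    shipping_markup=0.0, taxes_duties_markup=0.0, domestic_logistics_markup=0.0
)
FE = {"iron": CompoundSpec("ferrous_fumarate", "iron", 0.5, 10.0)}


class TestPremix:
    def test_single_nutrient_hand_case(self):
        standard = {"iron": StandardEntry(30.0, "ferrous_fumarate")}
        # 30 g nutrient/tonne / 0.5 activity / 1000 = 0.06 kg compound x $10
        assert premix_cost_per_tonne(standard, FE, NO_MARKUPS) == pytest.approx(0.60)

    def test_empty_standard_costs_nothing(self):
        assert premix_cost_per_tonne({}, FE, CostParameters()) == 0.0

    def test_markups_compound_multiplicatively(self):
        params = CostParameters(
            shipping_markup=0.1, taxes_duties_markup=0.05, domestic_logistics_markup=0.08
        )
        compounds = {
            "iron": CompoundSpec("fe", "iron", 0.33, 6.0),
            "zinc": CompoundSpec("zn", "zinc", 0.8, 3.0),
            "folate": CompoundSpec("fa", "folate", 1.0, 70.0),
        }
        standard = {
            "iron": StandardEntry(30.0, "fe"),
            "zinc": StandardEntry(40.0, "zn"),
            "folate": StandardEntry(1.3, "fa"),
        }
        base = (30 / 0.33 / 1000 * 6.0) + (40 / 0.8 / 1000 * 3.0) + (1.3 / 1.0 / 1000 * 70.0)
        expected = base * 1.1 * 1.05 * 1.08
        assert premix_cost_per_tonne(standard, compounds, params) == pytest.approx(
            expected, rel=1e-12
        )

    def test_missing_compound_errors_with_nutrient_name(self):
        with pytest.raises(ConfigurationError, match="zinc"):
            premix_cost_per_tonne({"zinc": StandardEntry(40.0, "zn")}, FE, NO_MARKUPS)

    def test_price_factor_scales_linearly(self):
        standard = {"iron": StandardEntry(30.0, "fe")}
        one = premix_cost_per_tonne(standard, FE, CostParameters())
        two = premix_cost_per_tonne(standard, FE, CostParameters(), price_factor=2.0)
        assert two == pytest.approx(2 * one, rel=1e-12)


class TestTonnage:
    def test_product(self):
        assert fortified_tonnage(1000.0, 0.8, 0.5) == pytest.approx(400.0)
        assert fortified_tonnage(1000.0, 0.8, 0.0) == 0.0

    def test_compliance_rise_scales_tonnage(self):
        assert fortified_tonnage(1000.0, 0.7, 0.9) == pytest.approx(
            1.8 * fortified_tonnage(1000.0, 0.7, 0.5), rel=1e-12
        )


class TestAnnualise:
    def test_straight_line_at_zero_rate(self):
        assert annualise(1000.0, 10.0, 0.0) == pytest.approx(100.0)

    def test_single_period(self):
        assert annualise(1000.0, 1.0, 0.03) == pytest.approx(1030.0)

    def test_present_value_root_oracle(self):
        """The annuity solves: discounted payments sum to the capital."""
        capital, life, rate = 1000.0, 10.0, 0.03

        def pv_gap(annual):
            return sum(annual / (1 + rate) ** t for t in range(1, 11)) - capital

        oracle = optimize.brentq(pv_gap, 1.0, capital)
        assert annualise(capital, life, rate) == pytest.approx(oracle, rel=1e-10)


class TestIndustryGovernment:
    def test_zero_facilities_cost_nothing(self):
        assert industry_cost(0, CostParameters()) == 0.0

    def test_facilities_scale_linearly(self):
        params = CostParameters()
        assert industry_cost(7, params) == pytest.approx(7 * industry_cost(1, params))

    def test_labour_only_unit_costs(self):
        from fortisim.costs import IndustryUnitCosts

        params = CostParameters(
            industry=IndustryUnitCosts(0.0, 0.0, 0.0, 500.0, 0.0, 0.0)
        )
        assert industry_cost(1, params) == pytest.approx(500.0)

    def test_new_programme_adds_annualised_planning(self):
        params = CostParameters()
        extra = government_cost(True, params) - government_cost(False, params)
        assert extra == pytest.approx(
            annualise(params.government.planning_launch, params.equipment_life,
                      params.discount_rate)
        )

    def test_zero_planning_cost_makes_new_flag_moot(self):
        from fortisim.costs import GovernmentUnitCosts

        params = CostParameters(government=GovernmentUnitCosts(planning_launch=0.0))
        assert government_cost(True, params) == government_cost(False, params)


def _single_program():
    return FortificationProgram(
        country="A", vehicle="wheat_flour", status="mandatory", percap_intake=100.0,
        industrially_processed=0.8, compliance=0.5,
        standard={"iron": StandardEntry(30.0, "fe")},
    )


class TestScenarioCosts:
    SUPPLY = {("A", "wheat_flour"): 1000.0}
    FACIL = {("A", "wheat_flour"): 3.0}
    POPS = {"A": 10_000.0}

    def test_single_programme_share_is_hundred(self):
        breakdown, summary = scenario_costs(
            [_single_program()], FE, CostParameters(), self.SUPPLY, self.FACIL, self.POPS
        )
        assert summary["vehicle_shares_pct"]["wheat_flour"] == pytest.approx(100.0)
        assert (breakdown["premix"] + breakdown["industry"] + breakdown["government"]
                == breakdown["total"]).all()

    def test_doubled_prices_double_premix_only(self):
        _, base = scenario_costs(
            [_single_program()], FE, CostParameters(), self.SUPPLY, self.FACIL, self.POPS
        )
        _, doubled = scenario_costs(
            [_single_program()], FE, CostParameters(), self.SUPPLY, self.FACIL, self.POPS,
            price_factor=2.0,
        )
        assert doubled["premix"] == pytest.approx(2 * base["premix"], rel=1e-12)
        assert doubled["industry"] == base["industry"]
        assert doubled["government"] == base["government"]

    def test_inactive_programmes_cost_nothing(self):
        p = _single_program()
        p.compliance = 0.0
        _, summary = scenario_costs(
            [p], FE, CostParameters(), self.SUPPLY, self.FACIL, self.POPS
        )
        assert summary["total"] == 0.0

    def test_positive_cost_with_zero_population_errors(self):
        with pytest.raises(IntegrityError):
            scenario_costs(
                [_single_program()], FE, CostParameters(), self.SUPPLY, self.FACIL,
                {"A": 0.0},
            )

    def test_per_person_normalisation(self):
        breakdown, _ = scenario_costs(
            [_single_program()], FE, CostParameters(), self.SUPPLY, self.FACIL, self.POPS
        )
        row = breakdown.iloc[0]
        assert row["per_person"] == pytest.approx(row["total"] / 10_000.0)
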