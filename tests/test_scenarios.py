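"""Programme imputation, the contribution equation and scenario rules."""

import math

import numpy as np
import pytest

from fortisim import (
    ConfigurationError,
    ExpansionParams,
    FortificationProgram,
    GuidelineStandard,
    ScenarioSpec,
    StandardEntry,
    UnitsRegistry,
    apply_scenario,
    expansion_eligibility,
    fortificant_contribution,
    group_vehicle_intake,
    impute_missing,
)
from fortisim.scenarios import CalorieScaling

UNITS = UnitsRegistry()


def program(country="A", vehicle="wheat_flour", status="mandatory", percap=100.0,
            ip=1.0, fc=1.0, standard=None):
    return FortificationProgram(
        country=country, vehicle=vehicle, status=status, percap_intake=percap,
        industrially_processed=ip, compliance=fc,
        standard=standard if standard is not None else {},
    )


class TestImputation:
    def test_regional_median(self):
        programs = [
            program("A", ip=None),
            program("B", ip=0.6),
            program("C", ip=0.8),
        ]
        regions = {"A": "R0", "B": "R0", "C": "R0"}
        out = impute_missing(programs, regions)
        assert out[0].industrially_processed == pytest.approx(0.7)
        assert out[0].imputed_ip

    def test_no_missing_is_identity(self):
        programs = [program("A", ip=0.5, fc=0.4)]
        out = impute_missing(programs, {"A": "R0"})
        assert out[0].industrially_processed == 0.5
        assert out[0].compliance == 0.4
        assert not out[0].imputed_ip and not out[0].imputed_fc

    def test_global_median_fallback(self):
        programs = [
            program("A", fc=None),
            program("B", fc=0.2),
            program("C", fc=0.5),
            program("D", fc=0.9),
        ]
        regions = {"A": "R0", "B": "R1", "C": "R1", "D": "R1"}
        out = impute_missing(programs, regions)
        assert out[0].compliance == pytest.approx(0.5)

    def test_idempotence(self):
        programs = [program("A", ip=None, fc=None), program("B", ip=0.6, fc=0.3)]
        regions = {"A": "R0", "B": "R0"}
        once = impute_missing(programs, regions)
        twice = impute_missing(once, regions)
        assert [(p.industrially_processed, p.compliance) for p in once] == [
            (p.industrially_processed, p.compliance) for p in twice
        ]

    def test_vehicle_with_no_donors_errors(self):
        with pytest.raises(ConfigurationError):
            impute_missing([program("A", ip=None)], {"A": "R0"})

    def test_inactive_programme_compliance_is_structural_zero(self):
        out = impute_missing([program("A", status="none", fc=None, ip=0.4)], {"A": "R0"})
        assert out[0].compliance == 0.0
        assert not out[0].imputed_fc


class TestGroupIntake:
    def test_scaling_product(self):
        scaling = CalorieScaling("A", "M_20-24", 1.2)
        assert group_vehicle_intake(program(percap=100.0), scaling) == pytest.approx(120.0)

    def test_missing_scaling_falls_back_to_one(self):
        assert group_vehicle_intake(program(percap=100.0), None) == pytest.approx(100.0)

    def test_population_weighted_group_intakes_average_to_percap(self, default_world):
        """Within a country, pop-weighted F_csa equals the per-capita intake."""
        merged = default_world.calorie_scaling.merge(
            default_world.populations, on=["country", "age_sex_group"]
        )
        for country, sub in merged.groupby("country"):
            mean_ratio = np.average(sub["calorie_ratio"], weights=sub["persons"])
            assert mean_ratio == pytest.approx(1.0, abs=1e-6)


class TestContribution:
    def test_single_vehicle_hand_product(self):
        p = program(standard={"iron": StandardEntry(30.0, "ferrous_fumarate")},
                    percap=100.0, ip=1.0, fc=1.0)
        assert fortificant_contribution([p], "iron", UNITS) == pytest.approx(3.0)

    def test_microgram_nutrient_unit_conversion(self):
        p = program(vehicle="salt", percap=10.0, ip=1.0, fc=1.0,
                    standard={"iodine": StandardEntry(30.0, "potassium_iodate")})
        # 10 g/day x 30 mg/kg / 1000 = 0.3 mg/day = 300 ug/day
        assert fortificant_contribution([p], "iodine", UNITS) == pytest.approx(300.0)

    def test_zero_compliance_means_zero(self):
        p = program(fc=0.0, standard={"iron": StandardEntry(30.0, "x")})
        assert fortificant_contribution([p], "iron", UNITS) == 0.0

    def test_inactive_and_uncovered_contribute_zero(self):
        inactive = program(status="none", standard=None)
        uncovered = program(standard={"zinc": StandardEntry(40.0, "x")})
        assert fortificant_contribution([inactive, uncovered], "iron", UNITS) == 0.0

    def test_multi_vehicle_brute_force_sum(self):
        rng = np.random.default_rng(3)
        vehicles = ["wheat_flour", "maize_flour", "oil", "rice", "salt"]
        for _ in range(50):
            programs, terms = [], []
            for vehicle in vehicles:
                f, ip, fc, d = rng.uniform(1, 300), rng.uniform(), rng.uniform(), rng.uniform(0, 60)
                programs.append(program(vehicle=vehicle, percap=f, ip=ip, fc=fc,
                                        standard={"iron": StandardEntry(d, "x")}))
                terms.append(f * ip * fc * d / 1000.0)
            expected = math.fsum(terms)
            assert fortificant_contribution(programs, "iron", UNITS) == pytest.approx(
                expected, rel=1e-12
            )

    def test_linearity_in_compliance(self):
        base = program(fc=0.3, standard={"iron": StandardEntry(30.0, "x")})
        double = program(fc=0.6, standard={"iron": StandardEntry(30.0, "x")})
        assert fortificant_contribution([double], "iron", UNITS) == pytest.approx(
            2 * fortificant_contribution([base], "iron", UNITS)
        )

    def test_unknown_nutrient_unit_errors(self):
        p = program(standard={"unobtainium": StandardEntry(1.0, "x")})
        with pytest.raises(ConfigurationError):
            fortificant_contribution([p], "unobtainium", UNITS)


GUIDELINES = {
    ("wheat_flour", "iron"): GuidelineStandard("wheat_flour", "iron", 30.0, "guide_fe"),
    ("wheat_flour", "calcium"): GuidelineStandard("wheat_flour", "calcium", 2100.0, "guide_ca"),
}


class TestApplyScenario:
    def test_current_is_identity(self):
        programs = [program(fc=0.75, standard={"iron": StandardEntry(20.0, "x")})]
        out = apply_scenario(programs, ScenarioSpec.canonical("current"))
        assert out[0].compliance == 0.75
        assert out[0].standard["iron"].level == 20.0

    def test_no_fortification_zeroes_compliance(self):
        out = apply_scenario([program(fc=0.75)], ScenarioSpec.canonical("no_fortification"))
        assert out[0].compliance == 0.0

    def test_compliance_floor_raises_to_ninety(self):
        out = apply_scenario([program(fc=0.75)], ScenarioSpec.canonical("improved_compliance"))
        assert out[0].compliance == pytest.approx(0.9)

    def test_compliance_above_floor_is_kept(self):
        out = apply_scenario([program(fc=0.95)], ScenarioSpec.canonical("improved_compliance"))
        assert out[0].compliance == pytest.approx(0.95)

    def test_voluntary_programmes_also_get_the_floor(self):
        out = apply_scenario(
            [program(status="voluntary", fc=0.2)],
            ScenarioSpec.canonical("improved_compliance"),
        )
        assert out[0].compliance == pytest.approx(0.9)

    def test_align_max_never_lowers_and_adds_missing(self):
        programs = [program(standard={"iron": StandardEntry(50.0, "local_fe")})]
        out = apply_scenario(
            programs, ScenarioSpec.canonical("aligned_standards"), guidelines=GUIDELINES
        )
        assert out[0].standard["iron"].level == 50.0  # above guideline: kept
        assert out[0].standard["iron"].compound == "local_fe"
        assert out[0].standard["calcium"].level == 2100.0  # missing: added

    def test_align_replace_overrides_levels(self):
        programs = [program(standard={"iron": StandardEntry(50.0, "local_fe")})]
        out = apply_scenario(
            programs,
            ScenarioSpec.canonical("aligned_standards", align_rule="replace_with_guideline"),
            guidelines=GUIDELINES,
        )
        assert out[0].standard["iron"].level == 30.0
        assert out[0].standard["iron"].compound == "guide_fe"

    def test_alignment_without_guidelines_errors(self):
        with pytest.raises(ConfigurationError):
            apply_scenario([program()], ScenarioSpec.canonical("aligned_standards"))

    def test_expansion_creates_new_mandatory_programme(self):
        inactive = program(status="none", percap=200.0, ip=0.8, fc=None, standard=None)
        out = apply_scenario(
            [inactive],
            ScenarioSpec.canonical("aligned_improved_expanded"),
            guidelines=GUIDELINES,
            baseline_prevalence={("A", "iron"): 0.5, ("A", "calcium"): 0.05},
        )
        p = out[0]
        assert p.status == "mandatory" and p.is_new
        assert p.compliance == pytest.approx(0.9)
        assert set(p.standard) == {"iron"}  # only the high-inadequacy nutrient

    def test_expansion_skips_ineligible_countries(self):
        inactive = program(status="none", percap=20.0, ip=0.8, fc=None, standard=None)
        out = apply_scenario(
            [inactive],
            ScenarioSpec.canonical("aligned_improved_expanded"),
            guidelines=GUIDELINES,
            baseline_prevalence={("A", "iron"): 0.5},
        )
        assert out[0].status == "none"


class TestEligibility:
    PARAMS = ExpansionParams()

    def test_meets_all_thresholds(self):
        p = program(status="none", percap=200.0, ip=0.8, fc=None, standard=None)
        assert expansion_eligibility(p, 0.5, self.PARAMS)

    def test_zero_prevalence_fails(self):
        p = program(status="none", percap=200.0, ip=0.8, fc=None, standard=None)
        assert not expansion_eligibility(p, 0.0, self.PARAMS)

    def test_low_vehicle_intake_fails(self):
        p = program(status="none", percap=10.0, ip=0.8, fc=None, standard=None)
        assert not expansion_eligibility(p, 0.5, self.PARAMS)

    def test_salt_uses_lower_intake_threshold(self):
        p = program(vehicle="salt", status="none", percap=6.0, ip=0.8, fc=None, standard=None)
        assert expansion_eligibility(p, 0.5, self.PARAMS)
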