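"""Fortification programmes, the contribution equation, and the six scenarios.

A fortification programme is one country x food-vehicle record carrying the
indicators a fortification data exchange reports: legal status (mandatory,
voluntary or none), population-level daily per-capita vehicle intake F
(g/day), the fraction of the vehicle that is industrially processed IP, the
fraction of processed vehicle fortified in compliance with the standard FC,
and the standard itself — a map nutrient -> (level in mg of nutrient per kg
of vehicle, fortificant compound).

The daily intake contribution of nutrient m for age-sex group (s, a) in
country c is summed over the five vehicles:

    I_mcsa = sum_FV  F_csa * IP_FVc * FC_FVc * D_FVcm / 1000

with F_csa in g/day, D in mg/kg, hence the /1000 giving mg/day; the units
registry converts to ug/day for trace nutrients.  F_csa is the population
per-capita intake scaled by the group's relative caloric intake.

Six scenarios transform the programme table:

* ``no_fortification`` — every contribution forced to zero (baseline).
* ``current`` — programmes exactly as observed.
* ``improved_compliance`` — FC := max(FC, 0.9) for all active programmes,
  mandatory and voluntary alike.
* ``aligned_standards`` — standards aligned to international guideline
  levels and compounds (by default never lowering an existing level, and
  adding guideline nutrients missing from the standard).
* ``aligned_improved`` — alignment plus the 90% compliance floor.
* ``aligned_improved_expanded`` — additionally establishes new mandatory
  programmes, with guideline standards and 90% compliance, for
  country-vehicle pairs with no programme where the vehicle is widely eaten
  and industrially processed and some guideline nutrient has a high
  baseline (no-fortification) prevalence of inadequacy.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import ConfigurationError, InvalidParameterError
from .units import UnitsRegistry

WHEAT_FLOUR = "wheat_flour"
MAIZE_FLOUR = "maize_flour"
OIL = "oil"
RICE = "rice"
SALT = "salt"
VEHICLES = (WHEAT_FLOUR, MAIZE_FLOUR, OIL, RICE, SALT)

MANDATORY = "mandatory"
VOLUNTARY = "voluntary"
NONE = "none"
STATUSES = (MANDATORY, VOLUNTARY, NONE)

SCENARIO_NAMES = (
    "no_fortification",
    "current",
    "improved_compliance",
    "aligned_standards",
    "aligned_improved",
    "aligned_improved_expanded",
)

ALIGN_KEEP = "keep"
ALIGN_REPLACE = "replace_with_guideline"
ALIGN_MAX = "max_with_guideline"
ALIGN_RULES = (ALIGN_KEEP, ALIGN_REPLACE, ALIGN_MAX)


@dataclass(frozen=True)
class StandardEntry:
    """One nutrient line of a fortification standard."""

    level: float  # mg of nutrient per kg of vehicle
    compound: str

    def __post_init__(self) -> None:
        if self.level < 0:
            raise InvalidParameterError(f"standard level must be >= 0, got {self.level}")


@dataclass(frozen=True)
class GuidelineStandard:
    """International guideline level/compound for one vehicle x nutrient."""

    vehicle: str
    nutrient: str
    level: float
    compound: str


@dataclass
class FortificationProgram:
    """Fortification-programme indicators for one country x vehicle."""

    country: str
    vehicle: str
    status: str
    percap_intake: float  # g/person/day, population level
    industrially_processed: float | None = None  # fraction, None = missing
    compliance: float | None = None  # fraction, None = missing
    standard: dict[str, StandardEntry] = field(default_factory=dict)
    imputed_ip: bool = False
    imputed_fc: bool = False
    is_new: bool = False  # set by scenario expansion; drives planning costs

    def __post_init__(self) -> None:
        if self.vehicle not in VEHICLES:
            raise InvalidParameterError(f"unknown vehicle {self.vehicle!r}")
        if self.status not in STATUSES:
            raise InvalidParameterError(f"unknown status {self.status!r}")
        if self.percap_intake < 0:
            raise InvalidParameterError("per-capita intake must be >= 0")
        for name, value in (
            ("industrially_processed", self.industrially_processed),
            ("compliance", self.compliance),
        ):
            if value is not None and not (0.0 <= value <= 1.0):
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {value}")
        if self.status == NONE and self.standard:
            raise InvalidParameterError(
                f"{self.country}/{self.vehicle}: inactive programme carries a standard"
            )

    @property
    def active(self) -> bool:
        return self.status != NONE

    def copy(self) -> "FortificationProgram":
        return replace(self, standard=dict(self.standard))


@dataclass(frozen=True)
class CalorieScaling:
    """Group caloric intake relative to the country population mean."""

    country: str
    age_sex_group: str
    calorie_ratio: float

    def __post_init__(self) -> None:
        if not (self.calorie_ratio > 0):
            raise InvalidParameterError("calorie ratio must be positive")


@dataclass(frozen=True)
class ExpansionParams:
    """Eligibility thresholds for establishing new programmes."""

    min_baseline_prevalence: float = 0.2
    min_vehicle_intake: float = 50.0  # g/day default
    min_processed_fraction: float = 0.5
    vehicle_intake_overrides: Mapping[str, float] = field(
        default_factory=lambda: {SALT: 5.0, OIL: 10.0}
    )

    def intake_threshold(self, vehicle: str) -> float:
        return float(self.vehicle_intake_overrides.get(vehicle, self.min_vehicle_intake))


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative rules producing one of the six scenarios."""

    name: str
    compliance_floor: float | None = None  # 0.9 where applicable
    align_rule: str = ALIGN_KEEP
    expand: bool = False
    expansion_params: ExpansionParams = field(default_factory=ExpansionParams)
    zero_out: bool = False  # no_fortification

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise InvalidParameterError(f"unknown scenario name {self.name!r}")
        if self.align_rule not in ALIGN_RULES:
            raise InvalidParameterError(f"unknown align rule {self.align_rule!r}")

    @classmethod
    def canonical(
        cls,
        name: str,
        align_rule: str = ALIGN_MAX,
        expansion_params: ExpansionParams | None = None,
    ) -> "ScenarioSpec":
        """The six canonical scenario specifications by name."""
        params = expansion_params or ExpansionParams()
        table = {
            "no_fortification": cls(name, zero_out=True),
            "current": cls(name),
            "improved_compliance": cls(name, compliance_floor=0.9),
            "aligned_standards": cls(name, align_rule=align_rule),
            "aligned_improved": cls(name, compliance_floor=0.9, align_rule=align_rule),
            "aligned_improved_expanded": cls(
                name,
                compliance_floor=0.9,
                align_rule=align_rule,
                expand=True,
                expansion_params=params,
            ),
        }
        try:
            return table[name]
        except KeyError:
            raise InvalidParameterError(f"unknown scenario name {name!r}")


# ---------------------------------------------------------------------------
# Imputation of missing programme indicators
# ---------------------------------------------------------------------------


def impute_missing(
    programs: Iterable[FortificationProgram],
    regions: Mapping[str, str],
) -> list[FortificationProgram]:
    """Fill missing IP and FC values by a median hierarchy.

    Missing values take the median of observed values for the same vehicle
    within the country's region, falling back to the global median for the
    vehicle.  Imputed values are flagged (``imputed_ip`` / ``imputed_fc``)
    so sensitivity analyses can substitute alternatives.  A vehicle with no
    observed value anywhere, while a programme needs one, is a
    configuration error.
    """
    programs = [p.copy() for p in programs]

    def observed(attr: str, vehicle: str, region: str | None):
        values = [
            getattr(p, attr)
            for p in programs
            if p.vehicle == vehicle
            and getattr(p, attr) is not None
            and (region is None or regions.get(p.country) == region)
        ]
        return values

    for program in programs:
        region = regions.get(program.country)
        for attr, flag in (
            ("industrially_processed", "imputed_ip"),
            ("compliance", "imputed_fc"),
        ):
            if getattr(program, attr) is not None:
                continue
            if attr == "compliance" and not program.active:
                # No programme: compliance is structurally zero, not missing.
                program.compliance = 0.0
                continue
            pool = observed(attr, program.vehicle, region)
            if not pool:
                pool = observed(attr, program.vehicle, None)
            if not pool:
                raise ConfigurationError(
                    f"no observed {attr} anywhere for vehicle {program.vehicle!r}"
                )
            setattr(program, attr, float(statistics.median(pool)))
            setattr(program, flag, True)
    return programs


# ---------------------------------------------------------------------------
# The contribution equation
# ---------------------------------------------------------------------------


def group_vehicle_intake(
    program: FortificationProgram, scaling: CalorieScaling | None
) -> float:
    """Age-sex specific daily vehicle intake F_csa in g/day.

    Scales the population-level per-capita intake by the group's relative
    caloric intake; a missing scaling row falls back to ratio 1.
    """
    ratio = 1.0 if scaling is None else scaling.calorie_ratio
    return program.percap_intake * ratio


def fortificant_contribution(
    programs: Iterable[FortificationProgram],
    nutrient: str,
    units: UnitsRegistry,
    calorie_ratio: float = 1.0,
) -> float:
    """Daily intake contribution I_mcsa of ``nutrient`` in intake units/day.

    Sums F_csa x IP x FC x D / 1000 over the country's vehicles; inactive
    programmes and standards not covering the nutrient contribute zero.
    The mg/day sum is converted to the nutrient's registry unit.
    """
    factor = units.mg_to_intake_unit(nutrient)
    total_mg = 0.0
    for program in programs:
        if not program.active:
            continue
        entry = program.standard.get(nutrient)
        if entry is None:
            continue
        ip = program.industrially_processed
        fc = program.compliance
        if ip is None or fc is None:
            raise ConfigurationError(
                f"{program.country}/{program.vehicle}: IP/FC missing; "
                "run impute_missing before computing contributions"
            )
        f_csa = program.percap_intake * calorie_ratio
        total_mg += f_csa * ip * fc * entry.level / 1000.0
    return total_mg * factor


# ---------------------------------------------------------------------------
# Scenario construction
# ---------------------------------------------------------------------------


def _align_standard(
    program: FortificationProgram,
    guidelines: Mapping[tuple[str, str], GuidelineStandard],
    rule: str,
) -> None:
    if rule == ALIGN_KEEP:
        return
    for (vehicle, nutrient), guide in guidelines.items():
        if vehicle != program.vehicle:
            continue
        existing = program.standard.get(nutrient)
        if rule == ALIGN_REPLACE or existing is None:
            program.standard[nutrient] = StandardEntry(guide.level, guide.compound)
        elif rule == ALIGN_MAX and existing.level < guide.level:
            program.standard[nutrient] = StandardEntry(guide.level, guide.compound)


def expansion_eligibility(
    program: FortificationProgram,
    baseline_prevalence: float,
    params: ExpansionParams,
) -> bool:
    """New-programme eligibility for one country x vehicle x nutrient.

    Requires a high baseline (no-fortification) prevalence of inadequacy,
    a vehicle eaten above the per-vehicle intake threshold, and a
    sufficiently industrialised supply.
    """
    if program.industrially_processed is None:
        return False
    return (
        baseline_prevalence >= params.min_baseline_prevalence
        and program.percap_intake >= params.intake_threshold(program.vehicle)
        and program.industrially_processed >= params.min_processed_fraction
    )


def apply_scenario(
    programs: Iterable[FortificationProgram],
    spec: ScenarioSpec,
    guidelines: Mapping[tuple[str, str], GuidelineStandard] | None = None,
    baseline_prevalence: Mapping[tuple[str, str], float] | None = None,
) -> list[FortificationProgram]:
    """Transform an (imputed) programme table into a scenario's table.

    ``guidelines`` maps (vehicle, nutrient) to guideline standards;
    ``baseline_prevalence`` maps (country, nutrient) to country-level
    no-fortification inadequacy prevalence, required when ``spec.expand``.
    """
    programs = [p.copy() for p in programs]
    if spec.zero_out:
        for program in programs:
            program.compliance = 0.0 if program.compliance is not None else None
        return programs

    needs_guidelines = spec.align_rule != ALIGN_KEEP or spec.expand
    if needs_guidelines and not guidelines:
        raise ConfigurationError(f"scenario {spec.name!r} requires a guideline table")
    if spec.expand and baseline_prevalence is None:
        raise ConfigurationError(
            f"scenario {spec.name!r} requires baseline no-fortification prevalences"
        )

    for program in programs:
        if not program.active:
            continue
        if spec.align_rule != ALIGN_KEEP:
            _align_standard(program, guidelines, spec.align_rule)
        if spec.compliance_floor is not None and program.compliance is not None:
            program.compliance = max(program.compliance, spec.compliance_floor)

    if spec.expand:
        floor = spec.compliance_floor if spec.compliance_floor is not None else 0.9
        for program in programs:
            if program.active:
                continue
            targets = {
                nutrient: guide
                for (vehicle, nutrient), guide in guidelines.items()
                if vehicle == program.vehicle
                and expansion_eligibility(
                    program,
                    baseline_prevalence.get((program.country, nutrient), 0.0),
                    spec.expansion_params,
                )
            }
            if not targets:
                continue
            program.status = MANDATORY
            program.is_new = True
            program.compliance = floor
            program.standard = {
                nutrient: StandardEntry(guide.level, guide.compound)
                for nutrient, guide in targets.items()
            }
    return programs
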