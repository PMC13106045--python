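"""Bottom-up annual costs of fortification: premix, industry, government.

The annual cost of a country x vehicle programme is the sum of three parts:

* **premix** — cost of the micronutrient compounds per tonne of vehicle
  (level in mg/kg is g/tonne; dividing by the compound's activity — the
  elemental-nutrient fraction of the compound — and by 1000 gives kg of
  compound per tonne, times the price per kg), marked up multiplicatively
  for international shipping, taxes/duties and domestic logistics, times
  the annual fortified tonnage (vehicle supply x IP x FC);
* **industry** — per-facility annualised fortification and QA-QC equipment
  plus recurrent QA-QC supplies, labour, training and management/overhead,
  times the number of processing facilities;
* **government** — per-programme annualised monitoring equipment plus
  recurrent monitoring supplies and labour, social marketing, training and
  management/overhead, with annualised planning-and-launch costs added for
  programmes newly established by a scenario.

Capital items are annualised as a standard annuity:
``capital * r / (1 - (1+r)^-life)``, straight-line ``capital / life`` at
r = 0.  All monetary amounts are 2021 USD per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError, InvalidParameterError
from .scenarios import VEHICLES, FortificationProgram, StandardEntry


@dataclass(frozen=True)
class CompoundSpec:
    """Price and activity (elemental fraction) of one fortificant compound."""

    compound: str
    nutrient: str
    activity: float  # fraction of nutrient in the compound, (0, 1]
    price: float  # USD (2021) per kg of compound

    def __post_init__(self) -> None:
        if not (0.0 < self.activity <= 1.0):
            raise InvalidParameterError(
                f"{self.compound}: activity must lie in (0, 1], got {self.activity}"
            )
        if self.price < 0:
            raise InvalidParameterError(f"{self.compound}: price must be >= 0")


@dataclass(frozen=True)
class IndustryUnitCosts:
    """Per-facility unit costs (USD capital, USD/yr recurrent)."""

    fortification_equipment: float = 25_000.0
    qaqc_equipment: float = 10_000.0
    qaqc_supplies: float = 2_000.0
    labour: float = 5_000.0
    training: float = 1_000.0
    management_overhead: float = 2_000.0


@dataclass(frozen=True)
class GovernmentUnitCosts:
    """Per-programme unit costs (USD capital, USD/yr recurrent)."""

    monitoring_equipment: float = 50_000.0
    monitoring_supplies: float = 10_000.0
    monitoring_labour: float = 30_000.0
    social_marketing: float = 20_000.0
    training: float = 10_000.0
    management_overhead: float = 15_000.0
    planning_launch: float = 100_000.0  # one-time, new programmes only


@dataclass(frozen=True)
class CostParameters:
    """Markups, annualisation parameters and unit-cost blocks."""

    shipping_markup: float = 0.10
    taxes_duties_markup: float = 0.05
    domestic_logistics_markup: float = 0.08
    discount_rate: float = 0.03  # per year
    equipment_life: float = 10.0  # years; also amortises planning/launch
    overage: float = 0.0  # extra fraction added above the label level
    industry: IndustryUnitCosts = field(default_factory=IndustryUnitCosts)
    government: GovernmentUnitCosts = field(default_factory=GovernmentUnitCosts)

    def __post_init__(self) -> None:
        if self.equipment_life <= 0:
            raise InvalidParameterError("equipment life must be positive")
        if self.discount_rate < 0:
            raise InvalidParameterError("discount rate must be >= 0")


def annualise(capital: float, life: float, rate: float) -> float:
    """Equivalent constant annual cost of a capital outlay (annuity)."""
    if life <= 0:
        raise InvalidParameterError("life must be positive")
    if rate < 0:
        raise InvalidParameterError("rate must be >= 0")
    if rate == 0:
        return capital / life
    return capital * rate / (1.0 - (1.0 + rate) ** (-life))


def premix_cost_per_tonne(
    standard: Mapping[str, StandardEntry],
    compounds: Mapping[str, CompoundSpec],
    params: CostParameters,
    price_factor: float = 1.0,
) -> float:
    """Delivered premix cost in USD per tonne of fortified vehicle.

    ``compounds`` maps nutrient -> CompoundSpec.  ``price_factor`` scales
    every compound price (the +/-50% price sensitivity lever).
    """
    base = 0.0
    for nutrient, entry in standard.items():
        spec = compounds.get(nutrient)
        if spec is None:
            raise ConfigurationError(f"no compound specification for nutrient {nutrient!r}")
        level = entry.level * (1.0 + params.overage)  # mg/kg == g/tonne
        kg_compound_per_tonne = level / spec.activity / 1000.0
        base += kg_compound_per_tonne * spec.price * price_factor
    return (
        base
        * (1.0 + params.shipping_markup)
        * (1.0 + params.taxes_duties_markup)
        * (1.0 + params.domestic_logistics_markup)
    )


def fortified_tonnage(vehicle_supply: float, ip: float, fc: float) -> float:
    """Annual tonnes of vehicle actually fortified: supply x IP x FC."""
    for name, frac in (("ip", ip), ("fc", fc)):
        if not (0.0 <= frac <= 1.0):
            raise InvalidParameterError(f"{name} must lie in [0, 1], got {frac}")
    return vehicle_supply * ip * fc


def industry_cost(facilities: float, params: CostParameters) -> float:
    """Annual industry-side cost for one country x vehicle programme."""
    if facilities < 0:
        raise InvalidParameterError("facility count must be >= 0")
    u = params.industry
    per_facility = (
        annualise(u.fortification_equipment, params.equipment_life, params.discount_rate)
        + annualise(u.qaqc_equipment, params.equipment_life, params.discount_rate)
        + u.qaqc_supplies
        + u.labour
        + u.training
        + u.management_overhead
    )
    return facilities * per_facility


def government_cost(is_new: bool, params: CostParameters) -> float:
    """Annual government-side cost for one active programme."""
    u = params.government
    total = (
        annualise(u.monitoring_equipment, params.equipment_life, params.discount_rate)
        + u.monitoring_supplies
        + u.monitoring_labour
        + u.social_marketing
        + u.training
        + u.management_overhead
    )
    if is_new:
        total += annualise(u.planning_launch, params.equipment_life, params.discount_rate)
    return total


def scenario_costs(
    programs: Iterable[FortificationProgram],
    compounds: Mapping[str, CompoundSpec],
    params: CostParameters,
    supply: Mapping[tuple[str, str], float],
    facilities: Mapping[tuple[str, str], float],
    populations: Mapping[str, float],
    price_factor: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Cost breakdown per country x vehicle plus a global summary.

    ``supply`` and ``facilities`` map (country, vehicle) to annual vehicle
    supply in tonnes and processing-facility counts; ``populations`` maps
    country to total persons.  A programme whose effective fortified
    tonnage is zero (no fortification scenario, or zero compliance) incurs
    no cost.  Returns the tidy breakdown frame and a summary dict with the
    global total, per-vehicle shares (percent of global total) and the
    mean/SD of per-person cost across the five vehicles.
    """
    rows = []
    for program in programs:
        if not program.active or not program.standard:
            continue
        ip = program.industrially_processed or 0.0
        fc = program.compliance or 0.0
        tonnes = fortified_tonnage(
            supply.get((program.country, program.vehicle), 0.0), ip, fc
        )
        if tonnes <= 0:
            continue
        premix = premix_cost_per_tonne(
            program.standard, compounds, params, price_factor=price_factor
        ) * tonnes
        industry = industry_cost(
            facilities.get((program.country, program.vehicle), 0.0), params
        )
        government = government_cost(program.is_new, params)
        total = premix + industry + government
        pop = populations.get(program.country, 0.0)
        if pop <= 0 and total > 0:
            raise IntegrityError(
                f"{program.country}: positive cost with zero population"
            )
        rows.append(
            {
                "country": program.country,
                "vehicle": program.vehicle,
                "premix": premix,
                "industry": industry,
                "government": government,
                "total": total,
                "per_person": total / pop,
            }
        )
    breakdown = pd.DataFrame(
        rows,
        columns=["country", "vehicle", "premix", "industry", "government", "total", "per_person"],
    )
    summary = summarise_costs(breakdown, populations)
    return breakdown, summary


def summarise_costs(breakdown: pd.DataFrame, populations: Mapping[str, float]) -> dict:
    """Global totals, vehicle shares and per-person statistics.

    The per-person mean/SD is taken across the five vehicle-level global
    per-person costs (global vehicle cost over global population); SD is
    the sample standard deviation.
    """
    global_pop = float(sum(populations.values()))
    total = float(breakdown["total"].sum()) if not breakdown.empty else 0.0
    by_vehicle = {
        v: float(breakdown.loc[breakdown["vehicle"] == v, "total"].sum())
        if not breakdown.empty
        else 0.0
        for v in VEHICLES
    }
    shares = {
        v: (100.0 * c / total if total > 0 else 0.0) for v, c in by_vehicle.items()
    }
    per_person_by_vehicle = {
        v: (c / global_pop if global_pop > 0 else 0.0) for v, c in by_vehicle.items()
    }
    values = np.array(list(per_person_by_vehicle.values()), dtype=float)
    return {
        "total": total,
        "premix": float(breakdown["premix"].sum()) if not breakdown.empty else 0.0,
        "industry": float(breakdown["industry"].sum()) if not breakdown.empty else 0.0,
        "government": float(breakdown["government"].sum()) if not breakdown.empty else 0.0,
        "by_vehicle": by_vehicle,
        "vehicle_shares_pct": shares,
        "per_person_by_vehicle": per_person_by_vehicle,
        "per_person_mean": float(values.mean()) if values.size else 0.0,
        "per_person_sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
    }
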