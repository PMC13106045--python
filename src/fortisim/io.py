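"""Table I/O and the in-memory ``World`` bundle of model inputs.

A "world" is the full set of tables the pipeline consumes: intake
distributions, fortification programmes and standards, guideline standards,
requirements, upper levels, populations, calorie scalings, compound specs,
facility/supply counts, a country->region map, and cost parameters.  On disk
a world is a directory of headered UTF-8 CSV files plus one YAML file of
cost parameters; this module reads and writes that layout and converts
between the tidy frames and the richer domain objects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .costs import CompoundSpec, CostParameters, GovernmentUnitCosts, IndustryUnitCosts
from .distributions import IntakeDistribution
from .adequacy import DEFAULT_REQ_CV, RequirementDistribution, UpperLevel
from .errors import ConfigurationError
from .scenarios import FortificationProgram, GuidelineStandard, StandardEntry
from .units import UnitsRegistry

WORLD_FILES = {
    "intakes": "intake_distributions.csv",
    "programs": "programs.csv",
    "standards": "standards.csv",
    "guidelines": "guideline_standards.csv",
    "requirements": "requirements.csv",
    "uls": "upper_levels.csv",
    "populations": "populations.csv",
    "calorie_scaling": "calorie_scaling.csv",
    "compounds": "compounds.csv",
    "facilities": "facilities.csv",
    "regions": "regions.csv",
}
COST_PARAMS_FILE = "cost_parameters.yaml"


@dataclass
class World:
    """All input tables for one model run."""

    intakes: pd.DataFrame
    programs: pd.DataFrame
    standards: pd.DataFrame
    guidelines: pd.DataFrame
    requirements: pd.DataFrame
    uls: pd.DataFrame
    populations: pd.DataFrame
    calorie_scaling: pd.DataFrame
    compounds: pd.DataFrame
    facilities: pd.DataFrame
    regions: pd.DataFrame
    cost_params: CostParameters
    units: UnitsRegistry

    # -- conversions to domain objects -------------------------------------

    def program_objects(self) -> list[FortificationProgram]:
        """Programme rows joined with their current standards."""
        standards: dict[tuple[str, str], dict[str, StandardEntry]] = {}
        for row in self.standards.itertuples(index=False):
            key = (row.country, row.vehicle)
            standards.setdefault(key, {})[row.nutrient] = StandardEntry(
                float(row.level_mg_per_kg), row.compound
            )
        programs = []
        for row in self.programs.itertuples(index=False):
            std = standards.get((row.country, row.vehicle), {})
            programs.append(
                FortificationProgram(
                    country=row.country,
                    vehicle=row.vehicle,
                    status=row.status,
                    percap_intake=float(row.percap_intake_g_day),
                    industrially_processed=_opt(row.industrially_processed),
                    compliance=_opt(row.compliance),
                    standard=std if row.status != "none" else {},
                )
            )
        return programs

    def guideline_map(self) -> dict[tuple[str, str], GuidelineStandard]:
        return {
            (row.vehicle, row.nutrient): GuidelineStandard(
                row.vehicle, row.nutrient, float(row.level_mg_per_kg), row.compound
            )
            for row in self.guidelines.itertuples(index=False)
        }

    def intake_objects(self) -> dict[tuple[str, str, str], IntakeDistribution]:
        out = {}
        for row in self.intakes.itertuples(index=False):
            out[(row.country, row.age_sex_group, row.nutrient)] = (
                IntakeDistribution.from_mean_cv(
                    row.family,
                    float(row.mean),
                    float(row.cv),
                    country=row.country,
                    age_sex_group=row.age_sex_group,
                    nutrient=row.nutrient,
                )
            )
        return out

    def requirement_objects(self) -> dict[tuple[str, str], RequirementDistribution]:
        out = {}
        for row in self.requirements.itertuples(index=False):
            out[(row.nutrient, row.age_sex_group)] = RequirementDistribution(
                nutrient=row.nutrient,
                age_sex_group=row.age_sex_group,
                ar=float(row.ar),
                req_cv=float(row.req_cv) if not pd.isna(row.req_cv) else DEFAULT_REQ_CV,
                family=row.req_family if isinstance(row.req_family, str) else "normal",
            )
        return out

    def ul_objects(self) -> dict[tuple[str, str], UpperLevel]:
        return {
            (row.nutrient, row.age_sex_group): UpperLevel(
                row.nutrient, row.age_sex_group, float(row.ul)
            )
            for row in self.uls.itertuples(index=False)
        }

    def compound_map(self) -> dict[str, CompoundSpec]:
        """Nutrient -> compound specification."""
        return {
            row.nutrient: CompoundSpec(
                row.compound, row.nutrient, float(row.activity), float(row.price_usd_per_kg)
            )
            for row in self.compounds.itertuples(index=False)
        }

    def region_map(self) -> dict[str, str]:
        return dict(zip(self.regions["country"], self.regions["region"]))

    def calorie_ratio_map(self) -> dict[tuple[str, str], float]:
        return {
            (row.country, row.age_sex_group): float(row.calorie_ratio)
            for row in self.calorie_scaling.itertuples(index=False)
        }

    def supply_map(self) -> dict[tuple[str, str], float]:
        return {
            (row.country, row.vehicle): float(row.supply_tonnes_yr)
            for row in self.facilities.itertuples(index=False)
        }

    def facility_map(self) -> dict[tuple[str, str], float]:
        return {
            (row.country, row.vehicle): float(row.facilities)
            for row in self.facilities.itertuples(index=False)
        }

    def country_populations(self) -> dict[str, float]:
        return self.populations.groupby("country")["persons"].sum().to_dict()


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


# ---------------------------------------------------------------------------
# Cost-parameter YAML
# ---------------------------------------------------------------------------


def cost_params_to_dict(params: CostParameters) -> dict:
    d = dataclasses.asdict(params)
    return d


def cost_params_from_dict(data: dict) -> CostParameters:
    data = dict(data or {})
    industry = IndustryUnitCosts(**data.pop("industry", {}))
    government = GovernmentUnitCosts(**data.pop("government", {}))
    return CostParameters(industry=industry, government=government, **data)


# ---------------------------------------------------------------------------
# Directory round-trip
# ---------------------------------------------------------------------------


def save_world(world: World, directory: str | Path) -> Path:
    """Write a world to a directory of CSVs plus cost_parameters.yaml."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, filename in WORLD_FILES.items():
        frame: pd.DataFrame = getattr(world, attr)
        frame.to_csv(directory / filename, index=False)
    with open(directory / COST_PARAMS_FILE, "w") as handle:
        yaml.safe_dump(cost_params_to_dict(world.cost_params), handle, sort_keys=True)
    return directory


def _read_intakes(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    cols = set(frame.columns)
    if {"mean", "cv"} <= cols:
        return frame
    if {"param1", "param2"} <= cols:
        # Family-native dialect: convert to the internal (mean, cv) layout.
        converted = []
        for row in frame.itertuples(index=False):
            dist = IntakeDistribution.from_params(
                row.family, float(row.param1), float(row.param2)
            )
            converted.append(
                {
                    "country": row.country,
                    "age_sex_group": row.age_sex_group,
                    "nutrient": row.nutrient,
                    "family": row.family,
                    "mean": dist.mean,
                    "cv": dist.cv,
                }
            )
        return pd.DataFrame(converted)
    raise ConfigurationError(
        f"{path}: expected columns mean/cv or param1/param2, got {sorted(cols)}"
    )


def load_world(directory: str | Path) -> World:
    """Read a world directory written by :func:`save_world` (or by hand)."""
    directory = Path(directory)
    frames = {}
    for attr, filename in WORLD_FILES.items():
        path = directory / filename
        if not path.exists():
            raise ConfigurationError(f"world directory missing {filename}")
        if attr == "intakes":
            frames[attr] = _read_intakes(path)
        else:
            frames[attr] = pd.read_csv(path)
    # Normalise optional columns.
    req = frames["requirements"]
    if "req_cv" not in req.columns:
        req["req_cv"] = np.nan
    if "req_family" not in req.columns:
        req["req_family"] = "normal"
    req["req_family"] = req["req_family"].fillna("normal")
    with open(directory / COST_PARAMS_FILE) as handle:
        params = cost_params_from_dict(yaml.safe_load(handle))
    units = UnitsRegistry()
    _validate_world_units(frames["intakes"], units)
    return World(cost_params=params, units=units, **frames)


def _validate_world_units(intakes: pd.DataFrame, units: UnitsRegistry) -> None:
    unknown = sorted(set(intakes["nutrient"]) - set(units.nutrients()))
    if unknown:
        raise ConfigurationError(
            f"nutrients with no registered intake unit: {unknown}"
        )
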