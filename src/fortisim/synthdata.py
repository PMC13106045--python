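"""Seeded generator of miniature worlds with the structure the model assumes.

The generator stands in for the real upstream extracts (modelled dietary
intake distributions, fortification-programme indicators, population tables,
cost surveys).  It matches their statistical *structure*, not any country's
geography: intake means are drawn on a log scale around the stratum's
average requirement so baseline inadequacy spans (0, 1); CVs are uniform on
[0.2, 0.8]; programme indicators are drawn within observed-plausible ranges
(compliance 0.10-0.95, industrial processing 0.20-1.00) with per-vehicle
missingness rates matching the share of values the source data had to
impute; and every referenced stratum exists in every table.

The default world has 10 countries in 2 regions with the full stratum
structure of the source data: 34 age-sex groups (17 age bands x 2 sexes)
and 13 micronutrients (the source's 15 minus fluoride, whose fortification
is rare, and vitamin D, whose requirement is partly met by sun exposure).

``generate_known_truth`` emits a degenerate two-country world whose answers
are closed-form — point-mass intakes, vanishing requirement CVs, and a
single-vehicle single-nutrient programme — together with an answer sheet,
for end-to-end pipeline recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costs import CostParameters
from .errors import InvalidParameterError
from .io import World
from .scenarios import MAIZE_FLOUR, OIL, RICE, SALT, VEHICLES, WHEAT_FLOUR
from .units import UnitsRegistry

#: The 13 modelled micronutrients.
NUTRIENTS = (
    "calcium",
    "folate",
    "iodine",
    "iron",
    "niacin",
    "riboflavin",
    "selenium",
    "thiamin",
    "vitamin_a",
    "vitamin_b12",
    "vitamin_b6",
    "vitamin_e",
    "zinc",
)

#: Adult-reference average requirements in registry units per day.
BASE_AR = {
    "calcium": 800.0,  # mg
    "folate": 250.0,  # ug
    "iodine": 95.0,  # ug
    "iron": 7.0,  # mg
    "niacin": 11.0,  # mg
    "riboflavin": 0.9,  # mg
    "selenium": 45.0,  # ug
    "thiamin": 0.9,  # mg
    "vitamin_a": 500.0,  # ug
    "vitamin_b12": 2.0,  # ug
    "vitamin_b6": 1.1,  # mg
    "vitamin_e": 10.0,  # mg
    "zinc": 8.0,  # mg
}

#: Harmonised tolerable upper levels exist for seven of the nutrients.
BASE_UL = {
    "calcium": 2500.0,  # mg
    "iodine": 600.0,  # ug
    "iron": 45.0,  # mg
    "selenium": 300.0,  # ug
    "vitamin_b6": 25.0,  # mg
    "vitamin_e": 300.0,  # mg
    "zinc": 40.0,  # mg
}

#: International guideline fortification levels (mg nutrient per kg vehicle).
GUIDELINE_LEVELS: dict[str, dict[str, float]] = {
    WHEAT_FLOUR: {
        "iron": 30.0,
        "zinc": 40.0,
        "folate": 1.3,
        "vitamin_b12": 0.01,
        "thiamin": 2.0,
        "riboflavin": 3.0,
        "niacin": 35.0,
        "vitamin_b6": 3.0,
        "vitamin_a": 1.5,
        "calcium": 2100.0,
        "selenium": 0.2,
    },
    MAIZE_FLOUR: {
        "iron": 30.0,
        "zinc": 40.0,
        "folate": 1.3,
        "vitamin_b12": 0.01,
        "thiamin": 2.0,
        "riboflavin": 3.0,
        "niacin": 35.0,
        "vitamin_b6": 3.0,
        "vitamin_a": 1.5,
    },
    OIL: {"vitamin_a": 9.0, "vitamin_e": 100.0},
    RICE: {
        "iron": 7.0,
        "zinc": 6.0,
        "folate": 1.3,
        "vitamin_b12": 0.01,
        "thiamin": 3.5,
        "niacin": 26.0,
        "vitamin_b6": 4.0,
    },
    SALT: {"iodine": 30.0},
}

#: Default fortificant compound per nutrient (activity = nutrient fraction).
COMPOUNDS = {
    "calcium": ("calcium_carbonate", 0.40, 1.2),
    "folate": ("folic_acid", 1.00, 70.0),
    "iodine": ("potassium_iodate", 0.59, 30.0),
    "iron": ("ferrous_fumarate", 0.33, 6.0),
    "niacin": ("niacinamide", 0.99, 12.0),
    "riboflavin": ("riboflavin", 1.00, 60.0),
    "selenium": ("sodium_selenate", 0.42, 55.0),
    "thiamin": ("thiamin_mononitrate", 0.92, 30.0),
    "vitamin_a": ("retinyl_palmitate_250", 0.50, 80.0),
    "vitamin_b12": ("cyanocobalamin_01_ws", 0.001, 30.0),
    "vitamin_b6": ("pyridoxine_hcl", 0.82, 25.0),
    "vitamin_e": ("dl_alpha_tocopheryl_acetate", 0.91, 20.0),
    "zinc": ("zinc_oxide", 0.80, 3.0),
}

#: Share of values missing in the source per vehicle (industrial processing
#: and compliance); drawn rows are blanked at these rates.
DEFAULT_IP_MISSINGNESS = {
    SALT: 0.90,
    OIL: 0.85,
    MAIZE_FLOUR: 0.29,
    RICE: 0.24,
    WHEAT_FLOUR: 0.04,
}
DEFAULT_FC_MISSINGNESS = {
    SALT: 0.73,
    OIL: 0.68,
    RICE: 0.29,
    WHEAT_FLOUR: 0.27,
    MAIZE_FLOUR: 0.19,
}

#: (p_mandatory, p_voluntary) per vehicle, reflecting the relative global
#: frequency of legislation by vehicle (salt most common, maize/rice rare).
STATUS_PROBS = {
    SALT: (0.65, 0.10),
    WHEAT_FLOUR: (0.50, 0.07),
    OIL: (0.20, 0.05),
    MAIZE_FLOUR: (0.10, 0.02),
    RICE: (0.05, 0.05),
}

#: Plausible per-capita vehicle intake ranges, g/person/day.
INTAKE_RANGES = {
    WHEAT_FLOUR: (30.0, 300.0),
    MAIZE_FLOUR: (5.0, 200.0),
    OIL: (10.0, 40.0),
    RICE: (20.0, 350.0),
    SALT: (5.0, 12.0),
}

_AGE_BANDS = (
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80+",
)
#: Roughly pyramidal population shares per age band (young-heavy).
_AGE_SHARES = np.array(
    [0.10, 0.095, 0.09, 0.085, 0.08, 0.075, 0.07, 0.065, 0.06, 0.055,
     0.05, 0.045, 0.04, 0.032, 0.025, 0.018, 0.015]
)
_AGE_SHARES = _AGE_SHARES / _AGE_SHARES.sum()

#: Menstruating-age female bands: skewed iron requirement.
_MENSTRUATING_BANDS = {"15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49"}


def default_age_sex_groups() -> list[str]:
    return [f"{sex}_{band}" for sex in ("M", "F") for band in _AGE_BANDS]


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of a generated world (defaults = study conditions)."""

    n_countries: int = 10
    n_regions: int = 2
    age_sex_groups: tuple[str, ...] = tuple(default_age_sex_groups())
    nutrients: tuple[str, ...] = NUTRIENTS
    ip_missingness: dict = field(default_factory=lambda: dict(DEFAULT_IP_MISSINGNESS))
    fc_missingness: dict = field(default_factory=lambda: dict(DEFAULT_FC_MISSINGNESS))
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_countries < 1 or self.n_regions < 1:
            raise InvalidParameterError("need at least one country and one region")
        for rates in (self.ip_missingness, self.fc_missingness):
            for v, r in rates.items():
                if not (0.0 <= r < 1.0):
                    raise InvalidParameterError(f"missingness for {v} must lie in [0, 1)")


def _group_parts(group: str) -> tuple[str, str]:
    sex, band = group.split("_", 1)
    return sex, band


def _requirement_factor(group: str) -> float:
    """Age-sex scaling of the adult-reference requirement."""
    sex, band = _group_parts(group)
    idx = _AGE_BANDS.index(band)
    factor = min(1.0, 0.35 + 0.65 * idx / 4.0)  # ramps to adult level by ~20 y
    if sex == "M" and idx >= 4:
        factor *= 1.1
    return factor


def _energy_factor(group: str) -> float:
    """Relative caloric intake of the group (pre-normalisation)."""
    sex, band = _group_parts(group)
    idx = _AGE_BANDS.index(band)
    factor = min(1.0, 0.40 + 0.60 * idx / 4.0)
    if idx >= 13:  # caloric intake declines in older age
        factor *= 0.92
    if sex == "M" and idx >= 3:
        factor *= 1.12
    return factor


def generate_world(config: WorldConfig | None = None) -> World:
    """Generate a complete, mutually consistent world from a seed."""
    config = config or WorldConfig()
    rng = np.random.default_rng(config.seed)
    countries = [f"C{i:03d}" for i in range(config.n_countries)]
    groups = list(config.age_sex_groups)
    nutrients = list(config.nutrients)
    units = UnitsRegistry()

    regions = pd.DataFrame(
        {
            "country": countries,
            "region": [f"R{i % config.n_regions}" for i in range(len(countries))],
        }
    )

    # Populations: country totals log-normal around 10 million, split over
    # groups by a fixed pyramid with an even sex ratio.
    totals = np.exp(rng.normal(math.log(1e7), 0.8, size=len(countries)))
    pop_rows = []
    for country, total in zip(countries, totals):
        for group in groups:
            _, band = _group_parts(group)
            share = _AGE_SHARES[_AGE_BANDS.index(band)] / 2.0
            pop_rows.append(
                {"country": country, "age_sex_group": group,
                 "persons": float(round(total * share))}
            )
    populations = pd.DataFrame(pop_rows)

    # Calorie scalings: shared age-sex energy pattern with mild per-country
    # noise, renormalised so the population-weighted mean is exactly 1.
    cal_rows = []
    for country in countries:
        noise = rng.normal(0.0, 0.03, size=len(groups))
        raw = np.array([_energy_factor(g) for g in groups]) * np.exp(noise)
        weights = populations.loc[
            populations["country"] == country, "persons"
        ].to_numpy()
        raw = raw / float(np.average(raw, weights=weights))
        for group, ratio in zip(groups, raw):
            cal_rows.append(
                {"country": country, "age_sex_group": group, "calorie_ratio": float(ratio)}
            )
    calorie_scaling = pd.DataFrame(cal_rows)

    # Requirements: adult-reference AR scaled per group; iron requirements
    # for menstruating-age women are right-skewed (log-normal, CV 0.25).
    req_rows = []
    for nutrient in nutrients:
        for group in groups:
            sex, band = _group_parts(group)
            ar = BASE_AR[nutrient] * _requirement_factor(group)
            req_cv, family = 0.10, "normal"
            if nutrient == "iron" and sex == "F" and band in _MENSTRUATING_BANDS:
                ar *= 1.4
                req_cv, family = 0.25, "lognormal"
            req_rows.append(
                {"nutrient": nutrient, "age_sex_group": group, "ar": round(ar, 6),
                 "req_cv": req_cv, "req_family": family}
            )
    requirements = pd.DataFrame(req_rows)

    ul_rows = [
        {"nutrient": nutrient, "age_sex_group": group,
         "ul": round(BASE_UL[nutrient] * _requirement_factor(group), 6)}
        for nutrient in nutrients if nutrient in BASE_UL
        for group in groups
    ]
    uls = pd.DataFrame(ul_rows)

    # Intake distributions: mean/AR ratio log-normal around 1 per country x
    # nutrient with small per-group noise, so baseline inadequacy spans (0,1).
    ar_lookup = {
        (r.nutrient, r.age_sex_group): r.ar for r in requirements.itertuples(index=False)
    }
    family_of = {
        nutrient: ("lognormal" if i % 2 == 0 else "gamma")
        for i, nutrient in enumerate(sorted(nutrients))
    }
    intake_rows = []
    for country in countries:
        for nutrient in nutrients:
            country_log_ratio = rng.normal(0.0, 0.6)
            for group in groups:
                ratio = math.exp(country_log_ratio + rng.normal(0.0, 0.15))
                mean = ar_lookup[(nutrient, group)] * ratio
                cv = float(rng.uniform(0.2, 0.8))
                intake_rows.append(
                    {"country": country, "age_sex_group": group, "nutrient": nutrient,
                     "family": family_of[nutrient], "mean": round(mean, 8),
                     "cv": round(cv, 8)}
                )
    intakes = pd.DataFrame(intake_rows)

    # Programmes and standards.
    program_rows, standard_rows, facility_rows = [], [], []
    pop_by_country = populations.groupby("country")["persons"].sum().to_dict()
    for country in countries:
        for vehicle in VEHICLES:
            p_mand, p_vol = STATUS_PROBS[vehicle]
            u = rng.uniform()
            status = "mandatory" if u < p_mand else (
                "voluntary" if u < p_mand + p_vol else "none"
            )
            lo, hi = INTAKE_RANGES[vehicle]
            percap = float(rng.uniform(lo, hi))
            ip = float(rng.uniform(0.2, 1.0))
            fc = float(rng.uniform(0.1, 0.95))
            blank_ip = rng.uniform() < config.ip_missingness.get(vehicle, 0.0)
            blank_fc = status == "none" or (
                rng.uniform() < config.fc_missingness.get(vehicle, 0.0)
            )
            program_rows.append(
                {"country": country, "vehicle": vehicle, "status": status,
                 "percap_intake_g_day": round(percap, 4),
                 "industrially_processed": np.nan if blank_ip else round(ip, 6),
                 "compliance": np.nan if blank_fc else round(fc, 6),
                 "_drawn_ip": round(ip, 6), "_drawn_fc": round(fc, 6)}
            )
            if status != "none":
                # Standards cover a random subset of the vehicle's guideline
                # nutrients at 0.5-1.6x the guideline level, so some countries
                # sit below and some above international guidelines.
                for nutrient, guide_level in GUIDELINE_LEVELS[vehicle].items():
                    if nutrient not in nutrients or rng.uniform() > 0.8:
                        continue
                    level = guide_level * float(rng.uniform(0.5, 1.6))
                    standard_rows.append(
                        {"vehicle": vehicle, "country": country, "nutrient": nutrient,
                         "level_mg_per_kg": round(level, 6),
                         "compound": COMPOUNDS[nutrient][0]}
                    )
            supply = percap * pop_by_country[country] * 365.0 / 1e6  # tonnes/yr
            facility_rows.append(
                {"country": country, "vehicle": vehicle,
                 "facilities": int(rng.integers(1, 51)),
                 "supply_tonnes_yr": round(supply, 4)}
            )
    # Blanking at high per-vehicle rates may remove every observed value; the
    # imputation hierarchy needs at least one donor per vehicle, so restore
    # the first drawn value where a vehicle would otherwise be all-missing.
    for vehicle in VEHICLES:
        rows = [r for r in program_rows if r["vehicle"] == vehicle]
        if rows and all(np.isnan(r["industrially_processed"]) for r in rows):
            rows[0]["industrially_processed"] = rows[0]["_drawn_ip"]
        active = [r for r in rows if r["status"] != "none"]
        if active and all(np.isnan(r["compliance"]) for r in active):
            active[0]["compliance"] = active[0]["_drawn_fc"]
    for row in program_rows:
        row.pop("_drawn_ip")
        row.pop("_drawn_fc")
    programs = pd.DataFrame(program_rows)
    standards = pd.DataFrame(
        standard_rows,
        columns=["vehicle", "country", "nutrient", "level_mg_per_kg", "compound"],
    )
    facilities = pd.DataFrame(facility_rows)

    guidelines = pd.DataFrame(
        [
            {"vehicle": vehicle, "country": "", "nutrient": nutrient,
             "level_mg_per_kg": level, "compound": COMPOUNDS[nutrient][0]}
            for vehicle, levels in GUIDELINE_LEVELS.items()
            for nutrient, level in levels.items()
            if nutrient in nutrients
        ]
    )

    compounds = pd.DataFrame(
        [
            {"compound": name, "nutrient": nutrient, "activity": activity,
             "price_usd_per_kg": price}
            for nutrient, (name, activity, price) in COMPOUNDS.items()
            if nutrient in nutrients
        ]
    )

    return World(
        intakes=intakes,
        programs=programs,
        standards=standards,
        guidelines=guidelines,
        requirements=requirements,
        uls=uls,
        populations=populations,
        calorie_scaling=calorie_scaling,
        compounds=compounds,
        facilities=facilities,
        regions=regions,
        cost_params=CostParameters(),
        units=units,
    )


# ---------------------------------------------------------------------------
# Known-truth worlds
# ---------------------------------------------------------------------------

_KT_AR = 7.0  # mg/day iron, the single nutrient used
_KT_CONTRIB = {"percap": 100.0, "ip": 0.8, "fc": 0.5, "level": 30.0}  # -> 1.2 mg/day


def generate_known_truth(seed: int = 0) -> tuple[World, pd.DataFrame]:
    """A degenerate two-country world with closed-form answers.

    Country ``KTLAND`` has no programmes; each of its age-sex "groups" is
    one analytic case for the adequacy estimator (point-mass intakes at,
    below and above the requirement; vanishing requirement CV reducing to
    the intake CDF at the AR).  Country ``FORTLAND`` runs one mandatory
    wheat-flour iron programme with hand-pickable indicators, so the
    contribution equation's output is a known product.  The answer sheet
    lists (country, age_sex_group, nutrient, scenario, quantity, expected).
    """
    nutrient = "iron"
    tiny = 1e-9
    groups = ["pm_at_ar", "pm_low", "pm_high", "cut_zero", "cut_one", "cut_lognormal"]
    countries = ["KTLAND", "FORTLAND"]

    req_rows, intake_rows, answers = [], [], []
    # Per-group requirement setups (shared by both countries).
    spec_by_group = {
        "pm_at_ar": {"req_cv": 0.10, "family": "normal"},
        "pm_low": {"req_cv": 0.10, "family": "normal"},
        "pm_high": {"req_cv": 0.10, "family": "normal"},
        "cut_zero": {"req_cv": tiny, "family": "normal"},
        "cut_one": {"req_cv": tiny, "family": "normal"},
        "cut_lognormal": {"req_cv": tiny, "family": "normal"},
    }
    for group, spec in spec_by_group.items():
        req_rows.append(
            {"nutrient": nutrient, "age_sex_group": group, "ar": _KT_AR,
             "req_cv": spec["req_cv"], "req_family": spec["family"]}
        )

    def intake(country, group, family, mean, cv):
        intake_rows.append(
            {"country": country, "age_sex_group": group, "nutrient": nutrient,
             "family": family, "mean": mean, "cv": cv}
        )

    for country in countries:
        intake(country, "pm_at_ar", "lognormal", _KT_AR, tiny)
        intake(country, "pm_low", "lognormal", 0.5 * _KT_AR, tiny)
        intake(country, "pm_high", "lognormal", 2.0 * _KT_AR, tiny)
        intake(country, "cut_zero", "gamma", 1.5 * _KT_AR, tiny)  # above AR
        intake(country, "cut_one", "gamma", 0.8 * _KT_AR, tiny)  # below AR
        intake(country, "cut_lognormal", "lognormal", 8.0, 0.3)

    # Closed-form answers for the unfortified country (independent of the
    # pipeline's quadrature): risk-curve values at a point mass and the
    # log-normal CDF at the AR via the error function.
    def normal_risk(x):
        return 0.5 * math.erfc((x - _KT_AR) / (0.10 * _KT_AR * math.sqrt(2.0)))

    sigma2 = math.log1p(0.3**2)
    mu = math.log(8.0) - sigma2 / 2.0
    lognorm_cdf_at_ar = 0.5 * (
        1.0 + math.erf((math.log(_KT_AR) - mu) / math.sqrt(2.0 * sigma2))
    )
    expected_prev = {
        "pm_at_ar": normal_risk(_KT_AR),  # exactly 0.5
        "pm_low": normal_risk(0.5 * _KT_AR),  # ~1
        "pm_high": normal_risk(2.0 * _KT_AR),  # ~0
        "cut_zero": 0.0,  # point mass above a sharp cut-point
        "cut_one": 1.0,  # point mass below a sharp cut-point
        "cut_lognormal": lognorm_cdf_at_ar,
    }
    for scenario in ("no_fortification", "current"):
        for group, value in expected_prev.items():
            answers.append(
                {"country": "KTLAND", "age_sex_group": group, "nutrient": nutrient,
                 "scenario": scenario, "quantity": "prev_inadequate",
                 "expected": value}
            )

    # FORTLAND: one wheat-flour iron programme; contribution is the product
    # F x IP x FC x D / 1000 for every group (calorie ratios are 1).
    c = _KT_CONTRIB
    contrib = c["percap"] * c["ip"] * c["fc"] * c["level"] / 1000.0
    for group in groups:
        answers.append(
            {"country": "FORTLAND", "age_sex_group": group, "nutrient": nutrient,
             "scenario": "current", "quantity": "contribution", "expected": contrib}
        )
        answers.append(
            {"country": "FORTLAND", "age_sex_group": group, "nutrient": nutrient,
             "scenario": "no_fortification", "quantity": "contribution",
             "expected": 0.0}
        )

    program_rows, facility_rows = [], []
    for country in countries:
        for vehicle in VEHICLES:
            active = country == "FORTLAND" and vehicle == WHEAT_FLOUR
            program_rows.append(
                {"country": country, "vehicle": vehicle,
                 "status": "mandatory" if active else "none",
                 "percap_intake_g_day": c["percap"] if active else 10.0,
                 "industrially_processed": c["ip"] if active else 0.5,
                 "compliance": c["fc"] if active else np.nan}
            )
            facility_rows.append(
                {"country": country, "vehicle": vehicle, "facilities": 1,
                 "supply_tonnes_yr": 1000.0}
            )

    standards = pd.DataFrame(
        [{"vehicle": WHEAT_FLOUR, "country": "FORTLAND", "nutrient": nutrient,
          "level_mg_per_kg": c["level"], "compound": COMPOUNDS[nutrient][0]}]
    )
    guidelines = pd.DataFrame(
        [{"vehicle": WHEAT_FLOUR, "country": "", "nutrient": nutrient,
          "level_mg_per_kg": 30.0, "compound": COMPOUNDS[nutrient][0]}]
    )
    populations = pd.DataFrame(
        [{"country": country, "age_sex_group": group, "persons": 1000.0}
         for country in countries for group in groups]
    )
    calorie_scaling = pd.DataFrame(
        [{"country": country, "age_sex_group": group, "calorie_ratio": 1.0}
         for country in countries for group in groups]
    )
    compounds = pd.DataFrame(
        [{"compound": COMPOUNDS[nutrient][0], "nutrient": nutrient,
          "activity": COMPOUNDS[nutrient][1],
          "price_usd_per_kg": COMPOUNDS[nutrient][2]}]
    )
    regions = pd.DataFrame({"country": countries, "region": ["R0", "R0"]})

    world = World(
        intakes=pd.DataFrame(intake_rows),
        programs=pd.DataFrame(program_rows),
        standards=standards,
        guidelines=guidelines,
        requirements=pd.DataFrame(req_rows),
        uls=pd.DataFrame(columns=["nutrient", "age_sex_group", "ul"]),
        populations=populations,
        calorie_scaling=calorie_scaling,
        compounds=compounds,
        facilities=pd.DataFrame(facility_rows),
        regions=regions,
        cost_params=CostParameters(),
        units=UnitsRegistry(),
    )
    return world, pd.DataFrame(answers)
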