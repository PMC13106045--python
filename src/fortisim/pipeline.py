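"""End-to-end orchestration: scenarios -> adequacy -> aggregation -> costs.

``run_world`` executes the whole model in memory on a loaded :class:`World`;
``run_all`` wraps it with disk I/O (world directory in, CSV report bundle
plus a YAML manifest out).  Three sensitivity analyses rerun the relevant
part of the pipeline under a perturbed input: calcium alignment for wheat
flour toggled off, an alternative compliance table, and compound-price
scaling.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate
from .adequacy import NOT_ASSESSED, prevalence_excess, prevalence_inadequate
from .costs import scenario_costs
from .distributions import SHIFT_CV
from .errors import ConfigurationError, IntegrityError
from .io import World, load_world
from .scenarios import (
    ALIGN_MAX,
    SCENARIO_NAMES,
    ExpansionParams,
    FortificationProgram,
    ScenarioSpec,
    apply_scenario,
    fortificant_contribution,
    impute_missing,
)

logger = logging.getLogger("fortisim")

BASELINE = "no_fortification"
CURRENT = "current"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    world_dir: str | Path
    out_dir: str | Path
    scenarios: tuple[str, ...] = SCENARIO_NAMES
    shift_convention: str = SHIFT_CV
    align_rule: str = ALIGN_MAX
    expansion_params: ExpansionParams = field(default_factory=ExpansionParams)
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class RunResult:
    """All tables produced by one run (unrounded)."""

    adequacy: pd.DataFrame  # scenario x stratum rows with prevalences/counts
    nutrient_summary: pd.DataFrame
    prevented_vs_baseline: pd.DataFrame
    prevented_vs_current: pd.DataFrame
    excess_summary: pd.DataFrame
    country_nutrient: pd.DataFrame
    cost_breakdown: pd.DataFrame
    cost_summary: pd.DataFrame
    totals: dict[str, float]  # scenario -> person-nutrient total
    cost_totals: dict[str, dict]  # scenario -> cost summary dict
    programs: dict[str, list[FortificationProgram]]


# ---------------------------------------------------------------------------
# Adequacy for one scenario
# ---------------------------------------------------------------------------


class _PrevalenceCache:
    """Memoises stratum prevalences keyed by the fortificant contribution.

    A stratum's shifted intake distribution is fully determined by the
    stratum identifiers and the contribution, so scenarios that leave a
    stratum's contribution unchanged (most of them, for most strata) reuse
    the quadrature result.
    """

    def __init__(self) -> None:
        self._store: dict[tuple, tuple[float, float]] = {}

    def get(self, key: tuple):
        return self._store.get(key)

    def put(self, key: tuple, value: tuple[float, float]) -> None:
        self._store[key] = value


def _scenario_adequacy(
    world: World,
    scenario: str,
    programs: list[FortificationProgram],
    cache: _PrevalenceCache,
    shift_convention: str,
    intakes: dict,
    requirements: dict,
    uls: dict,
    ratios: dict,
) -> pd.DataFrame:
    by_country: dict[str, list[FortificationProgram]] = {}
    for program in programs:
        by_country.setdefault(program.country, []).append(program)

    # Per-country, per-nutrient contribution at calorie ratio 1; the group
    # contribution is this coefficient times the group's calorie ratio.
    coef: dict[tuple[str, str], float] = {}
    rows = []
    for (country, group, nutrient), dist in intakes.items():
        req = requirements.get((nutrient, group))
        if req is None:
            raise IntegrityError(
                f"no requirement for nutrient={nutrient!r} group={group!r}"
            )
        ckey = (country, nutrient)
        if ckey not in coef:
            coef[ckey] = fortificant_contribution(
                by_country.get(country, ()), nutrient, world.units, calorie_ratio=1.0
            )
        ratio = ratios.get((country, group))
        if ratio is None:
            logger.warning(
                "no calorie scaling for %s/%s; falling back to ratio 1", country, group
            )
            ratio = 1.0
        contribution = coef[ckey] * ratio
        key = (country, group, nutrient, round(contribution, 12))
        cached = cache.get(key)
        if cached is None:
            shifted = dist.shift(contribution, convention=shift_convention)
            prev = prevalence_inadequate(shifted, req)
            ul = uls.get((nutrient, group))
            excess = prevalence_excess(shifted, ul)
            excess_value = np.nan if excess == NOT_ASSESSED else excess
            cached = (prev, excess_value)
            cache.put(key, cached)
        rows.append(
            {
                "scenario": scenario,
                "country": country,
                "age_sex_group": group,
                "nutrient": nutrient,
                "contribution": contribution,
                "prev_inadequate": cached[0],
                "prev_excess": cached[1],
                "ul_assessed": (nutrient, group) in uls,
            }
        )
    frame = pd.DataFrame(rows)
    return aggregate.attach_counts(frame, world.populations)


def _country_baseline_prevalence(baseline: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Population-weighted country x nutrient baseline inadequacy."""
    table = aggregate.country_nutrient_table(baseline)
    return {
        (row.country, row.nutrient): float(row.prev_inadequate)
        for row in table.itertuples(index=False)
    }


def _excess_summary(adequacy: pd.DataFrame) -> pd.DataFrame:
    """Population-weighted percent above the UL per scenario x nutrient.

    Only strata with an assessed UL enter the denominator.
    """
    assessed = adequacy[adequacy["ul_assessed"]]
    if assessed.empty:
        return pd.DataFrame(
            columns=["scenario", "nutrient", "pct_above_ul", "n_excess", "persons"]
        )
    grouped = assessed.groupby(["scenario", "nutrient"], as_index=False).agg(
        n_excess=("n_excess", "sum"), persons=("persons", "sum")
    )
    grouped["pct_above_ul"] = 100.0 * grouped["n_excess"] / grouped["persons"]
    return grouped


# ---------------------------------------------------------------------------
# Whole-world runs
# ---------------------------------------------------------------------------


def run_world(
    world: World,
    scenarios: tuple[str, ...] = SCENARIO_NAMES,
    shift_convention: str = SHIFT_CV,
    align_rule: str = ALIGN_MAX,
    expansion_params: ExpansionParams | None = None,
    guidelines: dict | None = None,
) -> RunResult:
    """Run the requested scenarios on a loaded world.

    ``guidelines`` overrides the world's guideline table (used by the
    calcium sensitivity analysis).
    """
    unknown = sorted(set(scenarios) - set(SCENARIO_NAMES))
    if unknown:
        raise ConfigurationError(f"unknown scenario names: {unknown}")
    expansion_params = expansion_params or ExpansionParams()
    guidelines = world.guideline_map() if guidelines is None else guidelines

    imputed = impute_missing(world.program_objects(), world.region_map())
    intakes = world.intake_objects()
    requirements = world.requirement_objects()
    uls = world.ul_objects()
    ratios = world.calorie_ratio_map()
    cache = _PrevalenceCache()

    # Baseline is always computed: it anchors prevented counts and the
    # expansion-eligibility rule.
    baseline_spec = ScenarioSpec.canonical(BASELINE)
    baseline_programs = apply_scenario(imputed, baseline_spec)
    baseline = _scenario_adequacy(
        world, BASELINE, baseline_programs, cache, shift_convention,
        intakes, requirements, uls, ratios,
    )
    baseline_map = _country_baseline_prevalence(baseline)

    adequacy_frames, cost_frames = [], []
    totals: dict[str, float] = {}
    cost_totals: dict[str, dict] = {}
    programs_by_scenario: dict[str, list[FortificationProgram]] = {}
    cost_summary_rows = []

    compounds = world.compound_map()
    supply = world.supply_map()
    facilities = world.facility_map()
    country_pops = world.country_populations()

    for name in scenarios:
        if name == BASELINE:
            frame, scenario_programs = baseline, baseline_programs
        else:
            spec = ScenarioSpec.canonical(
                name, align_rule=align_rule, expansion_params=expansion_params
            )
            scenario_programs = apply_scenario(
                imputed, spec, guidelines=guidelines, baseline_prevalence=baseline_map
            )
            frame = _scenario_adequacy(
                world, name, scenario_programs, cache, shift_convention,
                intakes, requirements, uls, ratios,
            )
        programs_by_scenario[name] = scenario_programs
        adequacy_frames.append(frame)
        totals[name] = aggregate.person_nutrient_total(frame)

        breakdown, summary = scenario_costs(
            scenario_programs, compounds, world.cost_params, supply, facilities,
            country_pops,
        )
        breakdown = breakdown.copy()
        breakdown.insert(0, "scenario", name)
        cost_frames.append(breakdown)
        cost_totals[name] = summary
        cost_summary_rows.append(
            {
                "scenario": name,
                "total": summary["total"],
                "premix": summary["premix"],
                "industry": summary["industry"],
                "government": summary["government"],
                "per_person_mean": summary["per_person_mean"],
                "per_person_sd": summary["per_person_sd"],
                **{f"share_{v}_pct": s for v, s in summary["vehicle_shares_pct"].items()},
            }
        )
        logger.info(
            "scenario %s: person-nutrient inadequacies %.6g, cost $%.6g/yr",
            name, totals[name], summary["total"],
        )

    adequacy = pd.concat(adequacy_frames, ignore_index=True)

    nutrient_rows = []
    for name in scenarios:
        sub = adequacy[adequacy["scenario"] == name]
        table = aggregate.nutrient_totals(sub)
        table.insert(0, "scenario", name)
        nutrient_rows.append(table)
    nutrient_summary = pd.concat(nutrient_rows, ignore_index=True)

    def _prevented_vs(reference: str) -> pd.DataFrame:
        if reference not in totals:
            return pd.DataFrame(
                columns=["scenario", "nutrient", "baseline", "remaining", "prevented"]
            )
        ref = adequacy[adequacy["scenario"] == reference]
        out = []
        for name in scenarios:
            if name == reference:
                continue
            table = aggregate.prevented_table(
                ref, adequacy[adequacy["scenario"] == name]
            )
            table.insert(0, "scenario", name)
            out.append(table)
        if not out:
            return pd.DataFrame(
                columns=["scenario", "nutrient", "baseline", "remaining", "prevented"]
            )
        return pd.concat(out, ignore_index=True)

    country_nutrient_rows = []
    for name in scenarios:
        table = aggregate.country_nutrient_table(
            adequacy[adequacy["scenario"] == name]
        )
        table.insert(0, "scenario", name)
        country_nutrient_rows.append(table)

    return RunResult(
        adequacy=adequacy,
        nutrient_summary=nutrient_summary,
        prevented_vs_baseline=_prevented_vs(BASELINE),
        prevented_vs_current=_prevented_vs(CURRENT),
        excess_summary=_excess_summary(adequacy),
        country_nutrient=pd.concat(country_nutrient_rows, ignore_index=True),
        cost_breakdown=_concat_nonempty(cost_frames),
        cost_summary=pd.DataFrame(cost_summary_rows),
        totals=totals,
        cost_totals=cost_totals,
        programs=programs_by_scenario,
    )


def _concat_nonempty(frames: list[pd.DataFrame]) -> pd.DataFrame:
    non_empty = [f for f in frames if not f.empty]
    if non_empty:
        return pd.concat(non_empty, ignore_index=True)
    return frames[0] if frames else pd.DataFrame()


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_all(config: RunConfig) -> RunResult:
    """Load a world directory, run the scenarios and write the report bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    world_dir = Path(config.world_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    world = load_world(world_dir)
    result = run_world(
        world,
        scenarios=tuple(config.scenarios),
        shift_convention=config.shift_convention,
        align_rule=config.align_rule,
        expansion_params=config.expansion_params,
    )

    for name in config.scenarios:
        sub = result.adequacy[result.adequacy["scenario"] == name]
        _write_csv(sub, out_dir / f"adequacy_{name}.csv", round_counts=True)
        _write_csv(
            result.cost_breakdown[result.cost_breakdown["scenario"] == name],
            out_dir / f"costs_{name}.csv",
            round_dollars=True,
        )
    _write_csv(result.nutrient_summary, out_dir / "nutrient_summary.csv", round_counts=True)
    _write_csv(result.prevented_vs_baseline, out_dir / "prevented_vs_baseline.csv", round_counts=True)
    _write_csv(result.prevented_vs_current, out_dir / "prevented_vs_current.csv", round_counts=True)
    _write_csv(result.excess_summary, out_dir / "excess_summary.csv")
    _write_csv(result.country_nutrient, out_dir / "country_nutrient.csv")
    _write_csv(result.cost_summary, out_dir / "cost_summary.csv")

    manifest = {
        "config": {
            "world_dir": str(world_dir),
            "scenarios": list(config.scenarios),
            "shift_convention": config.shift_convention,
            "align_rule": config.align_rule,
            "seed": config.seed,
        },
        "input_checksums": {
            path.name: _sha256(path) for path in sorted(world_dir.iterdir())
            if path.is_file()
        },
        "totals": {
            "person_nutrient_inadequacies": {
                name: round(total, 6) for name, total in result.totals.items()
            },
            "annual_cost_usd": {
                name: round(summary["total"], 6)
                for name, summary in result.cost_totals.items()
            },
        },
    }
    with open(out_dir / "manifest.yaml", "w") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=True)
    return result


def _write_csv(
    frame: pd.DataFrame,
    path: Path,
    round_counts: bool = False,
    round_dollars: bool = False,
) -> None:
    frame = frame.copy()
    if round_counts:
        for col in ("n_inadequate", "n_excess", "persons", "baseline", "remaining", "prevented"):
            if col in frame.columns:
                frame[col] = frame[col].round(0)
    if round_dollars:
        for col in ("premix", "industry", "government", "total"):
            if col in frame.columns:
                frame[col] = frame[col].round(2)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sensitivity analyses
# ---------------------------------------------------------------------------

_ALIGNED_SCENARIOS = ("aligned_standards", "aligned_improved", "aligned_improved_expanded")


def sensitivity_calcium(world: World, scenarios: tuple[str, ...] = _ALIGNED_SCENARIOS) -> pd.DataFrame:
    """Aligned scenarios with calcium-in-wheat alignment on versus off.

    The OFF arm removes the wheat-flour calcium row from the guideline
    table, so alignment neither raises existing calcium levels nor adds
    calcium to wheat standards; deltas isolate that single guideline line.
    """
    on = run_world(world, scenarios=scenarios)
    guidelines_off = {
        key: value
        for key, value in world.guideline_map().items()
        if key != ("wheat_flour", "calcium")
    }
    off = run_world(world, scenarios=scenarios, guidelines=guidelines_off)
    rows = []
    for name in scenarios:
        rows.append(
            {
                "scenario": name,
                "inadequacies_on": on.totals[name],
                "inadequacies_off": off.totals[name],
                "inadequacies_delta": on.totals[name] - off.totals[name],
                "cost_on": on.cost_totals[name]["total"],
                "cost_off": off.cost_totals[name]["total"],
                "cost_delta": on.cost_totals[name]["total"] - off.cost_totals[name]["total"],
                "premix_on": on.cost_totals[name]["premix"],
                "premix_off": off.cost_totals[name]["premix"],
            }
        )
    return pd.DataFrame(rows)


def sensitivity_compliance(
    world: World,
    alternative_fc: pd.DataFrame,
    scenarios: tuple[str, ...] = SCENARIO_NAMES,
) -> pd.DataFrame:
    """Rerun under an alternative compliance table and report deltas.

    ``alternative_fc`` must have columns country, vehicle, compliance and
    cover exactly the programme table's (country, vehicle) pairs.
    """
    base_keys = set(zip(world.programs["country"], world.programs["vehicle"]))
    alt_keys = set(zip(alternative_fc["country"], alternative_fc["vehicle"]))
    if base_keys != alt_keys:
        raise IntegrityError(
            "alternative compliance table does not cover the programme strata"
        )
    alt_world = replace(world, programs=world.programs.copy())
    alt = alternative_fc.set_index(["country", "vehicle"])["compliance"]
    idx = pd.MultiIndex.from_frame(alt_world.programs[["country", "vehicle"]])
    alt_world.programs["compliance"] = alt.reindex(idx).to_numpy()

    original = run_world(world, scenarios=scenarios)
    alternate = run_world(alt_world, scenarios=scenarios)
    rows = []
    for name in scenarios:
        rows.append(
            {
                "scenario": name,
                "inadequacies_original": original.totals[name],
                "inadequacies_alternative": alternate.totals[name],
                "inadequacies_delta": alternate.totals[name] - original.totals[name],
                "cost_original": original.cost_totals[name]["total"],
                "cost_alternative": alternate.cost_totals[name]["total"],
                "cost_delta": alternate.cost_totals[name]["total"]
                - original.cost_totals[name]["total"],
            }
        )
    return pd.DataFrame(rows)


def sensitivity_price(
    world: World,
    factors: tuple[float, ...] = (0.5, 1.5),
    scenarios: tuple[str, ...] = SCENARIO_NAMES,
) -> pd.DataFrame:
    """Scale every compound price and report the cost response.

    Premix costs are linear in prices, so the premix component scales by
    exactly the factor and the relative total-cost change equals
    ``(factor - 1) x premix share``; both are reported per scenario.
    """
    if any(f <= 0 for f in factors):
        raise ConfigurationError("price factors must be positive")
    baseline_result = run_world(world, scenarios=scenarios)
    compounds = world.compound_map()
    supply = world.supply_map()
    facility = world.facility_map()
    pops = world.country_populations()

    rows = []
    for name in scenarios:
        programs = baseline_result.programs[name]
        base = baseline_result.cost_totals[name]
        for factor in factors:
            _, scaled = scenario_costs(
                programs, compounds, world.cost_params, supply, facility, pops,
                price_factor=factor,
            )
            relative = (
                (scaled["total"] - base["total"]) / base["total"]
                if base["total"] > 0
                else 0.0
            )
            rows.append(
                {
                    "scenario": name,
                    "factor": factor,
                    "total": scaled["total"],
                    "premix": scaled["premix"],
                    "base_total": base["total"],
                    "base_premix": base["premix"],
                    "relative_total_change": relative,
                    "premix_share": base["premix"] / base["total"]
                    if base["total"] > 0
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)
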