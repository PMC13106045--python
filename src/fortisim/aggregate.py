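"""Population aggregation: person-nutrient counts and prevented/remaining.

A "person-nutrient inadequacy" counts one person inadequate in one nutrient,
so summing across the modelled nutrients can count the same person several
times.  Counts are kept as real numbers throughout and rounded only when a
report is rendered, so totals over thousands of strata carry no accumulated
rounding error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import IntegrityError

STRATUM_KEYS = ["country", "age_sex_group", "nutrient"]


def count_inadequate(prev: float, persons: float) -> float:
    """Number of people with inadequate intake in one stratum (unrounded)."""
    if not (0.0 <= prev <= 1.0):
        raise IntegrityError(f"prevalence {prev} outside [0, 1]")
    return prev * persons


def attach_counts(results: pd.DataFrame, populations: pd.DataFrame) -> pd.DataFrame:
    """Join populations and add n_inadequate / n_excess columns.

    ``results`` has one row per (country, age_sex_group, nutrient) with
    prev_inadequate and prev_excess (NaN where no UL is assessed);
    ``populations`` has columns country, age_sex_group, persons.
    """
    merged = results.merge(populations, on=["country", "age_sex_group"], how="left")
    if merged["persons"].isna().any():
        missing = merged.loc[merged["persons"].isna(), ["country", "age_sex_group"]]
        raise IntegrityError(
            f"population table missing strata: {missing.drop_duplicates().to_dict('records')[:5]}"
        )
    merged["n_inadequate"] = merged["prev_inadequate"] * merged["persons"]
    merged["n_excess"] = merged["prev_excess"] * merged["persons"]
    return merged


def _check_unique(results: pd.DataFrame) -> None:
    dups = results.duplicated(subset=STRATUM_KEYS)
    if dups.any():
        row = results.loc[dups, STRATUM_KEYS].iloc[0].to_dict()
        raise IntegrityError(f"duplicate stratum row: {row}")


def person_nutrient_total(results: pd.DataFrame) -> float:
    """Total inadequate person-nutrient intakes for one scenario's table."""
    if results.empty:
        return 0.0
    _check_unique(results)
    return float(results["n_inadequate"].sum())


def nutrient_totals(results: pd.DataFrame) -> pd.DataFrame:
    """Per-nutrient inadequate counts (and assessed excess counts)."""
    _check_unique(results)
    return (
        results.groupby("nutrient", as_index=False)
        .agg(
            n_inadequate=("n_inadequate", "sum"),
            n_excess=("n_excess", lambda s: s.sum(min_count=1)),
            persons=("persons", "sum"),
        )
        .sort_values("nutrient", ignore_index=True)
    )


def prevented(baseline_total: float, scenario_total: float) -> float:
    """Person-nutrient inadequacies prevented relative to a baseline total."""
    return baseline_total - scenario_total


def prevented_table(
    baseline: pd.DataFrame, scenario: pd.DataFrame
) -> pd.DataFrame:
    """Per-nutrient prevented and remaining counts versus a baseline.

    Both frames carry n_inadequate per stratum; the strata universes must
    match exactly so coverage differences can never masquerade as impact.
    """
    for frame in (baseline, scenario):
        _check_unique(frame)
    b = baseline.set_index(STRATUM_KEYS)["n_inadequate"]
    s = scenario.set_index(STRATUM_KEYS)["n_inadequate"]
    if not b.index.sort_values().equals(s.index.sort_values()):
        raise IntegrityError("baseline and scenario strata universes differ")
    s = s.reindex(b.index)
    out = pd.DataFrame(
        {
            "baseline": b.groupby(level="nutrient").sum(),
            "remaining": s.groupby(level="nutrient").sum(),
        }
    )
    out["prevented"] = out["baseline"] - out["remaining"]
    return out.reset_index()


def country_nutrient_table(results: pd.DataFrame) -> pd.DataFrame:
    """Country x nutrient prevalence and counts (population-weighted)."""
    _check_unique(results)
    grouped = results.groupby(["country", "nutrient"], as_index=False).agg(
        n_inadequate=("n_inadequate", "sum"), persons=("persons", "sum")
    )
    grouped["prev_inadequate"] = np.where(
        grouped["persons"] > 0, grouped["n_inadequate"] / grouped["persons"], 0.0
    )
    return grouped
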