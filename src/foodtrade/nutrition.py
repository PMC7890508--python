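"""Food supply -> nutrient intake -> sufficiency classification.

The pipeline discounts the food share of domestic supply for household waste
(region- and food-group-specific) and inedible fractions, applies the
country's fortification variant for refinable commodities, converts tonnes
to per-person-per-day nutrient amounts and classifies each nutrient against
the demographically weighted requirement. Total fat is banded (too little
and too much both count against the country); every other nutrient is
sufficient when intake reaches the requirement (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .world import (
    FAT_INDEX,
    NUTRIENTS,
    CommodityDef,
    CountryState,
    RequirementTable,
    SchemaError,
    World,
)

DAYS_PER_YEAR = 365.0

STATUS_SUFFICIENT = "sufficient"
STATUS_INSUFFICIENT = "insufficient"
STATUS_LOW = "low"
STATUS_HEALTHY = "healthy"
STATUS_OVER = "over"


@dataclass(frozen=True)
class SufficiencyReport:
    """Classification of one country's intake of one nutrient."""

    country: str
    nutrient: str
    intake: float              # per person per day
    requirement: float         # per person per day (lower bound for fat)
    requirement_upper: float | None  # upper bound for banded nutrients
    status: str
    margin: float              # intake / requirement


def edible_consumed(food_supply: np.ndarray, country: CountryState, world: World) -> np.ndarray:
    """Tonnes of edible, non-wasted food per commodity.

    Applies the household-waste rate of the country's region and the
    commodity's food group, then the edible fraction. Waste applies to the
    food component only; pre-household losses are already netted out of the
    food share of domestic supply.
    """
    out = np.empty(len(food_supply))
    for ci, com in enumerate(world.commodities):
        waste = world.waste.rate(country.region, com.group)
        out[ci] = food_supply[ci] * (1.0 - waste) * com.edible_fraction
    return out


def effective_composition(commodity: CommodityDef, country: CountryState) -> np.ndarray:
    """Nutrient amounts per tonne for the variant this country consumes.

    Refinable commodities resolve through the country's fortification
    profile; everything else uses the base (unrefined) composition.
    """
    variant = commodity.variant_for(country.fortification_profile)
    try:
        return commodity.composition[variant]
    except KeyError:
        raise SchemaError(
            f"commodity {commodity.code} has no composition variant {variant!r}") from None


def intake_per_capita(consumed: np.ndarray, compositions: np.ndarray,
                      population: float) -> np.ndarray:
    """Per-person-per-day nutrient intake from edible consumption.

    ``compositions`` is (n_commodities, n_nutrients) per tonne. Linear in
    consumption.
    """
    if not population > 0:
        raise ValueError("population must be positive")
    totals = consumed @ compositions
    return totals / (population * DAYS_PER_YEAR)


def requirement_per_capita(demographics: np.ndarray, table: RequirementTable,
                           ) -> tuple[np.ndarray, tuple[float, float]]:
    """Population-weighted mean requirement per nutrient, plus the fat band.

    ``demographics`` are shares per age-sex group summing to 1 and must align
    with the table's group list.
    """
    shares = np.asarray(demographics, dtype=float)
    if shares.shape != (len(table.groups),):
        raise SchemaError(
            f"demographics has {shares.shape[0]} groups, requirement table has "
            f"{len(table.groups)}")
    req = shares @ table.values
    fat_lower = float(req[FAT_INDEX])
    fat_upper = float(shares @ table.fat_upper)
    return req, (fat_lower, fat_upper)


def classify(intake: np.ndarray, requirement: np.ndarray,
             fat_band: tuple[float, float], country: str = "") -> list[SufficiencyReport]:
    """Classify every nutrient of one country.

    Non-banded nutrients are sufficient iff intake >= requirement. Fat is
    low below the band, over above it, healthy inside (band edges count as
    healthy). The margin is intake relative to the (lower) requirement.
    """
    reports = []
    for ni, nutrient in enumerate(NUTRIENTS):
        x = float(intake[ni])
        if nutrient == "fat":
            lo, hi = fat_band
            if x < lo:
                status = STATUS_LOW
            elif x > hi:
                status = STATUS_OVER
            else:
                status = STATUS_HEALTHY
            reports.append(SufficiencyReport(country, nutrient, x, lo, hi, status,
                                             x / lo if lo > 0 else np.inf))
        else:
            r = float(requirement[ni])
            status = STATUS_SUFFICIENT if x >= r else STATUS_INSUFFICIENT
            reports.append(SufficiencyReport(country, nutrient, x, r, None, status,
                                             x / r if r > 0 else np.inf))
    return reports


def country_nutrition(country: CountryState, world: World) -> list[SufficiencyReport]:
    """Full pipeline for one country from its current food supply."""
    consumed = edible_consumed(country.food_supply, country, world)
    comps = np.stack([effective_composition(c, country) for c in world.commodities])
    intake = intake_per_capita(consumed, comps, country.population)
    req, band = requirement_per_capita(country.demographics, world.requirements)
    country.nutrient_intake = intake
    country.nutrient_requirement = req
    country.fat_band = band
    return classify(intake, req, band, country.id)
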