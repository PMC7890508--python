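"""One simulated year, and multi-year horizons.

A year proceeds in a fixed order: exogenous GDP/population/production
updates, annual rescaling of each country's typical diet with global
per-capita supply, trade positions, one independent market per commodity,
the food-supply identity, the nutrition pipeline, and finally the
accumulation of the year's transactions onto the emergent-relationship
matrices (so new trade raises the pair's priority from the next year on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nutrition
from .engine import MarketParams, Transaction, run_commodity_market, update_emergent
from .world import PriorityWeights, World


@dataclass
class YearInputs:
    """Exogenous drivers for one year."""

    year: int
    gdp: dict[str, float]                    # country id -> currency units
    population: dict[str, float]             # country id -> persons
    production: dict[str, np.ndarray]        # country id -> tonnes per commodity

    @classmethod
    def from_baseline(cls, world: World, year: int) -> "YearInputs":
        """Inputs that hold every driver at its baseline value."""
        return cls(
            year=year,
            gdp={c.id: c.gdp for c in world.countries},
            population={c.id: c.population for c in world.countries},
            production={c.id: c.baseline_production.copy() for c in world.countries},
        )

    def validate(self, world: World) -> None:
        for c in world.countries:
            for name, table in (("gdp", self.gdp), ("population", self.population),
                                ("production", self.production)):
                if c.id not in table:
                    raise KeyError(f"year {self.year}: missing {name} for country {c.id}")
            if len(self.production[c.id]) != world.n_commodities:
                raise KeyError(
                    f"year {self.year}: production for {c.id} covers "
                    f"{len(self.production[c.id])} commodities, world has {world.n_commodities}")
            if not self.population[c.id] > 0:
                raise ValueError(f"year {self.year}: non-positive population for {c.id}")
            if np.any(self.production[c.id] < 0):
                raise ValueError(f"year {self.year}: negative production for {c.id}")


def scale_typical_diet(baseline_diet: np.ndarray, baseline_global_supply_pc: np.ndarray,
                       current_global_supply_pc: np.ndarray) -> np.ndarray:
    """Rescale a typical diet with the change in global per-capita supply.

    Each commodity entry moves in proportion to the ratio of current to
    baseline global per-capita supply, so diets drift with what the world
    actually produces rather than jumping to an ideal diet.
    """
    baseline_diet = np.asarray(baseline_diet, dtype=float)
    base = np.asarray(baseline_global_supply_pc, dtype=float)
    cur = np.asarray(current_global_supply_pc, dtype=float)
    consumed = baseline_diet > 0
    if np.any(consumed & (base <= 0)):
        bad = np.where(consumed & (base <= 0))[0]
        raise ValueError(f"zero baseline global supply for consumed commodities {bad.tolist()}")
    ratio = np.ones_like(base)
    ok = base > 0
    ratio[ok] = cur[ok] / base[ok]
    return baseline_diet * ratio


@dataclass
class YearResult:
    """Outputs of one simulated year."""

    year: int
    transactions: list[Transaction]
    reports: list[nutrition.SufficiencyReport]
    diet_targets: dict[str, np.ndarray] = field(default_factory=dict)

    def sufficiency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.country, r.nutrient, r.intake, r.requirement, r.status, r.margin)
             for r in self.reports],
            columns=["country", "nutrient", "intake", "requirement", "status", "margin"])


def _market_rng(seed: int, year: int, commodity_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, year, commodity_index)))


def step_year(world: World, inputs: YearInputs, params: MarketParams,
              weights: PriorityWeights, seed: int = 0,
              compute_nutrition: bool = True) -> YearResult:
    """Advance the world by one year in place.

    The commodity markets run in commodity-list order with independent
    seeded RNG streams; because markets do not interact, the order does not
    affect outcomes. Returns the year's transactions and sufficiency
    reports.
    """
    inputs.validate(world)
    n_com = world.n_commodities

    # (1) exogenous updates
    for c in world.countries:
        c.gdp = float(inputs.gdp[c.id])
        c.population = float(inputs.population[c.id])
        c.production = np.asarray(inputs.production[c.id], dtype=float).copy()

    # (2) diet rescaling with global per-capita supply
    total_pop = sum(c.population for c in world.countries)
    global_production = np.sum([c.production for c in world.countries], axis=0)
    base_pc = world.baseline_global_production / world.baseline_population
    cur_pc = global_production / total_pop
    ratios = np.ones(n_com)
    ok = base_pc > 0
    ratios[ok] = cur_pc[ok] / base_pc[ok]
    diet_targets: dict[str, np.ndarray] = {}
    for c in world.countries:
        diet_targets[c.id] = scale_typical_diet(c.typical_diet, base_pc, cur_pc)

    # (3) trade positions
    from .engine import determine_positions
    for c in world.countries:
        c.import_realized = np.zeros(n_com)
        c.export_realized = np.zeros(n_com)
        for ci in range(n_com):
            need_dom, need_int, avail = determine_positions(
                c, ci, diet_targets[c.id][ci], ratios[ci])
            c.import_needed_domestic[ci] = need_dom
            c.import_needed_intermediary[ci] = need_int
            c.export_available[ci] = avail

    # (4) one independent market per commodity
    transactions: list[Transaction] = []
    for ci in range(n_com):
        rng = _market_rng(seed, inputs.year, ci)
        transactions.extend(
            run_commodity_market(world, ci, params, weights, rng, year=inputs.year))

    # (5) food supply identity (stock variation set to zero)
    for c in world.countries:
        ds = c.production + c.import_realized - c.export_realized
        c.food_supply = np.maximum(ds, 0.0) * c.pct_food

    # (6) nutrition pipeline
    reports: list[nutrition.SufficiencyReport] = []
    if compute_nutrition:
        for c in world.countries:
            reports.extend(nutrition.country_nutrition(c, world))

    # (7) emergent-relationship update
    update_emergent(world.relations, transactions)

    return YearResult(inputs.year, transactions, reports, diet_targets)


@dataclass
class HorizonResult:
    """Outputs of a multi-year run, in the shape the calibration consumes."""

    years: list[int]
    results: list[YearResult]
    #: (country, flow in {import, export, food}, commodity, year) -> tonnes
    volumes: dict[tuple[str, str, str, int], float]
    #: realized (commodity, importer, exporter, year) keys
    partners: set[tuple[str, str, str, int]]

    @property
    def transactions(self) -> list[Transaction]:
        return [t for r in self.results for t in r.transactions]

    def transactions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.transactions,
                            columns=["year", "commodity", "importer", "exporter",
                                     "amount", "round"])


def _collect_volumes(world: World, year: int,
                     volumes: dict[tuple[str, str, str, int], float]) -> None:
    for c in world.countries:
        for ci, com in enumerate(world.commodities):
            volumes[(c.id, "import", com.code, year)] = float(c.import_realized[ci])
            volumes[(c.id, "export", com.code, year)] = float(c.export_realized[ci])
            volumes[(c.id, "food", com.code, year)] = float(c.food_supply[ci])


def run_horizon(world: World, inputs_by_year: list[YearInputs], params: MarketParams,
                weights: PriorityWeights, seed: int = 0,
                compute_nutrition: bool = True) -> HorizonResult:
    """Fold ``step_year`` over consecutive years, mutating the world.

    Emergent trade accumulates across years, so later years' rankings are
    path-dependent on earlier realized trade.
    """
    years = [inp.year for inp in inputs_by_year]
    if any(b - a != 1 for a, b in zip(years, years[1:])):
        raise ValueError(f"years must be consecutive, got {years}")
    results = []
    volumes: dict[tuple[str, str, str, int], float] = {}
    partners: set[tuple[str, str, str, int]] = set()
    for inp in inputs_by_year:
        res = step_year(world, inp, params, weights, seed=seed,
                        compute_nutrition=compute_nutrition)
        results.append(res)
        _collect_volumes(world, inp.year, volumes)
        for t in res.transactions:
            partners.add((t.commodity, t.importer_id, t.exporter_id, t.year))
    return HorizonResult(years, results, volumes, partners)
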