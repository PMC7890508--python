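"""Synthetic worlds with the statistical structure the simulator assumes.

The generator emulates the shape of food-balance-sheet data for a
configurable number of countries and commodities: log-normal GDP per capita
and population, production concentrated in a subset of countries, typical
diets proportional to population, gravity-law historic trade, a fraction of
re-export intermediaries, Dirichlet demographics and the default waste and
requirement tables. It also produces pseudo-observed trade records from
known priority weights so the calibration protocol can be tested for
parameter recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cycle import YearInputs, run_horizon
from .engine import MarketParams
from .world import (
    BASE_VARIANT,
    DEMOGRAPHIC_GROUPS,
    FIBRE_INDEX,
    FOOD_GROUPS,
    INCOME_CLASSES,
    INCOME_TO_VARIANT,
    MICRONUTRIENT_INDICES,
    N_NUTRIENTS,
    NUTRIENTS,
    WASTE_REGIONS,
    CommodityDef,
    CountryState,
    PriorityWeights,
    TradeRelations,
    World,
    default_requirement_table,
    default_waste_table,
    great_circle_km,
)


class GenerationError(ValueError):
    """The requested configuration cannot produce a feasible world."""


@dataclass
class WorldGenConfig:
    """Knobs of the synthetic world.

    Defaults mirror the scale of the empirical setting the model targets:
    165 countries and 91 food commodities, heavy-tailed GDP per capita
    (median ~8000 currency units) and population (median ~9 million), a
    tenth of countries acting as re-export intermediaries, and historic
    trade following a gravity law in GDP product over distance.
    """

    n_countries: int = 165
    n_commodities: int = 91
    seed: int = 0
    gdp_pc_log_mean: float = 9.0
    gdp_pc_log_sd: float = 1.2
    pop_log_mean: float = 16.0
    pop_log_sd: float = 1.5
    #: log-sd of each country's production/demand imbalance; larger values
    #: concentrate production of a commodity in fewer countries
    production_concentration: float = 0.8
    intermediary_fraction: float = 0.1
    gravity_exponent: float = 1.0
    noise_scale: float = 0.3
    #: annual per-capita food consumption pooled over all commodities, t/person
    diet_scale: float = 0.5

    def validate(self) -> None:
        if self.n_countries < 2:
            raise GenerationError("need at least 2 countries")
        if self.n_commodities < 1:
            raise GenerationError("need at least 1 commodity")
        for name in ("gdp_pc_log_sd", "pop_log_sd", "production_concentration",
                     "noise_scale", "diet_scale"):
            if not getattr(self, name) > 0:
                raise GenerationError(f"{name} must be positive")
        if not (0.0 <= self.intermediary_fraction <= 1.0):
            raise GenerationError("intermediary_fraction must lie in [0, 1]")


#: per-tonne composition scale of each nutrient in an average diet that
#: delivers roughly 2500 kcal and typical macro/micro amounts per person per
#: day at ~1.4 kg of food per day
_COMPOSITION_SCALE = {
    "calories": 2.0e6,       # kcal/t
    "protein": 6.5e4,        # g/t
    "fat": 5.5e4,            # g/t
    "vitamin_c": 6.0e4,      # mg/t
    "vitamin_a": 5.0e5,      # ug/t
    "folate": 2.5e5,         # ug/t
    "calcium": 7.0e5,        # mg/t
    "iron": 1.2e4,           # mg/t
    "zinc": 8.0e3,           # mg/t
    "fibre": 1.8e4,          # g/t
    "thiamin": 1.2e3,        # mg/t
    "riboflavin": 1.2e3,     # mg/t
    "niacin": 1.3e4,         # mg/t
    "vitamin_b6": 1.2e3,     # mg/t
    "saturated_fat": 2.0e4,  # g/t
}


def _make_commodities(cfg: WorldGenConfig, rng: np.random.Generator) -> list[CommodityDef]:
    scale = np.array([_COMPOSITION_SCALE[n] for n in NUTRIENTS])
    commodities = []
    for k in range(cfg.n_commodities):
        group = FOOD_GROUPS[k % len(FOOD_GROUPS)]
        refinable = group == "Cereals - Excluding Beer"
        base = scale * rng.lognormal(0.0, 0.8, size=N_NUTRIENTS)
        composition = {BASE_VARIANT: base}
        if refinable:
            refined = base.copy()
            refined[FIBRE_INDEX] *= 0.3
            micro = list(MICRONUTRIENT_INDICES)
            refined[micro] *= 0.4
            fortified = refined.copy()
            fortified[micro] = base[micro] * 0.9
            composition["refined_unfortified"] = refined
            composition["refined_fortified"] = fortified
        commodities.append(CommodityDef(
            code=f"C{k:03d}", name=f"commodity-{k:03d}", group=group,
            edible_fraction=float(rng.uniform(0.6, 1.0)),
            refinable=refinable, composition=composition))
    return commodities


def generate_world(cfg: WorldGenConfig) -> World:
    """Generate a valid world; identical seeds give bit-identical output.

    Per commodity, global production lands within +-10% of global
    domestic-supply demand, so every market has both sides. Intermediary
    flags are set exactly where the baseline flows satisfy the re-export
    rule (export above 80% of import with positive import).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_countries, cfg.n_commodities

    gdp_pc = rng.lognormal(cfg.gdp_pc_log_mean, cfg.gdp_pc_log_sd, size=n)
    pop = rng.lognormal(cfg.pop_log_mean, cfg.pop_log_sd, size=n)
    lat = rng.uniform(-55.0, 65.0, size=n)
    lon = rng.uniform(-180.0, 180.0, size=n)
    regions = rng.choice(len(WASTE_REGIONS), size=n)
    # income classes from GDP-per-capita quartiles
    quartiles = np.quantile(gdp_pc, [0.25, 0.5, 0.75])
    income = [INCOME_CLASSES[int(np.searchsorted(quartiles, g))] for g in gdp_pc]
    demo = rng.dirichlet([6, 6, 8, 8, 7, 7, 3, 3], size=n)

    commodities = _make_commodities(cfg, rng)

    # typical diet: population-proportional with commodity-level per-capita scale
    q = (cfg.diet_scale / k) * rng.lognormal(0.0, 0.5, size=k)
    diet = pop[:, None] * q[None, :] * rng.lognormal(0.0, cfg.noise_scale, size=(n, k))

    pct_food = rng.uniform(0.55, 0.9, size=(n, k))
    pct_loss = rng.uniform(0.02, 0.1, size=(n, k))
    ds_demand = diet / pct_food

    # production: around each country's own demand, with a heavy-tailed
    # imbalance factor so roughly half the countries are net importers
    prod = ds_demand * rng.lognormal(0.0, cfg.production_concentration, size=(n, k))
    balance = rng.uniform(0.9, 1.1, size=k)
    prod *= balance * ds_demand.sum(axis=0) / prod.sum(axis=0)

    baseline_import = np.maximum(0.0, ds_demand - prod)
    baseline_export = np.maximum(0.0, prod - ds_demand)

    # intermediaries: add a matched re-export volume on both sides
    n_int = int(round(cfg.intermediary_fraction * n))
    int_countries = rng.choice(n, size=n_int, replace=False)
    for i in int_countries:
        n_flagged = max(1, k // 10)
        for ci in rng.choice(k, size=n_flagged, replace=False):
            reexport = 0.2 * prod[:, ci].mean() * rng.lognormal(0.0, 0.3)
            baseline_import[i, ci] += reexport
            baseline_export[i, ci] += reexport
    is_intermediary = (baseline_import > 0) & (baseline_export > 0.8 * baseline_import)
    baseline_ds = prod + baseline_import - baseline_export

    # distances
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = great_circle_km((lat[i], lon[i]), (lat[j], lon[j]))
            dist[i, j] = dist[j, i] = d

    # gravity-law historic trade, scaled to pooled baseline imports
    gdp = gdp_pc * pop
    with np.errstate(divide="ignore"):
        grav = np.outer(gdp, gdp) / np.maximum(dist, 1.0) ** cfg.gravity_exponent
    np.fill_diagonal(grav, 0.0)
    grav *= rng.lognormal(0.0, cfg.noise_scale, size=(n, n))
    np.fill_diagonal(grav, 0.0)
    total_trade = baseline_import.sum()
    if grav.sum() <= 0:
        raise GenerationError("gravity flows degenerate; check GDP/distance scales")
    flow = grav * (total_trade / grav.sum())     # flow[i, j]: i exports to j
    historic_export = flow
    historic_import = flow.T.copy()

    ids = [f"K{i:03d}" for i in range(n)]
    countries = []
    for i in range(n):
        countries.append(CountryState(
            id=ids[i], name=f"country-{i:03d}",
            lat=float(lat[i]), lon=float(lon[i]),
            region=WASTE_REGIONS[regions[i]], sub_region=WASTE_REGIONS[regions[i]],
            income_class=income[i],
            fortification_profile=INCOME_TO_VARIANT[income[i]],
            population=float(pop[i]), gdp=float(gdp[i]),
            demographics=demo[i],
            baseline_production=prod[i].copy(),
            baseline_import=baseline_import[i].copy(),
            baseline_export=baseline_export[i].copy(),
            baseline_ds=baseline_ds[i].copy(),
            pct_food=pct_food[i].copy(),
            pct_loss=pct_loss[i].copy(),
            is_intermediary=is_intermediary[i].copy(),
            typical_diet=diet[i].copy(),
        ))

    relations = TradeRelations(ids, dist, historic_import, historic_export)
    world = World(
        countries=countries,
        commodities=commodities,
        relations=relations,
        requirements=default_requirement_table(),
        waste=default_waste_table(),
        demographic_groups=DEMOGRAPHIC_GROUPS,
    )
    return world


@dataclass
class Observations:
    """Pseudo-observed trade records in the format the calibration consumes."""

    volumes: dict[tuple[str, str, str, int], float]
    partners: set[tuple[str, str, str, int]]
    years: list[int]
    saturation: float
    cap: float | None = None
    true_weights: PriorityWeights | None = None


def baseline_inputs(world: World, years: list[int]) -> list[YearInputs]:
    """Exogenous inputs holding GDP, population and production at baseline."""
    return [YearInputs.from_baseline(world, y) for y in years]


def generate_observations(world: World, true_weights: PriorityWeights,
                          years: int = 3, saturation: float = 1.0,
                          noise: float = 0.0, seed: int = 0,
                          start_year: int = 2001,
                          cap: float | None = None) -> Observations:
    """Simulate the annual cycle under known weights and perturb the volumes.

    Every recorded volume is multiplied by ``1 + eps`` with ``eps`` uniform
    in ``[-noise, +noise]``; the realized partner set is left untouched, so
    noise affects the volume-match dimension only. The input world is not
    modified.
    """
    year_list = list(range(start_year, start_year + years))
    params = MarketParams(saturation=saturation, cap=cap)
    sim = run_horizon(world.copy(), baseline_inputs(world, year_list), params,
                      true_weights, seed=seed, compute_nutrition=False)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 771_230_941)))
    volumes = {}
    for key in sim.volumes:
        eps = rng.uniform(-noise, noise) if noise > 0 else 0.0
        volumes[key] = sim.volumes[key] * (1.0 + eps)
    return Observations(volumes=volumes, partners=set(sim.partners),
                        years=year_list, saturation=saturation, cap=cap,
                        true_weights=true_weights)
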