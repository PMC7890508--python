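"""Typed world state shared by every stage of the simulator.

The world holds country agents, food commodities with per-variant nutrient
composition, the directed trade-relation matrices (distance, historic and
emergent volumes), a demographically resolved nutrient-requirement table and
a region x food-group household-waste table.

Conventions
-----------
* All commodity flows are tonnes per year.
* Nutrient composition is expressed per tonne of edible food.
* Nutrient requirements and intakes are per person per day; supply is
  converted with a factor of ``population * 365``.
* Distances are great-circle kilometres between country centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0

#: Closed, ordered nutrient list. Energy is kcal; vitamin A and folate are
#: micrograms; vitamin C, calcium, iron, zinc, thiamin, riboflavin, niacin and
#: vitamin B6 are milligrams; protein, fat, fibre and saturated fat are grams.
NUTRIENTS: tuple[str, ...] = (
    "calories",
    "protein",
    "fat",
    "vitamin_c",
    "vitamin_a",
    "folate",
    "calcium",
    "iron",
    "zinc",
    "fibre",
    "thiamin",
    "riboflavin",
    "niacin",
    "vitamin_b6",
    "saturated_fat",
)

NUTRIENT_UNITS: dict[str, str] = {
    "calories": "kcal",
    "protein": "g",
    "fat": "g",
    "vitamin_c": "mg",
    "vitamin_a": "ug",
    "folate": "ug",
    "calcium": "mg",
    "iron": "mg",
    "zinc": "mg",
    "fibre": "g",
    "thiamin": "mg",
    "riboflavin": "mg",
    "niacin": "mg",
    "vitamin_b6": "mg",
    "saturated_fat": "g",
}

N_NUTRIENTS = len(NUTRIENTS)
FAT_INDEX = NUTRIENTS.index("fat")
FIBRE_INDEX = NUTRIENTS.index("fibre")
CALORIES_INDEX = NUTRIENTS.index("calories")

#: Micronutrients restored (partially or fully) by flour fortification.
MICRONUTRIENT_INDICES = tuple(
    NUTRIENTS.index(n)
    for n in ("vitamin_c", "vitamin_a", "folate", "calcium", "iron", "zinc",
              "thiamin", "riboflavin", "niacin", "vitamin_b6")
)

#: Fortification variants of a refinable commodity.
VARIANTS: tuple[str, ...] = ("unrefined", "refined_unfortified", "refined_fortified")
BASE_VARIANT = "unrefined"

#: Income class -> composition variant applied to refinable commodities.
#: High-income countries mostly refine without mandatory fortification;
#: middle-income countries commonly mandate fortification of refined flour;
#: low-income countries largely consume unrefined staples.
INCOME_TO_VARIANT: dict[str, str] = {
    "low": "unrefined",
    "lower_middle": "refined_fortified",
    "upper_middle": "refined_fortified",
    "high": "refined_unfortified",
}

INCOME_CLASSES: tuple[str, ...] = ("low", "lower_middle", "upper_middle", "high")

#: The 21 aggregate food groups used for commodities.
FOOD_GROUPS: tuple[str, ...] = (
    "Cereals - Excluding Beer",
    "Starchy Roots",
    "Sugar Crops",
    "Sugar & Sweeteners",
    "Pulses",
    "Treenuts",
    "Oilcrops",
    "Vegetable Oils",
    "Vegetables",
    "Fruits - Excluding Wine",
    "Spices",
    "Stimulants",
    "Alcoholic Beverages",
    "Meat",
    "Offal",
    "Animal fats",
    "Eggs",
    "Milk - Excluding Butter",
    "Fish; Seafood",
    "Aquatic Products",
    "Other",
)

#: Household-waste regions.
WASTE_REGIONS: tuple[str, ...] = (
    "Europe",
    "North America & Oceania",
    "Industrialized Asia",
    "Sub-Saharan Africa",
    "North Africa, West & Central Asia",
    "South & Southeast Asia",
    "Latin America",
)

WASTE_GROUPS: tuple[str, ...] = (
    "cereals", "roots", "oilseeds", "pulses", "nuts",
    "fruit", "veg", "meat", "offal", "fish", "milk",
)

#: Aggregate food group -> household-waste food group. Dry shelf-stable
#: groups without a direct analogue share the low oilseed rate.
GROUP_TO_WASTE: dict[str, str] = {
    "Cereals - Excluding Beer": "cereals",
    "Starchy Roots": "roots",
    "Sugar Crops": "roots",
    "Sugar & Sweeteners": "oilseeds",
    "Pulses": "pulses",
    "Treenuts": "nuts",
    "Oilcrops": "oilseeds",
    "Vegetable Oils": "oilseeds",
    "Vegetables": "veg",
    "Fruits - Excluding Wine": "fruit",
    "Spices": "oilseeds",
    "Stimulants": "oilseeds",
    "Alcoholic Beverages": "oilseeds",
    "Meat": "meat",
    "Offal": "offal",
    "Animal fats": "meat",
    "Eggs": "milk",
    "Milk - Excluding Butter": "milk",
    "Fish; Seafood": "fish",
    "Aquatic Products": "fish",
    "Other": "oilseeds",
}

#: Default age-sex groups: four age bands x two sexes.
DEMOGRAPHIC_GROUPS: tuple[str, ...] = (
    "f_0_14", "m_0_14",
    "f_15_34", "m_15_34",
    "f_35_64", "m_35_64",
    "f_65p", "m_65p",
)


class SchemaError(ValueError):
    """A table, column or config entry required by the schema is missing."""


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between two (lat, lon) points in degrees.

    Uses a spherical Earth of radius 6371 km. Symmetric, and zero iff the
    points coincide.
    """
    for lat, lon in (a, b):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    la1, lo1 = math.radians(a[0]), math.radians(a[1])
    la2, lo2 = math.radians(b[0]), math.radians(b[1])
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(la1) * math.cos(la2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass
class NutrientProfile:
    """One non-negative amount per nutrient, in the fixed nutrient order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_NUTRIENTS,):
            raise ValueError(f"expected {N_NUTRIENTS} nutrient values, got {self.values.shape}")

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "NutrientProfile":
        return cls(np.array([d.get(n, 0.0) for n in NUTRIENTS], dtype=float))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(NUTRIENTS, self.values.tolist()))

    def __getitem__(self, nutrient: str) -> float:
        return float(self.values[NUTRIENTS.index(nutrient)])


@dataclass
class CommodityDef:
    """A food commodity: group membership, edibility and composition variants."""

    code: str
    name: str
    group: str
    edible_fraction: float
    refinable: bool = False
    #: variant -> nutrient amounts per tonne of edible food
    composition: dict[str, np.ndarray] = field(default_factory=dict)

    def variant_for(self, fortification_profile: str) -> str:
        if not self.refinable:
            return BASE_VARIANT
        return fortification_profile


@dataclass
class CountryState:
    """One country agent.

    Per-commodity arrays are aligned with the world's commodity list.
    ``baseline_*`` flows are year-2000 averages and static; the current-year
    slots are overwritten every simulated year.
    """

    id: str
    name: str
    lat: float
    lon: float
    region: str
    sub_region: str
    income_class: str
    fortification_profile: str
    population: float
    gdp: float
    demographics: np.ndarray          # shares per age-sex group, sums to 1

    baseline_production: np.ndarray   # tonnes per commodity
    baseline_import: np.ndarray
    baseline_export: np.ndarray
    baseline_ds: np.ndarray
    pct_food: np.ndarray              # food share of domestic supply, 0-1
    pct_loss: np.ndarray              # loss share of domestic supply, 0-1
    is_intermediary: np.ndarray       # bool per commodity
    typical_diet: np.ndarray          # tonnes of food per commodity at baseline

    # current-year slots
    production: np.ndarray = None
    import_needed_domestic: np.ndarray = None
    import_needed_intermediary: np.ndarray = None
    export_available: np.ndarray = None
    import_realized: np.ndarray = None
    export_realized: np.ndarray = None
    food_supply: np.ndarray = None

    nutrient_intake: np.ndarray = None        # per person per day
    nutrient_requirement: np.ndarray = None   # per person per day
    fat_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        k = len(self.baseline_production)
        if self.production is None:
            self.production = self.baseline_production.copy()
        for attr in ("import_needed_domestic", "import_needed_intermediary",
                     "export_available", "import_realized", "export_realized", "food_supply"):
            if getattr(self, attr) is None:
                setattr(self, attr, np.zeros(k))
        if self.nutrient_intake is None:
            self.nutrient_intake = np.zeros(N_NUTRIENTS)
        if self.nutrient_requirement is None:
            self.nutrient_requirement = np.zeros(N_NUTRIENTS)

    @property
    def gdp_per_capita(self) -> float:
        return self.gdp / self.population

    def baseline_reexport(self) -> np.ndarray:
        """Baseline re-export volume per commodity (intermediary commodities only)."""
        out = np.minimum(self.baseline_import, self.baseline_export)
        out[~self.is_intermediary] = 0.0
        return out

    def copy(self) -> "CountryState":
        kw = {}
        for f in self.__dataclass_fields__:
            v = getattr(self, f)
            kw[f] = v.copy() if isinstance(v, np.ndarray) else v
        return CountryState(**kw)


@dataclass(frozen=True)
class TradeRelation:
    """A directed country pair with its distance and trade volumes."""

    from_id: str
    to_id: str
    distance: float
    historic_import: float
    historic_export: float
    emergent_import: float = 0.0
    emergent_export: float = 0.0


class TradeRelations:
    """Dense matrix store of all directed trade relations.

    ``historic_export[i, j]`` is the pooled baseline tonnage country ``i``
    exported to ``j``; ``historic_import[i, j]`` the tonnage ``i`` imported
    from ``j`` (so ``historic_import == historic_export.T`` for consistent
    data). Emergent volumes start at zero and accumulate endogenously.
    """

    def __init__(self, ids: list[str], distance: np.ndarray,
                 historic_import: np.ndarray, historic_export: np.ndarray,
                 emergent_import: np.ndarray | None = None,
                 emergent_export: np.ndarray | None = None) -> None:
        n = len(ids)
        self.ids = list(ids)
        self.index = {cid: i for i, cid in enumerate(ids)}
        self.distance = np.asarray(distance, dtype=float)
        self.historic_import = np.asarray(historic_import, dtype=float)
        self.historic_export = np.asarray(historic_export, dtype=float)
        self.emergent_import = np.zeros((n, n)) if emergent_import is None else np.asarray(emergent_import, dtype=float)
        self.emergent_export = np.zeros((n, n)) if emergent_export is None else np.asarray(emergent_export, dtype=float)

    def get(self, from_id: str, to_id: str) -> TradeRelation:
        i, j = self.index[from_id], self.index[to_id]
        return TradeRelation(
            from_id=from_id, to_id=to_id,
            distance=float(self.distance[i, j]),
            historic_import=float(self.historic_import[i, j]),
            historic_export=float(self.historic_export[i, j]),
            emergent_import=float(self.emergent_import[i, j]),
            emergent_export=float(self.emergent_export[i, j]),
        )

    def copy(self) -> "TradeRelations":
        return TradeRelations(
            self.ids, self.distance.copy(),
            self.historic_import.copy(), self.historic_export.copy(),
            self.emergent_import.copy(), self.emergent_export.copy(),
        )


@dataclass(frozen=True)
class PriorityWeights:
    """Weights of the four partner-ranking elements.

    The distance weight is the fixed benchmark (1 in calibration); the other
    three are free and, when produced by the calibration transform, lie in
    [0.05, 20].
    """

    gdp: float
    hist: float
    emerg: float
    dist: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gdp", "hist", "emerg", "dist"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name} must be non-negative")

    def total(self) -> float:
        return self.gdp + self.dist + self.hist + self.emerg


#: Weights calibrated against observed trade (GDP, distance, historic,
#: emergent) shipped as the default configuration.
CALIBRATED_WEIGHTS = PriorityWeights(gdp=1.40, hist=1.40, emerg=0.72, dist=1.0)


@dataclass
class RequirementTable:
    """Per age-sex-group daily nutrient requirements.

    ``values[g, n]`` is the requirement of group ``g`` for nutrient ``n`` per
    person per day. Total fat is banded: the ``fat`` column holds the lower
    bound and ``fat_upper`` the upper bound (too little and too much fat both
    carry health consequences). Energy rows are average dietary energy
    requirements under a physical activity level of 1.75 and BMI 21 kg/m^2.
    """

    groups: tuple[str, ...]
    values: np.ndarray        # (n_groups, N_NUTRIENTS); fat column = lower bound
    fat_upper: np.ndarray     # (n_groups,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.fat_upper = np.asarray(self.fat_upper, dtype=float)

    def copy(self) -> "RequirementTable":
        return RequirementTable(self.groups, self.values.copy(), self.fat_upper.copy())


@dataclass
class WasteTable:
    """Household-waste fractions by region and waste food group."""

    regions: tuple[str, ...]
    groups: tuple[str, ...]
    fractions: np.ndarray     # (n_regions, n_groups), 0-1
    group_map: dict[str, str] = field(default_factory=lambda: dict(GROUP_TO_WASTE))

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)

    def rate(self, region: str, food_group: str) -> float:
        """Waste fraction for a country region and an aggregate food group."""
        if region not in self.regions:
            raise SchemaError(f"unknown waste region: {region!r}")
        wg = self.group_map.get(food_group)
        if wg is None or wg not in self.groups:
            raise SchemaError(f"food group not resolvable in waste table: {food_group!r}")
        return float(self.fractions[self.regions.index(region), self.groups.index(wg)])

    def copy(self) -> "WasteTable":
        return WasteTable(self.regions, self.groups, self.fractions.copy(), dict(self.group_map))


#: Household-waste percentages (share of edible food wasted in the household)
#: by region and food group, after Gustavsson et al.'s global estimates.
#: Columns follow WASTE_GROUPS; rows follow WASTE_REGIONS.
DEFAULT_WASTE_PCT = np.array([
    # cereals roots oilseeds pulses nuts fruit veg meat offal fish milk
    [25, 17, 4, 4, 4, 19, 19, 11, 11, 11, 7],      # Europe
    [27, 30, 4, 4, 4, 28, 28, 11, 11, 33, 15],     # North America & Oceania
    [20, 10, 4, 4, 4, 15, 15, 8, 8, 8, 5],         # Industrialized Asia
    [1, 2, 1, 1, 1, 5, 5, 2, 2, 2, 0.1],           # Sub-Saharan Africa
    [12, 6, 2, 2, 2, 12, 12, 8, 8, 4, 2],          # North Africa, West & Central Asia
    [3, 3, 1, 1, 1, 7, 7, 4, 4, 2, 1],             # South & Southeast Asia
    [10, 4, 2, 2, 2, 10, 10, 6, 6, 4, 4],          # Latin America
], dtype=float)


def default_waste_table() -> WasteTable:
    return WasteTable(WASTE_REGIONS, WASTE_GROUPS, DEFAULT_WASTE_PCT / 100.0)


def default_requirement_table() -> RequirementTable:
    """Synthetic default daily requirements per age-sex group.

    Energy rows approximate ADERs (PAL 1.75, BMI 21); micronutrient rows are
    plausible adult/child recommended intakes. The table is a documented
    synthetic stand-in for the WHO reference values, which users can replace
    via ``requirements.csv``.
    """
    groups = DEMOGRAPHIC_GROUPS
    # per group: calories, protein, fat(lower), vitC, vitA, folate, calcium,
    # iron, zinc, fibre, thiamin, riboflavin, niacin, B6, sat fat
    rows = {
        "f_0_14":  [1750, 34, 29.2, 40, 450, 250, 1000, 9, 6, 18, 0.9, 0.9, 11, 1.0, 5],
        "m_0_14":  [1850, 34, 30.8, 40, 450, 250, 1000, 9, 6, 19, 0.9, 0.9, 12, 1.0, 5],
        "f_15_34": [2300, 52, 38.3, 45, 500, 400, 1000, 20, 8, 25, 1.1, 1.1, 14, 1.3, 6],
        "m_15_34": [2900, 62, 48.3, 45, 600, 400, 1000, 9, 12, 30, 1.2, 1.3, 16, 1.3, 6],
        "f_35_64": [2200, 50, 36.7, 45, 500, 400, 1000, 18, 8, 25, 1.1, 1.1, 14, 1.3, 6],
        "m_35_64": [2700, 60, 45.0, 45, 600, 400, 1000, 9, 12, 30, 1.2, 1.3, 16, 1.3, 6],
        "f_65p":   [1900, 46, 31.7, 45, 500, 400, 1200, 8, 8, 22, 1.1, 1.1, 14, 1.5, 6],
        "m_65p":   [2300, 56, 38.3, 45, 600, 400, 1200, 8, 11, 26, 1.2, 1.3, 16, 1.7, 6],
    }
    values = np.array([rows[g] for g in groups], dtype=float)
    # fat band: lower = 15% of energy, upper = 30% of energy, in grams (9 kcal/g)
    energy = values[:, CALORIES_INDEX]
    values[:, FAT_INDEX] = 0.15 * energy / 9.0
    fat_upper = 0.30 * energy / 9.0
    return RequirementTable(groups, values, fat_upper)


@dataclass
class World:
    """Full simulation state."""

    countries: list[CountryState]
    commodities: list[CommodityDef]
    relations: TradeRelations
    requirements: RequirementTable
    waste: WasteTable
    demographic_groups: tuple[str, ...] = DEMOGRAPHIC_GROUPS
    #: global production per commodity and total population in the baseline
    #: year, the denominators of the annual diet-rescaling ratio
    baseline_global_production: np.ndarray = None
    baseline_population: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_global_production is None:
            self.baseline_global_production = np.sum(
                [c.baseline_production for c in self.countries], axis=0)
        if not self.baseline_population:
            self.baseline_population = float(sum(c.population for c in self.countries))

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    @property
    def n_commodities(self) -> int:
        return len(self.commodities)

    @property
    def country_ids(self) -> list[str]:
        return [c.id for c in self.countries]

    def country(self, cid: str) -> CountryState:
        for c in self.countries:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def copy(self) -> "World":
        return World(
            countries=[c.copy() for c in self.countries],
            commodities=[
                CommodityDef(m.code, m.name, m.group, m.edible_fraction, m.refinable,
                             {v: a.copy() for v, a in m.composition.items()})
                for m in self.commodities
            ],
            relations=self.relations.copy(),
            requirements=self.requirements.copy(),
            waste=self.waste.copy(),
            demographic_groups=self.demographic_groups,
            baseline_global_production=self.baseline_global_production.copy(),
            baseline_population=self.baseline_population,
        )


def _check_composition(world: World, out: list[str]) -> None:
    for com in world.commodities:
        if not (0.0 <= com.edible_fraction <= 1.0):
            out.append(f"commodity={com.code} field=edible_fraction: "
                       f"value {com.edible_fraction} outside [0, 1]")
        if BASE_VARIANT not in com.composition:
            out.append(f"commodity={com.code} field=composition: missing base variant")
            continue
        for variant, vals in com.composition.items():
            if np.any(np.asarray(vals) < 0):
                out.append(f"commodity={com.code} field=composition[{variant}]: negative amount")
        if com.refinable:
            missing = [v for v in VARIANTS if v not in com.composition]
            if missing:
                out.append(f"commodity={com.code} field=composition: refinable commodity "
                           f"missing variants {missing}")
                continue
            unref = com.composition["unrefined"]
            ru = com.composition["refined_unfortified"]
            rf = com.composition["refined_fortified"]
            if not unref[FIBRE_INDEX] > ru[FIBRE_INDEX] or not unref[FIBRE_INDEX] > rf[FIBRE_INDEX]:
                out.append(f"commodity={com.code} field=composition: refined variants must "
                           f"carry less fibre than unrefined")
            micro = list(MICRONUTRIENT_INDICES)
            if np.any(rf[micro] < ru[micro]):
                out.append(f"commodity={com.code} field=composition: fortified variant has "
                           f"lower micronutrients than unfortified")


def validate_world(world: World, tol: float = 1e-9) -> list[str]:
    """Check every schema invariant; return a list of human-readable violations.

    An empty list means the world is valid. The function is side-effect-free
    and idempotent.
    """
    out: list[str] = []
    k = world.n_commodities
    _check_composition(world, out)

    if world.requirements.groups != world.demographic_groups:
        out.append("field=requirements: group list does not match world demographic groups")
    if np.any(world.requirements.values <= 0):
        out.append("field=requirements: non-positive requirement")
    if np.any(world.requirements.fat_upper <= world.requirements.values[:, FAT_INDEX]):
        out.append("field=requirements: fat band upper bound not above lower bound")
    if np.any(world.waste.fractions < 0) or np.any(world.waste.fractions > 1):
        out.append("field=waste: fraction outside [0, 1]")

    for c in world.countries:
        loc = f"country={c.id}"
        if not c.population > 0:
            out.append(f"{loc} field=population: must be positive")
        if abs(float(np.sum(c.demographics)) - 1.0) > tol:
            out.append(f"{loc} field=demographics: shares sum to "
                       f"{float(np.sum(c.demographics)):.6f}, expected 1")
        if c.region not in world.waste.regions:
            out.append(f"{loc} field=region: {c.region!r} not in waste table")
        if c.income_class not in INCOME_CLASSES:
            out.append(f"{loc} field=income_class: unknown {c.income_class!r}")
        for name in ("baseline_production", "baseline_import", "baseline_export",
                     "typical_diet", "production", "import_realized",
                     "export_realized", "food_supply",
                     "import_needed_domestic", "import_needed_intermediary",
                     "export_available"):
            arr = getattr(c, name)
            if len(arr) != k:
                out.append(f"{loc} field={name}: length {len(arr)} != {k} commodities")
                continue
            bad = np.where(np.asarray(arr) < 0)[0]
            for ci in bad:
                out.append(f"{loc} commodity={world.commodities[ci].code} "
                           f"field={name}: negative value {arr[ci]}")
        over = np.where(c.pct_food + c.pct_loss > 1.0 + tol)[0]
        for ci in over:
            out.append(f"{loc} commodity={world.commodities[ci].code} "
                       f"field=pct_food+pct_loss: {c.pct_food[ci] + c.pct_loss[ci]:.4f} > 1")

    rel = world.relations
    n = world.n_countries
    if rel.distance.shape != (n, n):
        out.append(f"field=relations.distance: shape {rel.distance.shape} != ({n}, {n})")
    else:
        if np.any(np.diag(rel.distance) != 0):
            out.append("field=relations.distance: non-zero diagonal")
        if np.any(rel.distance < 0):
            out.append("field=relations.distance: negative distance")
        if not np.allclose(rel.distance, rel.distance.T, rtol=0, atol=1e-6):
            out.append("field=relations.distance: not symmetric")
    for name in ("historic_import", "historic_export", "emergent_import", "emergent_export"):
        m = getattr(rel, name)
        if np.any(m < 0):
            out.append(f"field=relations.{name}: negative volume")
    if not np.allclose(rel.historic_import, rel.historic_export.T, rtol=1e-9, atol=1e-6):
        out.append("field=relations: historic_import is not the transpose of historic_export")
    return out
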