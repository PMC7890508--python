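"""Delimited-text readers and writers for worlds, runs and reports.

A world serializes to a directory of UTF-8 comma-separated tables:
``countries.csv``, ``commodities.csv``, ``production.csv``,
``typical_diet.csv``, ``relations.csv``, ``composition.csv``,
``requirements.csv`` and ``waste.csv``. Writers are deterministic (sorted
rows, repr-exact floats) so the same state always produces byte-identical
files, and ``load_world(write_world(w))`` round-trips exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cycle import YearResult
from .engine import Transaction
from .world import (
    NUTRIENTS,
    CommodityDef,
    CountryState,
    SchemaError,
    TradeRelations,
    World,
    validate_world,
)

log = logging.getLogger(__name__)

WORLD_TABLES = {
    "countries.csv", "commodities.csv", "production.csv", "typical_diet.csv",
    "relations.csv", "composition.csv", "requirements.csv", "waste.csv",
}


def _read(path: Path, name: str, required: list[str]) -> pd.DataFrame:
    f = path / name
    if not f.exists():
        raise SchemaError(f"missing table {name}")
    df = pd.read_csv(f, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"table {name} missing columns {missing}")
    extra = [c for c in df.columns if c not in required and not c.startswith("demo_")
             and c not in NUTRIENTS and c != "fat_upper"]
    if extra:
        log.warning("table %s carries unrecognized columns %s (ignored)", name, extra)
    return df


def write_world(world: World, out_dir: str | Path) -> Path:
    """Write the world as the delimited-table directory format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = world.demographic_groups

    rows = []
    for c in world.countries:
        row = {
            "id": c.id, "name": c.name, "lat": c.lat, "lon": c.lon,
            "region": c.region, "sub_region": c.sub_region,
            "income_class": c.income_class,
            "fortification_profile": c.fortification_profile,
            "population": c.population, "gdp": c.gdp,
        }
        row.update({f"demo_{g}": c.demographics[gi] for gi, g in enumerate(groups)})
        rows.append(row)
    pd.DataFrame(rows).sort_values("id").to_csv(out / "countries.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [{"code": m.code, "name": m.name, "group": m.group,
          "edible_fraction": m.edible_fraction, "refinable": m.refinable}
         for m in world.commodities]
    ).sort_values("code").to_csv(out / "commodities.csv", index=False, float_format="%.17g")

    prod_rows, diet_rows, comp_rows = [], [], []
    for c in world.countries:
        for ci, m in enumerate(world.commodities):
            prod_rows.append({
                "country": c.id, "commodity": m.code,
                "production": c.baseline_production[ci],
                "import": c.baseline_import[ci],
                "export": c.baseline_export[ci],
                "domestic_supply": c.baseline_ds[ci],
                "pct_food": c.pct_food[ci], "pct_loss": c.pct_loss[ci],
                "is_intermediary": bool(c.is_intermediary[ci]),
            })
            diet_rows.append({"country": c.id, "commodity": m.code,
                              "tonnes": c.typical_diet[ci]})
    pd.DataFrame(prod_rows).sort_values(["country", "commodity"]).to_csv(
        out / "production.csv", index=False, float_format="%.17g")
    pd.DataFrame(diet_rows).sort_values(["country", "commodity"]).to_csv(
        out / "typical_diet.csv", index=False, float_format="%.17g")

    for m in world.commodities:
        for variant in sorted(m.composition):
            row = {"commodity": m.code, "variant": variant}
            row.update({n: m.composition[variant][ni] for ni, n in enumerate(NUTRIENTS)})
            comp_rows.append(row)
    pd.DataFrame(comp_rows).sort_values(["commodity", "variant"]).to_csv(
        out / "composition.csv", index=False, float_format="%.17g")

    rel = world.relations
    rel_rows = []
    for i, a in enumerate(rel.ids):
        for j, b in enumerate(rel.ids):
            if i == j:
                continue
            rel_rows.append({
                "from": a, "to": b, "distance_km": rel.distance[i, j],
                "historic_import": rel.historic_import[i, j],
                "historic_export": rel.historic_export[i, j],
                "emergent_import": rel.emergent_import[i, j],
                "emergent_export": rel.emergent_export[i, j],
            })
    pd.DataFrame(rel_rows).sort_values(["from", "to"]).to_csv(
        out / "relations.csv", index=False, float_format="%.17g")

    req = world.requirements
    req_rows = []
    for gi, g in enumerate(req.groups):
        row = {"group": g}
        row.update({n: req.values[gi, ni] for ni, n in enumerate(NUTRIENTS)})
        row["fat_upper"] = req.fat_upper[gi]
        req_rows.append(row)
    pd.DataFrame(req_rows).to_csv(out / "requirements.csv", index=False, float_format="%.17g")

    w = world.waste
    waste_rows = [{"region": r, "waste_group": g,
                   "fraction": w.fractions[ri, gi]}
                  for ri, r in enumerate(w.regions) for gi, g in enumerate(w.groups)]
    pd.DataFrame(waste_rows).to_csv(out / "waste.csv", index=False, float_format="%.17g")
    return out


def load_world(in_dir: str | Path) -> World:
    """Load a world directory; fails with the violation list if invalid."""
    path = Path(in_dir)
    from .world import (
        DEMOGRAPHIC_GROUPS,
        RequirementTable,
        WasteTable,
    )

    countries_df = _read(path, "countries.csv", ["id", "name", "lat", "lon", "region",
                                                 "sub_region", "income_class",
                                                 "fortification_profile", "population", "gdp"])
    com_df = _read(path, "commodities.csv", ["code", "name", "group",
                                             "edible_fraction", "refinable"])
    prod_df = _read(path, "production.csv", ["country", "commodity", "production",
                                             "import", "export", "domestic_supply",
                                             "pct_food", "pct_loss", "is_intermediary"])
    diet_df = _read(path, "typical_diet.csv", ["country", "commodity", "tonnes"])
    rel_df = _read(path, "relations.csv", ["from", "to", "distance_km",
                                           "historic_import", "historic_export",
                                           "emergent_import", "emergent_export"])
    comp_df = _read(path, "composition.csv", ["commodity", "variant", *NUTRIENTS])
    req_df = _read(path, "requirements.csv", ["group", *NUTRIENTS, "fat_upper"])
    waste_df = _read(path, "waste.csv", ["region", "waste_group", "fraction"])

    codes = com_df.sort_values("code")["code"].tolist()
    code_index = {c: i for i, c in enumerate(codes)}
    commodities = []
    comp_by_code: dict[str, dict[str, np.ndarray]] = {}
    for _, r in comp_df.iterrows():
        comp_by_code.setdefault(r["commodity"], {})[r["variant"]] = (
            r[list(NUTRIENTS)].to_numpy(dtype=float))
    for _, r in com_df.sort_values("code").iterrows():
        commodities.append(CommodityDef(
            code=r["code"], name=r["name"], group=r["group"],
            edible_fraction=float(r["edible_fraction"]),
            refinable=bool(r["refinable"]),
            composition=comp_by_code.get(r["code"], {})))

    groups = tuple(g[len("demo_"):] for g in countries_df.columns if g.startswith("demo_"))
    if not groups:
        groups = DEMOGRAPHIC_GROUPS

    k = len(codes)
    prod_df = prod_df.set_index(["country", "commodity"]).sort_index()
    diet_df = diet_df.set_index(["country", "commodity"]).sort_index()
    countries = []
    for _, r in countries_df.sort_values("id").iterrows():
        cid = r["id"]
        sub = prod_df.loc[cid]
        if len(sub) != k:
            raise SchemaError(f"production.csv covers {len(sub)} commodities for "
                              f"{cid}, expected {k}")
        sub = sub.reindex(codes)
        dsub = diet_df.loc[cid].reindex(codes)
        countries.append(CountryState(
            id=cid, name=r["name"], lat=float(r["lat"]), lon=float(r["lon"]),
            region=r["region"], sub_region=r["sub_region"],
            income_class=r["income_class"],
            fortification_profile=r["fortification_profile"],
            population=float(r["population"]), gdp=float(r["gdp"]),
            demographics=np.array([r[f"demo_{g}"] for g in groups], dtype=float),
            baseline_production=sub["production"].to_numpy(dtype=float),
            baseline_import=sub["import"].to_numpy(dtype=float),
            baseline_export=sub["export"].to_numpy(dtype=float),
            baseline_ds=sub["domestic_supply"].to_numpy(dtype=float),
            pct_food=sub["pct_food"].to_numpy(dtype=float),
            pct_loss=sub["pct_loss"].to_numpy(dtype=float),
            is_intermediary=sub["is_intermediary"].to_numpy(dtype=bool),
            typical_diet=dsub["tonnes"].to_numpy(dtype=float),
        ))

    ids = [c.id for c in countries]
    index = {cid: i for i, cid in enumerate(ids)}
    n = len(ids)
    dist = np.zeros((n, n))
    hist_imp = np.zeros((n, n))
    hist_exp = np.zeros((n, n))
    em_imp = np.zeros((n, n))
    em_exp = np.zeros((n, n))
    for _, r in rel_df.iterrows():
        i, j = index[r["from"]], index[r["to"]]
        dist[i, j] = r["distance_km"]
        hist_imp[i, j] = r["historic_import"]
        hist_exp[i, j] = r["historic_export"]
        em_imp[i, j] = r["emergent_import"]
        em_exp[i, j] = r["emergent_export"]
    relations = TradeRelations(ids, dist, hist_imp, hist_exp, em_imp, em_exp)

    req_groups = tuple(req_df["group"].tolist())
    req = RequirementTable(
        groups=req_groups,
        values=req_df[list(NUTRIENTS)].to_numpy(dtype=float),
        fat_upper=req_df["fat_upper"].to_numpy(dtype=float))

    regions = tuple(dict.fromkeys(waste_df["region"]))
    wgroups = tuple(dict.fromkeys(waste_df["waste_group"]))
    fractions = np.zeros((len(regions), len(wgroups)))
    for _, r in waste_df.iterrows():
        fractions[regions.index(r["region"]), wgroups.index(r["waste_group"])] = r["fraction"]
    waste = WasteTable(regions, wgroups, fractions)

    world = World(countries=countries, commodities=commodities, relations=relations,
                  requirements=req, waste=waste, demographic_groups=groups)
    violations = validate_world(world)
    if violations:
        raise SchemaError("invalid world:\n" + "\n".join(violations))
    return world


def write_transactions(transactions: list[Transaction], path: str | Path) -> None:
    df = pd.DataFrame(transactions, columns=["year", "commodity", "importer",
                                             "exporter", "amount", "round"])
    df.to_csv(path, index=False)


def intake_table(results: list[YearResult]) -> pd.DataFrame:
    """Per-country per-nutrient intake table (wide layout), last year of run."""
    if not results:
        raise ValueError("no simulated years")
    last = results[-1]
    df = last.sufficiency_frame()
    wide = df.pivot(index="country", columns="nutrient", values="intake")
    return wide[list(df["nutrient"].unique())].reset_index()


def status_table(results_by_scenario: dict[str, list[YearResult]]) -> pd.DataFrame:
    """Sufficiency status per country x nutrient, one column per scenario."""
    frames = {}
    for label, results in results_by_scenario.items():
        df = results[-1].sufficiency_frame()
        frames[label] = df.set_index(["country", "nutrient"])["status"]
    return pd.DataFrame(frames).reset_index()


def report(results_by_scenario: dict[str, list[YearResult]],
           out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Emit the summary tables: per-scenario intakes and the status matrix."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {}
    for label, results in results_by_scenario.items():
        t = intake_table(results)
        t.to_csv(out / f"intake_{label}.csv", index=False)
        tables[f"intake_{label}"] = t
    st = status_table(results_by_scenario)
    st.to_csv(out / "sufficiency_status.csv", index=False, float_format="%.17g")
    tables["status"] = st
    return tables
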