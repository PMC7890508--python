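"""Round-based trade market: positions, priority ranking, offer matching.

Each commodity trades in its own market within a year. Importers post buying
offers to their top-ranked exporter; exporters accept offers in their own
priority order until their stock is gone; unmet importers retry next round.
A per-round transaction cap stops large countries from flooding the market,
and a saturation parameter s stops the market once s x potential volume has
been realized, where potential = min(total demand, total supply) at market
open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .world import CountryState, PriorityWeights, TradeRelation, TradeRelations, World

log = logging.getLogger(__name__)

Role = Literal["importer", "exporter"]

#: tonnes below which a position or offer is treated as exhausted
EPS = 1e-9


class Transaction(NamedTuple):
    """One realized commodity flow."""

    year: int
    commodity: str
    importer_id: str
    exporter_id: str
    amount: float
    round: int


@dataclass
class MarketParams:
    """Market controls shared by all commodities in a year.

    ``cap`` is the maximum tonnage per transaction per round; ``None`` means
    one tenth of the market's potential volume, which yields round counts in
    the single-digit-to-low-tens range on balanced markets.
    """

    saturation: float = 1.0
    cap: float | None = None
    max_rounds: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.saturation <= 1.0):
            raise ValueError("saturation must lie in [0, 1]")
        if self.cap is not None and not self.cap > 0:
            raise ValueError("per-round cap must be positive")


def determine_positions(country: CountryState, commodity_index: int,
                        diet_target: float, global_ratio: float = 1.0,
                        ) -> tuple[float, float, float]:
    """Trade position of one country for one commodity.

    The diet target (tonnes of food) is converted to its domestic-supply
    equivalent through the baseline food share; the gap to current production
    gives the import need or export surplus. Intermediary countries
    additionally demand their baseline re-export volume, rescaled by the
    global supply ratio like the diet.

    Returns ``(import_needed_domestic, import_needed_intermediary,
    export_available)``; at most one of the first and last is positive.
    """
    prod = float(country.production[commodity_index])
    if np.isnan(prod):
        raise RuntimeError(f"production unset for {country.id}")
    pf = float(country.pct_food[commodity_index])
    if diet_target > EPS and pf <= 0:
        raise ValueError(
            f"country {country.id} has zero food share but positive diet target "
            f"for commodity index {commodity_index}")
    ds_equiv = diet_target / pf if pf > 0 else 0.0
    need_dom = max(0.0, ds_equiv - prod)
    surplus = max(0.0, prod - ds_equiv)
    need_int = 0.0
    if country.is_intermediary[commodity_index]:
        base = min(country.baseline_import[commodity_index],
                   country.baseline_export[commodity_index])
        need_int = base * global_ratio
    return need_dom, need_int, surplus


def _minmax(values: np.ndarray) -> np.ndarray:
    """Min-max normalize onto [0, 1]; a degenerate spread maps to all ones."""
    lo = values.min()
    hi = values.max()
    if hi - lo <= 0:
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def score_candidates(actor_index: int, candidate_indices: np.ndarray,
                     role: Role, weights: PriorityWeights,
                     world: World) -> np.ndarray:
    """Priority scores the actor assigns to each candidate partner.

    Each element is min-max normalized over the candidate set: GDP per
    capita, role-appropriate historic volume and emergent volume enter
    directly, distance enters as ``1 - normalized distance``. The score is
    the weighted average of the four elements and lies in [0, 1].
    """
    rel = world.relations
    cand = np.asarray(candidate_indices)
    gdp_pc = np.array([world.countries[j].gdp_per_capita for j in cand])
    dist = rel.distance[actor_index, cand]
    if role == "importer":
        hist = rel.historic_import[actor_index, cand]
        emerg = rel.emergent_import[actor_index, cand]
    else:
        hist = rel.historic_export[actor_index, cand]
        emerg = rel.emergent_export[actor_index, cand]
    g = _minmax(gdp_pc)
    d = 1.0 - _minmax(dist) if dist.max() > dist.min() else np.ones_like(dist)
    h = _minmax(hist)
    e = _minmax(emerg)
    total = weights.total()
    return (weights.gdp * g + weights.dist * d + weights.hist * h + weights.emerg * e) / total


def priority_score(relation: TradeRelation, partner: CountryState, role: Role,
                   weights: PriorityWeights,
                   norms: dict[str, tuple[float, float]]) -> float:
    """Score a single candidate given precomputed per-element normalizers.

    ``norms`` maps each element (``gdp``, ``dist``, ``hist``, ``emerg``) to
    the (min, max) over the candidate set of the current ranking event. A
    degenerate normalizer (min == max) maps the element to 1.
    """
    def norm(x: float, key: str) -> float:
        lo, hi = norms[key]
        if hi - lo <= 0:
            return 1.0
        return (x - lo) / (hi - lo)

    g = norm(partner.gdp_per_capita, "gdp")
    lo, hi = norms["dist"]
    d = 1.0 if hi - lo <= 0 else 1.0 - (relation.distance - lo) / (hi - lo)
    if role == "importer":
        h = norm(relation.historic_import, "hist")
        e = norm(relation.emergent_import, "emerg")
    else:
        h = norm(relation.historic_export, "hist")
        e = norm(relation.emergent_export, "emerg")
    return (weights.gdp * g + weights.dist * d + weights.hist * h + weights.emerg * e) / weights.total()


def rank_partners(actor_index: int, candidate_indices: Sequence[int], role: Role,
                  weights: PriorityWeights, world: World,
                  rng: np.random.Generator) -> list[int]:
    """Candidates ordered by descending priority; exact ties broken by a
    seeded uniform draw (one draw per candidate, in candidate order)."""
    cand = np.asarray(list(candidate_indices))
    if cand.size == 0:
        return []
    scores = score_candidates(actor_index, cand, role, weights, world)
    tiebreak = rng.random(cand.size)
    order = np.lexsort((tiebreak, -scores))
    return [int(c) for c in cand[order]]


def run_commodity_market(world: World, commodity_index: int, params: MarketParams,
                         weights: PriorityWeights, rng: np.random.Generator,
                         year: int = 0) -> list[Transaction]:
    """Run the round-based offer/matching market for one commodity.

    Two-phase rounds: all importers with remaining demand post an offer of
    ``min(remaining demand, cap)`` to their top-ranked exporter with stock;
    then each offered exporter accepts offers in its own priority order until
    its stock runs out. Tonnes an intermediary buys against its re-export
    demand re-enter the market as its export stock in the next round. At
    saturation 1 the market trades until no feasible offer remains; below 1
    it closes once cumulative realized volume reaches
    ``saturation x potential``, with ``potential = min(total demand, total
    supply)`` at market open (the last transaction is truncated to land on
    the target exactly). ``max_rounds`` is a safety bound.

    Realized amounts are accumulated onto each country's ``import_realized``
    and ``export_realized`` slots; the returned transactions carry the same
    totals.
    """
    ci = commodity_index
    code = world.commodities[ci].code
    n = world.n_countries
    dem_dom = np.array([c.import_needed_domestic[ci] for c in world.countries])
    dem_int = np.array([c.import_needed_intermediary[ci] for c in world.countries])
    supply = np.array([c.export_available[ci] for c in world.countries])

    total_demand = float(dem_dom.sum() + dem_int.sum())
    total_supply = float(supply.sum())
    potential = min(total_demand, total_supply)
    if potential <= EPS:
        return []
    cap = params.cap if params.cap is not None else potential / 10.0
    # At full saturation the market trades to exhaustion (until no feasible
    # importer/exporter pair remains); below it, the round loop is truncated
    # exactly at s x potential.
    target = params.saturation * potential if params.saturation < 1.0 else np.inf

    transactions: list[Transaction] = []
    realized = 0.0
    closed = realized >= target - EPS

    for rnd in range(1, params.max_rounds + 1):
        if closed:
            break
        importers = [i for i in range(n) if dem_dom[i] + dem_int[i] > EPS]
        if not importers or supply.max() <= EPS:
            break
        # offer phase: each importer targets its top-ranked exporter
        offers: dict[int, list[tuple[int, float]]] = {}
        for i in importers:
            cands = [j for j in range(n) if j != i and supply[j] > EPS]
            if not cands:
                continue
            ranked = rank_partners(i, cands, "importer", weights, world, rng)
            top = ranked[0]
            amount = min(dem_dom[i] + dem_int[i], cap)
            offers.setdefault(top, []).append((i, amount))
        if not offers:
            break
        # acceptance phase: exporters serve offers in their own priority order
        restock = np.zeros(n)
        accepted_any = False
        for j in sorted(offers):
            pending = offers[j]
            if len(pending) > 1:
                idx = [i for i, _ in pending]
                ranked = rank_partners(j, idx, "exporter", weights, world, rng)
                by_importer = dict(pending)
                pending = [(i, by_importer[i]) for i in ranked]
            for i, amount in pending:
                if closed:
                    break
                amt = min(amount, supply[j], target - realized)
                if amt <= EPS:
                    if target - realized <= EPS:
                        closed = True
                    continue
                transactions.append(Transaction(year, code, world.countries[i].id,
                                                world.countries[j].id, amt, rnd))
                accepted_any = True
                supply[j] -= amt
                realized += amt
                take_dom = min(amt, dem_dom[i])
                dem_dom[i] -= take_dom
                take_int = amt - take_dom
                dem_int[i] = max(0.0, dem_int[i] - take_int)
                restock[i] += take_int
                world.countries[i].import_realized[ci] += amt
                world.countries[j].export_realized[ci] += amt
                if realized >= target - EPS:
                    closed = True
        supply += restock
        log.debug("market %s round %d: offers=%d accepted=%.3f t cumulative=%.3f t",
                  code, rnd, sum(len(v) for v in offers.values()),
                  sum(t.amount for t in transactions if t.round == rnd), realized)
        if not accepted_any:
            break
    else:
        if not closed and (dem_dom + dem_int).max() > EPS and supply.max() > EPS:
            log.warning("market %s hit max_rounds=%d with feasible offers remaining",
                        code, params.max_rounds)
    return transactions


def update_emergent(relations: TradeRelations, transactions: Sequence[Transaction]) -> TradeRelations:
    """Accumulate realized trade onto the emergent-relationship matrices.

    For each transaction, the exporter's emergent export volume toward the
    importer and the importer's emergent import volume toward the exporter
    each grow by the transaction amount; nothing else changes. Returns the
    (mutated) relations for convenience.
    """
    for t in transactions:
        i = relations.index[t.importer_id]
        j = relations.index[t.exporter_id]
        relations.emergent_export[j, i] += t.amount
        relations.emergent_import[i, j] += t.amount
    return relations
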