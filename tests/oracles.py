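"""Independent reference implementations used to cross-check the package.

These are deliberately plain, dictionary-and-loop re-implementations of the
documented procedures (partner scoring, the round-based market, Pareto
domination), kept free of any imports from the package's engine internals so
they constitute a second, independent route to the same answers.
"""

from __future__ import annotations

import math


def haversine_reference(lat1, lon1, lat2, lon2, radius=6371.0):
    """Great-circle distance via the spherical law of cosines."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    cosc = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius * math.acos(max(-1.0, min(1.0, cosc)))


def score_oracle(elements: dict[str, float], norms: dict[str, tuple[float, float]],
                 weights: dict[str, float]) -> float:
    """Weighted average of min-max normalized ranking elements.

    ``elements`` holds the raw gdp/dist/hist/emerg values of one candidate;
    ``norms`` the (min, max) per element over the candidate set. Distance is
    inverted. Degenerate normalizers map to 1.
    """
    parts = {}
    for key in ("gdp", "dist", "hist", "emerg"):
        lo, hi = norms[key]
        if hi - lo <= 0:
            z = 1.0
        else:
            z = (elements[key] - lo) / (hi - lo)
            if key == "dist":
                z = 1.0 - z
        parts[key] = z
    total = sum(weights.values())
    return sum(weights[k] * parts[k] for k in parts) / total


def rank_oracle(candidates: list[int], raw: dict[int, dict[str, float]],
                weights: dict[str, float], tiebreak: dict[int, float]) -> list[int]:
    """Score-then-sort: descending score, ties by the supplied uniform draw."""
    norms = {}
    for key in ("gdp", "dist", "hist", "emerg"):
        vals = [raw[c][key] for c in candidates]
        norms[key] = (min(vals), max(vals))
    scores = {c: score_oracle(raw[c], norms, weights) for c in candidates}
    return sorted(candidates, key=lambda c: (-scores[c], tiebreak[c]))


def market_oracle(world, commodity_index, saturation, cap, weights, rng, year=0):
    """Straightforward implementation of the round-based trade procedure.

    Mirrors the documented market semantics: two-phase rounds, per-round
    transaction cap, intermediary restocking, exact truncation at
    saturation x potential, seeded tie-breaks consumed one uniform per
    candidate per ranking event. Returns a list of
    (year, commodity, importer, exporter, amount, round) tuples. Does not
    touch the world's realized slots.
    """
    ci = commodity_index
    eps = 1e-9
    countries = world.countries
    n = len(countries)
    ids = [c.id for c in countries]
    code = world.commodities[ci].code
    rel = world.relations

    dem_dom = {i: float(countries[i].import_needed_domestic[ci]) for i in range(n)}
    dem_int = {i: float(countries[i].import_needed_intermediary[ci]) for i in range(n)}
    supply = {i: float(countries[i].export_available[ci]) for i in range(n)}

    total_d = sum(dem_dom.values()) + sum(dem_int.values())
    total_s = sum(supply.values())
    potential = min(total_d, total_s)
    if potential <= eps:
        return []
    if cap is None:
        cap = potential / 10.0
    target = saturation * potential if saturation < 1.0 else math.inf

    def raw_elements(actor, cands, role):
        out = {}
        for c in cands:
            gdp_pc = countries[c].gdp / countries[c].population
            dist = float(rel.distance[actor, c])
            if role == "importer":
                hist = float(rel.historic_import[actor, c])
                emerg = float(rel.emergent_import[actor, c])
            else:
                hist = float(rel.historic_export[actor, c])
                emerg = float(rel.emergent_export[actor, c])
            out[c] = {"gdp": gdp_pc, "dist": dist, "hist": hist, "emerg": emerg}
        return out

    def rank(actor, cands, role, weights):
        draws = rng.random(len(cands))
        tb = {c: float(draws[k]) for k, c in enumerate(cands)}
        return rank_oracle(cands, raw_elements(actor, cands, role),
                           {"gdp": weights.gdp, "dist": weights.dist,
                            "hist": weights.hist, "emerg": weights.emerg}, tb)

    transactions = []
    realized = 0.0
    closed = realized >= target - eps

    for rnd in range(1, 10_001):
        if closed:
            break
        importers = [i for i in range(n) if dem_dom[i] + dem_int[i] > eps]
        if not importers or max(supply.values()) <= eps:
            break
        offers: dict[int, list[tuple[int, float]]] = {}
        for i in importers:
            cands = [j for j in range(n) if j != i and supply[j] > eps]
            if not cands:
                continue
            ranked = rank(i, cands, "importer", weights)
            offers.setdefault(ranked[0], []).append((i, min(dem_dom[i] + dem_int[i], cap)))
        if not offers:
            break
        restock = {i: 0.0 for i in range(n)}
        accepted_any = False
        for j in sorted(offers):
            pending = offers[j]
            if len(pending) > 1:
                amounts = dict(pending)
                order = rank(j, [i for i, _ in pending], "exporter", weights)
                pending = [(i, amounts[i]) for i in order]
            for i, amount in pending:
                if closed:
                    break
                amt = min(amount, supply[j], target - realized)
                if amt <= eps:
                    if target - realized <= eps:
                        closed = True
                    continue
                transactions.append((year, code, ids[i], ids[j], amt, rnd))
                accepted_any = True
                supply[j] -= amt
                realized += amt
                take_dom = min(amt, dem_dom[i])
                dem_dom[i] -= take_dom
                take_int = amt - take_dom
                dem_int[i] = max(0.0, dem_int[i] - take_int)
                restock[i] += take_int
                if realized >= target - eps:
                    closed = True
        for i in range(n):
            supply[i] += restock[i]
        if not accepted_any:
            break
    return transactions


def pareto_oracle(points):
    """O(n^2) pairwise strict-domination filter over (volume, partner) rates."""
    out = []
    for p in points:
        dominated = False
        for q in points:
            if (q.volume_rate >= p.volume_rate and q.partner_rate >= p.partner_rate
                    and (q.volume_rate > p.volume_rate or q.partner_rate > p.partner_rate)):
                dominated = True
                break
        if not dominated:
            out.append(p)
    return out
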