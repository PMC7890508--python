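import numpy as np
import pytest

import foodtrade as ft
from foodtrade.engine import score_candidates

from .conftest import make_two_agent_market
from .oracles import market_oracle, rank_oracle


def positions_for(world, saturation=1.0):
    """Set positions from the baseline diet, as the annual cycle would."""
    from foodtrade.engine import determine_positions
    for c in world.countries:
        c.import_realized[:] = 0.0
        c.export_realized[:] = 0.0
        for ci in range(world.n_commodities):
            nd, ni, av = determine_positions(c, ci, c.typical_diet[ci], 1.0)
            c.import_needed_domestic[ci] = nd
            c.import_needed_intermediary[ci] = ni
            c.export_available[ci] = av


class TestDeterminePositions:
    def _country(self, production, pct_food=1.0, intermediary=False,
                 base_imp=0.0, base_exp=0.0):
        c = ft.CountryState(
            id="X", name="X", lat=0, lon=0, region="Europe", sub_region="Europe",
            income_class="high", fortification_profile="refined_unfortified",
            population=1e6, gdp=1e9, demographics=np.ones(8) / 8,
            baseline_production=np.array([production]),
            baseline_import=np.array([base_imp]),
            baseline_export=np.array([base_exp]),
            baseline_ds=np.array([production + base_imp - base_exp]),
            pct_food=np.array([pct_food]), pct_loss=np.array([0.0]),
            is_intermediary=np.array([intermediary]),
            typical_diet=np.array([0.0]))
        return c

    def test_balanced_country_has_no_position(self):
        c = self._country(100.0)
        assert ft.determine_positions(c, 0, 100.0) == (0.0, 0.0, 0.0)

    def test_deficit_becomes_domestic_import_need(self):
        c = self._country(80.0)
        assert ft.determine_positions(c, 0, 100.0) == (20.0, 0.0, 0.0)

    def test_intermediary_surplus_demands_reexport_volume(self):
        c = self._country(120.0, intermediary=True, base_imp=30.0, base_exp=35.0)
        need_dom, need_int, avail = ft.determine_positions(c, 0, 100.0)
        assert (need_dom, need_int, avail) == (0.0, 30.0, 20.0)

    def test_reexport_need_rescales_with_global_supply(self):
        c = self._country(120.0, intermediary=True, base_imp=30.0, base_exp=35.0)
        _, need_int, _ = ft.determine_positions(c, 0, 100.0, global_ratio=0.5)
        assert need_int == 15.0

    def test_food_share_converts_diet_to_supply_equivalent(self):
        c = self._country(100.0, pct_food=0.5)
        need_dom, _, avail = ft.determine_positions(c, 0, 80.0)
        assert need_dom == 60.0  # 80 t food needs 160 t DS
        assert avail == 0.0

    def test_at_most_one_side_positive(self):
        for prod in (50.0, 100.0, 150.0):
            nd, _, av = ft.determine_positions(self._country(prod), 0, 100.0)
            assert nd == 0.0 or av == 0.0


class TestPriorityScore:
    def test_only_distance_matters_with_unit_distance_weight(self, small_world):
        w = ft.PriorityWeights(gdp=0, hist=0, emerg=0, dist=1)
        cands = np.arange(1, 5)
        scores = score_candidates(0, cands, "importer", w, small_world)
        nearest = np.argmin(small_world.relations.distance[0, cands])
        assert np.argmax(scores) == nearest
        assert scores[nearest] == 1.0

    def test_single_candidate_degenerate_normalizer(self, small_world):
        w = ft.CALIBRATED_WEIGHTS
        scores = score_candidates(0, np.array([3]), "importer", w, small_world)
        assert scores[0] == pytest.approx(1.0)

    def test_weighted_average_matches_hand_arithmetic(self):
        # Three candidates with hand-built elements under the shipped weights
        # (gdp 1.40, dist 1, hist 1.40, emerg 0.72).
        norms = {"gdp": (1000.0, 5000.0), "dist": (100.0, 900.0),
                 "hist": (0.0, 50.0), "emerg": (0.0, 10.0)}
        rel = ft.TradeRelation("A", "B", distance=300.0, historic_import=25.0,
                               historic_export=0.0, emergent_import=10.0)
        partner = type("P", (), {"gdp_per_capita": 3000.0})()
        got = ft.priority_score(rel, partner, "importer", ft.CALIBRATED_WEIGHTS, norms)
        g = (3000 - 1000) / 4000
        d = 1 - (300 - 100) / 800
        h = 25 / 50
        e = 10 / 10
        expected = (1.40 * g + 1.0 * d + 1.40 * h + 0.72 * e) / (1.40 + 1.0 + 1.40 + 0.72)
        assert got == pytest.approx(expected, rel=1e-12)
        assert 0.0 <= got <= 1.0

    def test_score_strictly_monotone_in_each_element(self, small_world):
        w = ft.CALIBRATED_WEIGHTS
        cands = np.arange(1, 6)
        base = score_candidates(0, cands, "importer", w, small_world)
        rich = small_world.copy()
        j = int(cands[2])
        rich.countries[j].gdp *= 1.5
        bumped = score_candidates(0, cands, "importer", w, rich)
        assert bumped[2] > base[2]


class TestRankPartners:
    def test_pure_gdp_ranking(self, small_world):
        w = ft.PriorityWeights(gdp=1, hist=0, emerg=0, dist=0)
        cands = list(range(1, 8))
        rng = np.random.default_rng(0)
        order = ft.rank_partners(0, cands, "importer", w, small_world, rng)
        gdp_pc = [small_world.countries[j].gdp_per_capita for j in order]
        assert gdp_pc == sorted(gdp_pc, reverse=True)

    def test_all_equal_candidates_random_but_reproducible(self, small_world):
        w = ft.PriorityWeights(gdp=0, hist=0, emerg=0, dist=0.0001)
        clone = small_world.copy()
        for c in clone.countries:
            c.gdp = 1e9
            c.population = 1e6
        clone.relations.distance[:] = 0.0
        cands = list(range(1, 8))
        o1 = ft.rank_partners(0, cands, "importer", w, clone, np.random.default_rng(7))
        o2 = ft.rank_partners(0, cands, "importer", w, clone, np.random.default_rng(7))
        o3 = ft.rank_partners(0, cands, "importer", w, clone, np.random.default_rng(8))
        assert o1 == o2
        assert sorted(o1) == sorted(cands)
        assert o1 != o3 or True  # different seed may coincide; only determinism is asserted

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_score_then_sort_oracle(self, default_worldlet, seed):
        rng_master = np.random.default_rng(seed)
        actor = int(rng_master.integers(0, default_worldlet.n_countries))
        others = [j for j in range(default_worldlet.n_countries) if j != actor]
        size = int(rng_master.integers(1, 7))
        cands = list(rng_master.choice(others, size=size, replace=False))
        cands = [int(c) for c in cands]
        role = "importer" if rng_master.random() < 0.5 else "exporter"
        tie_seed = int(rng_master.integers(0, 2**31))
        got = ft.rank_partners(actor, cands, role, ft.CALIBRATED_WEIGHTS,
                               default_worldlet, np.random.default_rng(tie_seed))
        rel = default_worldlet.relations
        raw = {}
        for c in cands:
            raw[c] = {
                "gdp": default_worldlet.countries[c].gdp_per_capita,
                "dist": float(rel.distance[actor, c]),
                "hist": float(rel.historic_import[actor, c] if role == "importer"
                              else rel.historic_export[actor, c]),
                "emerg": float(rel.emergent_import[actor, c] if role == "importer"
                               else rel.emergent_export[actor, c]),
            }
        draws = np.random.default_rng(tie_seed).random(len(cands))
        tb = {c: float(draws[k]) for k, c in enumerate(cands)}
        expected = rank_oracle(cands, raw, {"gdp": 1.40, "dist": 1.0,
                                            "hist": 1.40, "emerg": 0.72}, tb)
        assert got == expected


class TestCommodityMarket:
    def test_greedy_rounds_hand_enumeration(self):
        world = make_two_agent_market(demand=10.0, supply=8.0)
        params = ft.MarketParams(saturation=1.0, cap=5.0)
        txs = ft.run_commodity_market(world, 0, params, ft.CALIBRATED_WEIGHTS,
                                      np.random.default_rng(0))
        assert [(t.amount, t.round) for t in txs] == [(5.0, 1), (3.0, 2)]
        assert sum(t.amount for t in txs) == 8.0

    def test_half_saturation_stops_at_half_potential(self):
        world = make_two_agent_market(demand=10.0, supply=8.0)
        params = ft.MarketParams(saturation=0.5, cap=5.0)
        txs = ft.run_commodity_market(world, 0, params, ft.CALIBRATED_WEIGHTS,
                                      np.random.default_rng(0))
        assert sum(t.amount for t in txs) == pytest.approx(4.0)

    def test_no_demand_means_no_transactions(self):
        world = make_two_agent_market(demand=0.0, supply=8.0)
        txs = ft.run_commodity_market(world, 0, ft.MarketParams(), ft.CALIBRATED_WEIGHTS,
                                      np.random.default_rng(0))
        assert txs == []

    def test_conservation_and_no_overtrading(self, small_world):
        world = small_world.copy()
        positions_for(world)
        need = {c.id: c.import_needed_domestic + c.import_needed_intermediary
                for c in world.countries}
        avail = {c.id: c.export_available.copy() for c in world.countries}
        for ci in range(world.n_commodities):
            txs = ft.run_commodity_market(world, ci, ft.MarketParams(saturation=0.8),
                                          ft.CALIBRATED_WEIGHTS, np.random.default_rng(ci))
            total = sum(t.amount for t in txs)
            imp = sum(c.import_realized[ci] for c in world.countries)
            exp = sum(c.export_realized[ci] for c in world.countries)
            assert imp == pytest.approx(total, rel=1e-12)
            assert exp == pytest.approx(total, rel=1e-12)
            for t in txs:
                assert t.importer_id != t.exporter_id
                assert t.amount > 0
        for c in world.countries:
            assert np.all(c.import_realized <= need[c.id] + 1e-9)
            assert np.all(c.export_realized <= avail[c.id]
                          + c.import_realized + 1e-9)  # intermediaries restock

    def test_saturation_monotone_and_cap_insensitive(self, small_world):
        totals = {}
        for s in (0.6, 0.8, 1.0):
            world = small_world.copy()
            positions_for(world)
            per_com = []
            for ci in range(world.n_commodities):
                txs = ft.run_commodity_market(world, ci, ft.MarketParams(saturation=s),
                                              ft.CALIBRATED_WEIGHTS,
                                              np.random.default_rng(ci))
                per_com.append(sum(t.amount for t in txs))
            totals[s] = per_com
        for ci in range(small_world.n_commodities):
            assert totals[0.6][ci] <= totals[0.8][ci] + 1e-9
            assert totals[0.8][ci] <= totals[1.0][ci] + 1e-9

    def test_cap_insensitive_at_full_saturation(self):
        # On one-sided markets (no intermediaries) the cleared volume at s=1
        # is exactly min(total demand, total supply) for any per-round cap;
        # only the round counts differ.
        base = ft.generate_world(ft.WorldGenConfig(n_countries=10, n_commodities=3,
                                                   seed=3, intermediary_fraction=0.0))
        positions_for(base)
        for ci in range(base.n_commodities):
            dem = sum(c.import_needed_domestic[ci] for c in base.countries)
            sup = sum(c.export_available[ci] for c in base.countries)
            potential = min(dem, sup)
            rounds_seen = set()
            for cap_scale in (0.03, 0.2, 0.7):
                world = base.copy()
                txs = ft.run_commodity_market(
                    world, ci, ft.MarketParams(saturation=1.0, cap=cap_scale * potential),
                    ft.CALIBRATED_WEIGHTS, np.random.default_rng(ci))
                assert sum(t.amount for t in txs) == pytest.approx(potential, rel=1e-9)
                rounds_seen.add(max(t.round for t in txs))
            assert len(rounds_seen) > 1

    @pytest.mark.parametrize("seed", range(12))
    def test_engine_equals_brute_force_oracle(self, seed):
        rng_master = np.random.default_rng(seed)
        n = int(rng_master.integers(2, 6))
        cfg = ft.WorldGenConfig(n_countries=n, n_commodities=1, seed=seed + 1000,
                                intermediary_fraction=0.3)
        world = ft.generate_world(cfg)
        positions_for(world)
        s = float(rng_master.choice([0.6, 0.8, 1.0]))
        txs = ft.run_commodity_market(world.copy(), 0, ft.MarketParams(saturation=s),
                                      ft.CALIBRATED_WEIGHTS, np.random.default_rng(seed))
        expected = market_oracle(world.copy(), 0, s, None, ft.CALIBRATED_WEIGHTS,
                                 np.random.default_rng(seed))
        assert [tuple(t) for t in txs] == expected


class TestUpdateEmergent:
    def test_empty_transaction_list_changes_nothing(self, small_world):
        rel = small_world.relations.copy()
        before_i = rel.emergent_import.copy()
        ft.update_emergent(rel, [])
        assert np.array_equal(rel.emergent_import, before_i)

    def test_single_transaction_raises_both_directed_volumes(self, small_world):
        rel = small_world.relations.copy()
        a, b = small_world.countries[0].id, small_world.countries[1].id
        t = ft.Transaction(2001, "C000", importer_id=a, exporter_id=b,
                           amount=7.0, round=1)
        ft.update_emergent(rel, [t])
        assert rel.emergent_import[0, 1] == 7.0
        assert rel.emergent_export[1, 0] == 7.0
        assert rel.emergent_import.sum() == 7.0
        assert rel.emergent_export.sum() == 7.0
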