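import pytest
from hypothesis import HealthCheck, settings

import foodtrade as ft

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """8 countries x 4 commodities, with intermediaries."""
    cfg = ft.WorldGenConfig(n_countries=8, n_commodities=4, seed=11,
                            intermediary_fraction=0.25)
    return ft.generate_world(cfg)


@pytest.fixture(scope="session")
def default_worldlet():
    """20 countries x 6 commodities, defaults otherwise."""
    cfg = ft.WorldGenConfig(n_countries=20, n_commodities=6, seed=5)
    return ft.generate_world(cfg)


@pytest.fixture()
def fresh_world(small_world):
    return small_world.copy()


def make_two_agent_market(demand: float, supply: float, n_extra: int = 0,
                          seed: int = 0) -> ft.World:
    """A hand-built world whose first country imports and second exports."""
    cfg = ft.WorldGenConfig(n_countries=2 + n_extra, n_commodities=1, seed=seed,
                            intermediary_fraction=0.0)
    world = ft.generate_world(cfg)
    for c in world.countries:
        c.import_needed_domestic[:] = 0.0
        c.import_needed_intermediary[:] = 0.0
        c.export_available[:] = 0.0
        c.import_realized[:] = 0.0
        c.export_realized[:] = 0.0
    world.countries[0].import_needed_domestic[0] = demand
    world.countries[1].export_available[0] = supply
    return world
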