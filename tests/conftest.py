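"""Shared fixtures: small hand-built networks and a session twin experiment."""

import numpy as np
import pytest

from campflow import (Link, Location, LocationGraph, LocationKind,
                      ScenarioSpec, SimulationParameters, generate_scenario,
                      generate_twin_data)


def build_star(camp_distances, zone_population=10 ** 6):
    """One conflict zone Z linked directly to named camps abroad."""
    g = LocationGraph()
    g.add_location(Location("Z", "Home", LocationKind.CONFLICT,
                            population=zone_population, conflict_day=0))
    for name, dist in camp_distances.items():
        g.add_location(Location(name, "Abroad", LocationKind.CAMP, foreign=True))
        g.add_link(Link("Z", name, dist))
    return g


@pytest.fixture
def params():
    return SimulationParameters()


@pytest.fixture
def star_graph():
    # weights 2/100, 2/100, 2/200 -> route probabilities 0.4 / 0.4 / 0.2
    return build_star({"A": 100.0, "B": 100.0, "C": 200.0})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def twin_setup():
    """Default desk-scale twin experiment: 3 zones / 4 camps / 8 towns,
    5,000 agents over 100 days; reference run seeded at 10."""
    spec = ScenarioSpec()
    scenario = generate_scenario(spec)
    registrations, reference = generate_twin_data(scenario, seed=10)
    return spec, scenario, registrations, reference
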