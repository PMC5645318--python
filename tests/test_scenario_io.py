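"""Registration preprocessing and scenario-bundle round trips."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from campflow import (Link, Location, LocationGraph, LocationKind,
                      RegistrationSeries, Scenario, ScenarioError,
                      ScenarioSpec, aggregate_total, extract_conflict_zones,
                      generate_scenario, load_scenario, rescale_level1,
                      write_scenario)


# -- interpolation ----------------------------------------------------------

def test_interpolation_midpoint_knots_and_clamp():
    s = RegistrationSeries.from_points("c", [(0, 0.0), (10, 100.0)])
    assert s.interpolate(5) == 50.0
    assert s.interpolate(0) == 0.0 and s.interpolate(10) == 100.0
    assert s.interpolate(-3) == 0.0      # clamp before first knot
    assert s.interpolate(99) == 100.0    # clamp after last knot
    s2 = RegistrationSeries.from_points("c", [(0, 40.0), (4, 40.0)])
    assert s2.interpolate(-3) == 40.0


def test_interpolation_is_piecewise_linear_between_knots():
    s = RegistrationSeries.from_points("c", [(0, 0.0), (6, 30.0), (10, 10.0)])
    days = np.arange(0, 11)
    vals = s.interpolate(days)
    # second differences vanish strictly inside each segment
    inner = np.diff(vals, 2)
    assert np.allclose(inner[[0, 1, 2, 3, 4]], 0)  # inside [0, 6]
    assert np.allclose(inner[[6, 7, 8]], 0)        # inside [6, 10]
    assert inner[5] != 0                            # the kink at the knot
    for d in s.days:
        assert s.interpolate(d) == dict(zip(s.days, s.counts))[d]


def test_series_validation():
    with pytest.raises(ValueError):
        RegistrationSeries("c", (), ())
    with pytest.raises(ValueError):
        RegistrationSeries("c", (0, 0), (1.0, 2.0))
    with pytest.raises(ValueError):
        RegistrationSeries("c", (0, 1), (1.0, -2.0))


# -- level-1 rescaling ------------------------------------------------------

def test_rescale_level1_matches_segments():
    """Level-1 ending at 120 against level-2 starting at 100 scales the
    provisional segment by 5/6 and preserves level 2 bit-exactly."""
    s = RegistrationSeries.from_points(
        "c", [(0, 60.0), (5, 120.0), (10, 100.0), (15, 130.0)],
        level_split_day=10)
    r = rescale_level1(s)
    assert r.counts[:2] == (50.0, 100.0)
    assert r.counts[2:] == s.counts[2:]
    assert r.days == s.days


def test_rescale_level1_identity_cases(caplog):
    matched = RegistrationSeries.from_points(
        "c", [(0, 50.0), (5, 100.0), (10, 100.0)], level_split_day=10)
    assert rescale_level1(matched).counts == matched.counts
    no_split = RegistrationSeries.from_points("c", [(0, 50.0), (5, 120.0)])
    assert rescale_level1(no_split) is no_split
    zero_l1 = RegistrationSeries.from_points(
        "c", [(0, 0.0), (10, 100.0)], level_split_day=10)
    assert rescale_level1(zero_l1).counts == zero_l1.counts
    assert "rescaling skipped" in caplog.text


# -- aggregation ------------------------------------------------------------

def test_aggregate_total_identity_and_constants():
    s = RegistrationSeries.from_points("a", [(0, 10.0), (5, 10.0)])
    t = RegistrationSeries.from_points("b", [(0, 20.0), (5, 20.0)])
    total = aggregate_total([s, t])
    assert total.counts == (30.0, 30.0)
    alone = aggregate_total([s])
    assert alone.days == s.days and alone.counts == s.counts


def test_aggregate_total_disjoint_knots_pointwise_oracle():
    """The aggregate at every union day equals the sum of each series
    interpolated there (brute-force pointwise oracle)."""
    a = RegistrationSeries.from_points("a", [(0, 0.0), (10, 100.0)])
    b = RegistrationSeries.from_points("b", [(3, 30.0), (7, 10.0)])
    total = aggregate_total([a, b])
    assert total.days == (0, 3, 7, 10)
    for day in range(-2, 13):
        assert total.interpolate(day) == pytest.approx(
            a.interpolate(day) + b.interpolate(day))
    with pytest.raises(ValueError):
        aggregate_total([])


# -- conflict-event filtering -----------------------------------------------

def event_table(rows):
    return pd.DataFrame(rows, columns=["location", "population",
                                       "event_type", "date"])


def test_extract_conflict_zones_filters_and_earliest_battle():
    table = event_table([
        ("Big", 50_000, "battle", 12),
        ("Big", 50_000, "battle", 5),
        ("Small", 9_999, "battle", 1),      # below the population floor
        ("Quiet", 80_000, "riot", 2),       # never a battle
        ("Edge", 10_000, "Battle", 9),      # threshold inclusive, case-blind
        ("Broken", None, "battle", 3),      # malformed, skipped
    ])
    assert extract_conflict_zones(table) == [("Big", 5), ("Edge", 9)]


def test_extract_conflict_zones_iso_dates_need_start_date():
    table = event_table([("Big", 50_000, "battle", "2015-05-10")])
    zones = extract_conflict_zones(table, start_date=date(2015, 5, 1))
    assert zones == [("Big", 9)]
    with pytest.raises(ScenarioError):
        extract_conflict_zones(table)


# -- bundle round trip and schema errors ------------------------------------

def sample_scenario():
    g = LocationGraph()
    g.add_location(Location("Z", "Home", LocationKind.CONFLICT,
                            population=5000, conflict_day=0))
    g.add_location(Location("T", "Home", LocationKind.TOWN, population=800))
    g.add_location(Location("H", "Home", LocationKind.FORWARD))
    g.add_location(Location("C", "Away", LocationKind.CAMP, foreign=True,
                            capacity=2000))
    g.add_link(Link("Z", "T", 120.0))
    g.add_link(Link("T", "H", 60.0))
    g.add_link(Link("H", "C", 40.0, forced_redirection=True))
    g.find_link("Z", "T").close_interval(4, 211)
    regs = {"C": RegistrationSeries.from_points("C", [(0, 0.0), (30, 900.0)])}
    total = RegistrationSeries.from_points("total", [(0, 0.0), (30, 900.0)])
    return Scenario(graph=g, registrations=regs, total=total)


def test_scenario_round_trip(tmp_path):
    original = sample_scenario()
    write_scenario(original, tmp_path / "bundle")
    loaded = load_scenario(tmp_path / "bundle")
    g = loaded.graph
    assert set(g.locations) == set(original.graph.locations)
    for name, loc in original.graph.locations.items():
        got = g.locations[name]
        assert (got.declared_kind, got.country, got.population, got.capacity,
                got.foreign, got.conflict_day) == \
            (loc.declared_kind, loc.country, loc.population, loc.capacity,
             loc.foreign, loc.conflict_day)
    assert [(l.endpoint_a, l.endpoint_b, l.distance_km, l.forced_redirection)
            for l in g.links] == \
        [(l.endpoint_a, l.endpoint_b, l.distance_km, l.forced_redirection)
         for l in original.graph.links]
    for day in range(0, 240, 7):
        for got, want in zip(g.links, original.graph.links):
            assert got.is_open(day) == want.is_open(day)
    assert loaded.registrations["C"].days == original.registrations["C"].days
    assert loaded.registrations["C"].counts == original.registrations["C"].counts
    assert loaded.total.counts == original.total.counts
    # second round trip is stable
    write_scenario(loaded, tmp_path / "bundle2")
    again = load_scenario(tmp_path / "bundle2")
    assert [l.open_windows for l in again.graph.links] == \
        [l.open_windows for l in g.links]


def test_generated_bundle_round_trips(tmp_path):
    scenario = generate_scenario(ScenarioSpec(seed=4), directory=tmp_path / "s")
    loaded = load_scenario(tmp_path / "s")
    assert set(loaded.graph.locations) == set(scenario.graph.locations)
    assert loaded.total.counts == scenario.total.counts


def test_missing_file_errors_name_the_file(tmp_path):
    with pytest.raises(ScenarioError, match="locations.csv"):
        load_scenario(tmp_path)
    write_scenario(sample_scenario(), tmp_path / "b")
    (tmp_path / "b" / "routes.csv").unlink()
    with pytest.raises(ScenarioError, match="routes.csv"):
        load_scenario(tmp_path / "b")


def test_unknown_location_in_routes_names_the_row(tmp_path):
    write_scenario(sample_scenario(), tmp_path / "b")
    routes = pd.read_csv(tmp_path / "b" / "routes.csv")
    routes.loc[len(routes)] = ["Z", "Nowhere", 10.0, False]
    routes.to_csv(tmp_path / "b" / "routes.csv", index=False)
    with pytest.raises(ScenarioError, match=r"routes.csv row 5"):
        load_scenario(tmp_path / "b")


def test_bad_closure_scope_rejected(tmp_path):
    write_scenario(sample_scenario(), tmp_path / "b")
    pd.DataFrame([{"scope": "galaxy", "name_a": "Z", "name_b": "T",
                   "start_day": 0, "end_day": 5}]
                 ).to_csv(tmp_path / "b" / "closures.csv", index=False)
    with pytest.raises(ScenarioError, match="closures.csv row 2"):
        load_scenario(tmp_path / "b")


def test_location_and_country_closure_scopes(tmp_path):
    write_scenario(sample_scenario(), tmp_path / "b")
    pd.DataFrame([
        {"scope": "location", "name_a": "T", "name_b": "",
         "start_day": 2, "end_day": 4},
        {"scope": "country", "name_a": "Home", "name_b": "Away",
         "start_day": 10, "end_day": ""},
    ]).to_csv(tmp_path / "b" / "closures.csv", index=False)
    loaded = load_scenario(tmp_path / "b")
    g = loaded.graph
    assert not g.find_link("Z", "T").is_open(2)       # location scope
    assert g.find_link("Z", "T").is_open(4)
    assert not g.find_link("T", "H").is_open(3)
    cross = g.find_link("H", "C")                      # only cross-border link
    assert cross.is_open(9) and not cross.is_open(10) and not cross.is_open(9999)
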