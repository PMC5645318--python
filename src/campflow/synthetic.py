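"""Self-contained synthetic scenarios and twin-experiment data.

The generator emulates the structure of real conflict networks: a
connected interior of conflict zones and towns in the country of
conflict, camps abroad each attached by a single direct link to an
interior node, optional forwarding hubs, and an observed total-arrival
curve (linear or logistic cumulative total). Everything is deterministic
given the seed, and bundles are written as plain CSV so every other
module is testable without any download.

Twin experiments close the loop: a reference run of the simulator itself
produces the "observed" per-camp registration series (its raw in-camp
daily counts), while the total curve that drove the reference run is
stored as the insertion driver. Re-running with the same seed therefore
reproduces the observations exactly (E(t) = 0), and a different seed
isolates pure stochastic route noise — the basis of the parameter
recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import RunResult, Simulation
from .geography import Link, Location, LocationGraph, LocationKind
from .params import SimulationParameters
from .scenario_io import RegistrationSeries, Scenario, write_scenario

HOME = "Homeland"
ABROAD = "Neighbourland"


@dataclass(frozen=True)
class ScenarioSpec:
    """Shape of a synthetic scenario.

    Defaults give the desk-scale study condition used throughout the
    test suite: 3 conflict zones, 4 camps, 8 towns, 5,000 displaced
    people arriving linearly over 100 days.
    """

    n_conflict_zones: int = 3
    n_camps: int = 4
    n_towns: int = 8
    n_forward_hubs: int = 0
    distance_km: tuple[float, float] = (40.0, 180.0)
    population: tuple[int, int] = (20_000, 200_000)
    total_agents: int = 5_000
    duration: int = 100
    curve: str = "linear"  # or "logistic"
    closure_density: float = 0.0  # expected closures per interior link
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conflict_zones < 1:
            raise ValueError("need at least one conflict zone")
        if self.n_camps < 1:
            raise ValueError("need at least one camp")
        if self.curve not in ("linear", "logistic"):
            raise ValueError(f"unknown curve shape {self.curve!r}")
        if self.duration < 1 or self.total_agents < 0:
            raise ValueError("duration >= 1 and total_agents >= 0 required")


def total_curve(spec: ScenarioSpec) -> RegistrationSeries:
    """Cumulative total-arrival curve implied by the spec."""
    T, N = spec.duration, spec.total_agents
    if spec.curve == "linear":
        return RegistrationSeries("total", (0, T), (0.0, float(N)))
    days = tuple(range(T + 1))
    t = np.arange(T + 1, dtype=float)
    raw = 1.0 / (1.0 + np.exp(-10.0 * (t / T - 0.5)))  # logistic in [0,1]
    counts = N * (raw - raw[0]) / (raw[-1] - raw[0])
    return RegistrationSeries("total", days, tuple(counts))


def generate_scenario(spec: ScenarioSpec,
                      directory: Optional[str | Path] = None,
                      seed: Optional[int] = None) -> Scenario:
    """Build a synthetic scenario; optionally write the bundle to disk.

    The interior (conflict zones + towns) is a random spanning tree plus
    extra chords, so it is connected by construction; each camp and each
    forwarding hub hangs off a random interior node. Deterministic given
    (spec, seed).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    graph = LocationGraph()
    lo_km, hi_km = spec.distance_km
    lo_pop, hi_pop = spec.population

    zones = [f"Zone{i}" for i in range(spec.n_conflict_zones)]
    towns = [f"Town{i}" for i in range(spec.n_towns)]
    camps = [f"Camp{i}" for i in range(spec.n_camps)]
    interior = zones + towns

    for name in zones:
        graph.add_location(Location(
            name=name, country=HOME, kind=LocationKind.CONFLICT,
            population=int(rng.integers(lo_pop, hi_pop + 1)), conflict_day=0))
    for name in towns:
        graph.add_location(Location(
            name=name, country=HOME, kind=LocationKind.TOWN,
            population=int(rng.integers(lo_pop, hi_pop + 1))))
    for name in camps:
        graph.add_location(Location(
            name=name, country=ABROAD, kind=LocationKind.CAMP,
            population=0, foreign=True,
            capacity=int(spec.total_agents) or None))

    def dist() -> float:
        return float(np.round(rng.uniform(lo_km, hi_km), 1))

    # spanning tree over the interior, then ~n/3 extra chords
    for i in range(1, len(interior)):
        j = int(rng.integers(0, i))
        graph.add_link(Link(interior[j], interior[i], dist()))
    for _ in range(max(len(interior) // 3, 1) if len(interior) > 1 else 0):
        i, j = rng.choice(len(interior), size=2, replace=False)
        a, b = interior[int(i)], interior[int(j)]
        try:
            graph.find_link(a, b)
        except KeyError:
            graph.add_link(Link(a, b, dist()))

    # each camp attaches to one interior node by a single direct route
    for name in camps:
        anchor = interior[int(rng.integers(0, len(interior)))]
        graph.add_link(Link(anchor, name, dist()))

    # optional forwarding hubs: interior -> hub -> camp, compelled onward
    for h in range(spec.n_forward_hubs):
        hub = f"Hub{h}"
        graph.add_location(Location(name=hub, country=HOME,
                                    kind=LocationKind.FORWARD))
        anchor = interior[int(rng.integers(0, len(interior)))]
        camp = camps[int(rng.integers(0, len(camps)))]
        graph.add_link(Link(anchor, hub, dist()))
        graph.add_link(Link(hub, camp, dist(), forced_redirection=True))

    if spec.closure_density > 0:
        for link in list(graph.links):
            if link.forced_redirection:
                continue
            if rng.random() < spec.closure_density:
                start = int(rng.integers(1, max(spec.duration, 2)))
                end = int(min(start + rng.integers(5, 40), spec.duration))
                link.close_interval(start, end)

    scenario = Scenario(graph=graph, total=total_curve(spec))
    if directory is not None:
        write_scenario(scenario, directory)
    return scenario


def generate_twin_data(scenario: Scenario,
                       curve: Optional[RegistrationSeries] = None,
                       seed: int = 0,
                       duration: Optional[int] = None,
                       params: Optional[SimulationParameters] = None,
                       directory: Optional[str | Path] = None
                       ) -> tuple[dict[str, RegistrationSeries], RunResult]:
    """Produce twin "observed" registrations from a reference run.

    Runs the simulator on ``scenario`` with ``curve`` (default: the
    scenario's own total curve) as insertion driver and returns the raw
    per-camp daily counts as registration series, writing them (plus the
    driving total curve) into the scenario directory when given. The
    aggregate of the twin series equals the reference run's in-camp
    total by construction.
    """
    curve = curve if curve is not None else scenario.total_series()
    if curve is None:
        raise ValueError("no total curve available to drive the reference run")
    T = duration if duration is not None else int(max(curve.days))
    sim = Simulation(scenario.graph, params=params, total_series=curve, seed=seed)
    result = sim.run(T)

    registrations = {
        camp: RegistrationSeries.from_points(
            camp, zip(result.camp_counts.index, result.camp_counts[camp]))
        for camp in result.camp_counts.columns
    }
    scenario.registrations = registrations
    scenario.total = curve
    if directory is not None:
        directory = Path(directory)
        rows = [{"camp": s.camp_name, "day": d, "count": c}
                for s in registrations.values()
                for d, c in zip(s.days, s.counts)]
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(directory / "registrations.csv", index=False)
        pd.DataFrame({"day": curve.days, "count": curve.counts}
                     ).to_csv(directory / "total.csv", index=False)
    return registrations, result
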