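"""Agent state and the daily evolution loop.

Each simulation step is one day. Per day, in order: scheduled topology
changes are applied, new agents are inserted at conflict zones according
to the observed total-registration increase, and every agent (in creation
order) takes its daily step. An agent's step is a sequence of decisions
against a single global random stream:

* an agent partway along a link keeps moving (transit move chance 1.0)
  and advances by at most its remaining daily budget;
* an agent at a location draws against the class move chance (conflict
  1.0, camp 0.001, elsewhere 0.3) and, on success, picks an open link
  with probability proportional to attractiveness(destination) / length;
* reaching a location with budget to spare triggers a fresh draw, so
  multi-hop days are possible up to the 200 km/day budget;
* arrival at a forwarding hub compels the designated onward route with
  no draw.

Agents are never deleted, so the population at any day equals the
cumulative insertions — a conservation law the test suite checks.
"""

from __future__ import annotations

import copy
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import calibration
from .calibration import DebtLedger
from .geography import (Link, Location, LocationGraph, LocationKind,
                        apply_events, attractiveness, open_neighbours)
from .params import SimulationParameters
from .scenario_io import RegistrationSeries, Scenario

_EPS_KM = 1e-9  # tolerance for "link completed" in km


@dataclass
class Agent:
    """A displaced person: at a location, or partway along a link.

    ``location`` is the current location name while settled, and the
    link's origin endpoint while in transit (``link`` is not None then).
    """

    location: str
    origin: str
    created_day: int
    link: Optional[Link] = None
    distance_done_km: float = 0.0

    @property
    def in_transit(self) -> bool:
        return self.link is not None

    def destination(self) -> Optional[str]:
        return None if self.link is None else self.link.other_end(self.location)


def move_chance(agent: Agent, graph: LocationGraph,
                params: SimulationParameters,
                occupancy: Optional[Counter] = None) -> float:
    """Daily probability that the agent attempts a move.

    Transit dominates the location class. With the optional capacity rule,
    a camp at or above capacity behaves like an ordinary location.
    """
    if agent.in_transit:
        return params.movechance_transit
    loc = graph.locations[agent.location]
    kind = loc.kind
    if kind is LocationKind.CONFLICT:
        return params.movechance_conflict
    if kind is LocationKind.CAMP:
        if (params.capacity_rule and occupancy is not None
                and loc.capacity is not None
                and occupancy[loc.name] >= loc.capacity):
            return params.movechance_default
        return params.movechance_camp
    if kind is LocationKind.FORWARD:
        return 1.0
    return params.movechance_default


class NoMovePossible(Exception):
    """Raised by select_link when the open neighbourhood is empty."""


def select_link(location: str, graph: LocationGraph, day: int,
                params: SimulationParameters, rng: np.random.Generator) -> Link:
    """Weighted route choice out of ``location``.

    Each open link is weighted by attractiveness(destination) / length_km;
    one uniform draw is inverted against the cumulative weights, with
    destinations in routes-file load order (deterministic tie-breaking).
    """
    neighbours = open_neighbours(graph, location, day)
    if not neighbours:
        raise NoMovePossible(location)
    if len(neighbours) == 1:
        return neighbours[0][0]
    weights = np.array([attractiveness(dest, params, day) / link.distance_km
                        for link, dest in neighbours])
    u = rng.random() * weights.sum()
    idx = int(np.searchsorted(np.cumsum(weights), u, side="right"))
    idx = min(idx, len(neighbours) - 1)
    return neighbours[idx][0]


def step_agent(agent: Agent, graph: LocationGraph, day: int,
               params: SimulationParameters, rng: np.random.Generator,
               occupancy: Optional[Counter] = None) -> Agent:
    """Advance one agent through one day (mutates and returns it).

    The daily budget starts at ``max_km_per_day`` and is spent across as
    many hops as draws allow. An agent that cannot or does not move is
    unchanged. ``occupancy`` (location -> headcount) is kept current when
    given, for camp-capacity behaviour and fast per-day counting.
    """
    budget = params.max_km_per_day

    if agent.in_transit:
        # one transit draw per day; with the default chance of 1.0 the
        # agent always presses on, and it can never reverse mid-link
        if rng.random() >= params.movechance_transit:
            return agent
        budget = _advance(agent, budget, occupancy)

    while budget > _EPS_KM and not agent.in_transit:
        loc = graph.locations[agent.location]
        if loc.kind is LocationKind.FORWARD:
            link = graph.redirect_link(agent.location, day)
            if link is None:
                break
        else:
            if rng.random() >= move_chance(agent, graph, params, occupancy):
                break
            try:
                link = select_link(agent.location, graph, day, params, rng)
            except NoMovePossible:
                break
        if occupancy is not None:
            occupancy[agent.location] -= 1
        agent.link = link
        agent.distance_done_km = 0.0
        budget = _advance(agent, budget, occupancy)
    return agent


def _advance(agent: Agent, budget: float, occupancy: Optional[Counter]) -> float:
    """Move along the current link by min(remaining link, budget)."""
    remaining = agent.link.distance_km - agent.distance_done_km
    step = min(remaining, budget)
    agent.distance_done_km += step
    budget -= step
    if agent.link.distance_km - agent.distance_done_km <= _EPS_KM:
        dest = agent.link.other_end(agent.location)
        agent.location = dest
        agent.link = None
        agent.distance_done_km = 0.0
        if occupancy is not None:
            occupancy[dest] += 1
    return budget


@dataclass
class RunResult:
    """Per-day record of a simulation run.

    ``camp_counts``: DataFrame indexed by day (0..T-1), one column per
    camp, raw end-of-day agent counts. ``totals``: DataFrame with columns
    ``agents`` (all agents alive), ``in_camps`` (N_sim_all),
    ``inserted`` (that day), ``deferred`` (insertions postponed for lack
    of an active conflict zone) and ``debt``.
    """

    camp_counts: pd.DataFrame
    totals: pd.DataFrame

    @property
    def days(self) -> np.ndarray:
        return self.camp_counts.index.to_numpy()


class Simulation:
    """The daily evolution loop over a scenario.

    Parameters
    ----------
    graph:
        The location network (typically ``scenario.graph``).
    params:
        Behavioural constants; ``params.seed`` seeds the single global
        random stream unless ``seed`` overrides it.
    total_series:
        Observed total-registration curve driving daily insertion; when
        None, agents are only inserted via :meth:`insert_agents`.
    """

    def __init__(self, graph: LocationGraph,
                 params: Optional[SimulationParameters] = None,
                 total_series: Optional[RegistrationSeries] = None,
                 seed: Optional[int] = None,
                 copy_graph: bool = True) -> None:
        # the run mutates its graph (spawn-zone populations, materialised
        # kinds), so work on a private copy unless the caller opts out
        self.graph = copy.deepcopy(graph) if copy_graph else graph
        self.params = params or SimulationParameters()
        self.total_series = total_series
        self.rng = np.random.default_rng(
            self.params.seed if seed is None else seed)
        self.agents: list[Agent] = []
        self.day = 0
        self.ledger = DebtLedger()
        self.deferred = 0
        self.occupancy: Counter = Counter()
        self._camp_history: list[dict[str, int]] = []
        self._totals_history: list[dict[str, float]] = []

    @classmethod
    def from_scenario(cls, scenario: Scenario,
                      params: Optional[SimulationParameters] = None,
                      seed: Optional[int] = None) -> "Simulation":
        return cls(scenario.graph, params=params,
                   total_series=scenario.total_series(), seed=seed)

    # -- insertion ---------------------------------------------------------

    def insert_agents(self, count: int) -> int:
        """Insert ``count`` agents at population-weighted conflict zones.

        Returns the number actually inserted; with no active conflict
        zone today, insertion is deferred to the next day that has one.
        """
        zones = self.graph.conflict_zones(self.day)
        if not zones:
            self.deferred += count
            return 0
        for _ in range(count):
            zone = calibration.choose_spawn_zone(zones, self.rng)
            self.agents.append(Agent(location=zone.name, origin=zone.name,
                                     created_day=self.day))
            self.occupancy[zone.name] += 1
        return count

    # -- evolution ---------------------------------------------------------

    def evolve(self) -> "Simulation":
        """Advance one day: events, insertions, then every agent once."""
        day = self.day
        apply_events(self.graph, day)

        inserted = 0
        if self.total_series is not None:
            count, self.ledger = calibration.daily_insertions(
                self.total_series, day, self.ledger)
            count += self.deferred
            self.deferred = 0
            inserted = self.insert_agents(count)

        for agent in self.agents:
            step_agent(agent, self.graph, day, self.params, self.rng,
                       self.occupancy)

        self._record(day, inserted)
        self.day += 1
        return self

    def run(self, days: int) -> RunResult:
        for _ in range(days):
            self.evolve()
        return self.result()

    def _record(self, day: int, inserted: int) -> None:
        camp_names = [c.name for c in self.graph.camps()]
        counts = {name: self.occupancy[name] for name in camp_names
                  if self.graph.locations[name].is_camp(day)}
        # camps not yet open contribute 0
        for name in camp_names:
            counts.setdefault(name, 0)
        self._camp_history.append(counts)
        self._totals_history.append({
            "agents": len(self.agents),
            "in_camps": float(sum(counts.values())),
            "inserted": inserted,
            "deferred": self.deferred,
            "debt": self.ledger.debt,
        })

    def result(self) -> RunResult:
        index = pd.RangeIndex(len(self._camp_history), name="day")
        camps = pd.DataFrame(self._camp_history, index=index).fillna(0).astype(int)
        camps = camps.reindex(sorted(camps.columns), axis=1)
        totals = pd.DataFrame(self._totals_history, index=index)
        return RunResult(camp_counts=camps, totals=totals)
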