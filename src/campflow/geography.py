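"""Location network: places, links, and scheduled topology changes.

The world is a graph of named locations joined by undirected links with an
exogenous length in kilometres. Locations are classified as conflict zones
(agent spawn sites, low attractiveness), camps (registration destinations,
very low move chance), forwarding hubs (arrivals are compelled onward along
a designated route) or ordinary towns. The classification is
time-dependent: a town becomes a conflict zone on the day of its first
battle, and a camp scheduled to open later behaves as a town until its
opening day. Border closures and late openings make links traversable only
inside explicit day windows.

All time dependence is compiled into per-link open windows and per-location
switch days when the graph is built, so that replaying the schedule for
days 0..T is idempotent and order-insensitive by construction.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .params import SimulationParameters

log = logging.getLogger(__name__)

INF_DAY = math.inf


class LocationKind(str, enum.Enum):
    CONFLICT = "conflict"
    CAMP = "camp"
    FORWARD = "forward"
    TOWN = "town"


class EventAction(str, enum.Enum):
    CLOSE_LINK = "close_link"
    OPEN_LINK = "open_link"
    OPEN_CAMP = "open_camp"
    MARK_CONFLICT = "mark_conflict"
    SET_REDIRECT = "set_redirect"


@dataclass
class Location:
    """A named place with a (possibly time-dependent) classification.

    ``kind`` holds the *declared* kind from the scenario; the effective
    kind on a given day is :meth:`kind_at`, which accounts for
    ``conflict_day`` (town -> conflict) and ``camp_open_day`` (town ->
    camp). ``population`` is mutable at run time: it is decremented as
    agents are spawned from a conflict zone.
    """

    name: str
    country: str = ""
    kind: LocationKind = LocationKind.TOWN
    population: int = 0
    capacity: Optional[int] = None
    foreign: bool = False
    conflict_day: Optional[int] = None
    camp_open_day: Optional[int] = None

    def __post_init__(self) -> None:
        self.kind = LocationKind(self.kind)
        # the scenario's declaration; `kind` itself is the materialised
        # per-day classification and is mutated by apply_events
        self.declared_kind: LocationKind = self.kind
        if self.population < 0:
            raise ValueError(f"{self.name}: population must be >= 0")
        if self.capacity is not None and self.capacity < 0:
            raise ValueError(f"{self.name}: capacity must be >= 0")

    def kind_at(self, day: int) -> LocationKind:
        """Effective classification on ``day``.

        Conflict status (once reached) dominates every other class and
        never reverts; a camp before its scheduled opening is a town.
        """
        declared = self.declared_kind
        if self.conflict_day is not None and day >= self.conflict_day:
            return LocationKind.CONFLICT
        if declared is LocationKind.CONFLICT:
            # declared conflict with a future start day behaves as a town
            return LocationKind.CONFLICT if self.conflict_day is None else LocationKind.TOWN
        if declared is LocationKind.CAMP and self.camp_open_day is not None \
                and day < self.camp_open_day:
            return LocationKind.TOWN
        return declared

    def is_conflict(self, day: int) -> bool:
        return self.kind_at(day) is LocationKind.CONFLICT

    def is_camp(self, day: int) -> bool:
        return self.kind_at(day) is LocationKind.CAMP


def _subtract_window(windows: list[tuple[float, float]],
                     start: float, end: float) -> list[tuple[float, float]]:
    """Remove [start, end) from a disjoint sorted list of [a, b) windows."""
    out: list[tuple[float, float]] = []
    for a, b in windows:
        if end <= a or start >= b:
            out.append((a, b))
            continue
        if a < start:
            out.append((a, start))
        if end < b:
            out.append((end, b))
    return out


def _add_window(windows: list[tuple[float, float]],
                start: float, end: float) -> list[tuple[float, float]]:
    """Merge [start, end) into a disjoint sorted list of [a, b) windows."""
    merged: list[tuple[float, float]] = []
    placed = False
    for a, b in sorted(windows + [(start, end)]):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
        placed = True
    return merged if placed else [(start, end)]


@dataclass
class Link:
    """An undirected route of fixed length, traversable inside open windows.

    ``forced_redirection`` marks the compelled one-way route out of a
    forwarding hub; kinematics are unchanged, only choice is removed.
    """

    endpoint_a: str
    endpoint_b: str
    distance_km: float
    open_windows: list[tuple[float, float]] = field(default_factory=lambda: [(0, INF_DAY)])
    forced_redirection: bool = False

    def __post_init__(self) -> None:
        if self.distance_km <= 0:
            raise ValueError(
                f"link {self.endpoint_a}-{self.endpoint_b}: distance_km must be > 0")

    def is_open(self, day: int) -> bool:
        return any(a <= day < b for a, b in self.open_windows)

    def other_end(self, name: str) -> str:
        if name == self.endpoint_a:
            return self.endpoint_b
        if name == self.endpoint_b:
            return self.endpoint_a
        raise KeyError(f"{name} is not an endpoint of {self.endpoint_a}-{self.endpoint_b}")

    def touches(self, name: str) -> bool:
        return name in (self.endpoint_a, self.endpoint_b)

    def close_interval(self, start: float, end: float) -> None:
        self.open_windows = _subtract_window(self.open_windows, start, end)

    def open_interval(self, start: float, end: float) -> None:
        self.open_windows = _add_window(self.open_windows, start, end)


def _event_end(ev: "Event") -> float:
    """End day of a link open/close event; very large ends mean 'forever'."""
    if len(ev.payload) <= 2:
        return INF_DAY
    end = float(ev.payload[2])
    return INF_DAY if end >= 1e9 else end


@dataclass(frozen=True)
class Event:
    day: int
    action: EventAction
    payload: tuple  # location name, or (name_a, name_b) for link actions


class EventSchedule:
    """Sorted list of scheduled topology changes.

    Link events are compiled into link open windows when the schedule is
    attached to a graph; location events (camp openings, conflict
    activations, redirect designations) are compiled into per-location
    switch days. Applying a day of the schedule is therefore idempotent.
    """

    def __init__(self, events: Iterable[Event] = ()) -> None:
        self.events: list[Event] = sorted(events, key=lambda e: e.day)

    def add(self, day: int, action: EventAction | str, *payload: str) -> None:
        self.events.append(Event(day, EventAction(action), tuple(payload)))
        self.events.sort(key=lambda e: e.day)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


class LocationGraph:
    """The location network plus its compiled schedule.

    Locations keep insertion order; links keep load order (route choice
    tie-breaking depends on it, so the order is part of the scenario).
    """

    def __init__(self) -> None:
        self.locations: dict[str, Location] = {}
        self.links: list[Link] = []
        self._adjacency: dict[str, list[int]] = {}
        self.schedule = EventSchedule()

    # -- construction -----------------------------------------------------

    def add_location(self, location: Location) -> Location:
        if location.name in self.locations:
            raise ValueError(f"duplicate location {location.name!r}")
        self.locations[location.name] = location
        self._adjacency[location.name] = []
        return location

    def add_link(self, link: Link) -> Link:
        for end in (link.endpoint_a, link.endpoint_b):
            if end not in self.locations:
                raise KeyError(f"link references unknown location {end!r}")
        idx = len(self.links)
        self.links.append(link)
        self._adjacency[link.endpoint_a].append(idx)
        self._adjacency[link.endpoint_b].append(idx)
        return link

    def find_link(self, name_a: str, name_b: str) -> Link:
        for idx in self._adjacency.get(name_a, ()):
            link = self.links[idx]
            if link.touches(name_b):
                return link
        raise KeyError(f"no link between {name_a!r} and {name_b!r}")

    def attach_schedule(self, schedule: EventSchedule) -> None:
        """Validate and compile a schedule into the graph.

        Unknown location or link references are hard errors at this point
        (load time), never at run time.
        """
        for ev in schedule:
            if ev.action in (EventAction.CLOSE_LINK, EventAction.OPEN_LINK,
                             EventAction.SET_REDIRECT):
                a, b = ev.payload[0], ev.payload[1]
                link = self.find_link(a, b)  # raises KeyError if absent
                if ev.action is EventAction.CLOSE_LINK:
                    link.close_interval(ev.day, _event_end(ev))
                elif ev.action is EventAction.OPEN_LINK:
                    link.open_interval(ev.day, _event_end(ev))
                else:
                    link.forced_redirection = True
                    self.locations[a].kind = LocationKind.FORWARD
                    self.locations[a].declared_kind = LocationKind.FORWARD
            else:
                name = ev.payload[0]
                if name not in self.locations:
                    raise KeyError(f"event references unknown location {name!r}")
                loc = self.locations[name]
                if ev.action is EventAction.OPEN_CAMP:
                    loc.declared_kind = LocationKind.CAMP
                    loc.camp_open_day = ev.day
                    loc.kind = loc.kind_at(0)
                elif ev.action is EventAction.MARK_CONFLICT:
                    if loc.conflict_day is None or ev.day < loc.conflict_day:
                        loc.conflict_day = ev.day
        self.schedule.events = sorted(self.schedule.events + list(schedule.events),
                                      key=lambda e: e.day)

    # -- queries -----------------------------------------------------------

    def links_of(self, name: str) -> list[Link]:
        return [self.links[i] for i in self._adjacency[name]]

    def redirect_link(self, name: str, day: int) -> Optional[Link]:
        """The designated outgoing route of a forwarding hub, if open."""
        for link in self.links_of(name):
            if link.forced_redirection and link.is_open(day):
                return link
        return None

    def camps(self, day: int | None = None) -> list[Location]:
        """All camp locations; with ``day``, only camps already open."""
        if day is None:
            return [l for l in self.locations.values()
                    if l.declared_kind is LocationKind.CAMP]
        return [l for l in self.locations.values() if l.is_camp(day)]

    def conflict_zones(self, day: int) -> list[Location]:
        return [l for l in self.locations.values() if l.is_conflict(day)]

    def check_connectivity(self, day: int = 0) -> bool:
        """Warn (never fail) if some camp is unreachable from some conflict zone.

        Reachability is over links open on ``day``. Camps are included even
        if they open later, since agents route toward them eventually.
        """
        g = nx.Graph()
        g.add_nodes_from(self.locations)
        for link in self.links:
            if link.is_open(day):
                g.add_edge(link.endpoint_a, link.endpoint_b)
        ok = True
        camps = [l.name for l in self.locations.values()
                 if l.declared_kind is LocationKind.CAMP]
        zones = [l.name for l in self.locations.values()
                 if l.declared_kind is LocationKind.CONFLICT or l.conflict_day is not None]
        for camp in camps:
            for zone in zones:
                if not nx.has_path(g, zone, camp):
                    log.warning("camp %s unreachable from conflict zone %s on day %d",
                                camp, zone, day)
                    ok = False
        return ok


def attractiveness(location: Location, params: SimulationParameters,
                   day: int | None = None) -> float:
    """Destination weight of a location: conflict 0.25, in-country 1.0, abroad 2.0.

    Conflict classification takes precedence over the in-country/abroad
    split. With ``day`` given, the time-dependent classification is used;
    otherwise the location's current (materialised) kind.
    """
    kind = location.kind if day is None else location.kind_at(day)
    if kind is LocationKind.CONFLICT:
        return params.attract_conflict
    if location.foreign:
        return params.attract_abroad
    return params.attract_incountry


def apply_events(graph: LocationGraph, day: int) -> LocationGraph:
    """Materialise the day's classification on every location.

    Link openness needs no action (windows are queried by day); location
    kinds are switched so that code reading ``location.kind`` sees the
    state of ``day``. Idempotent: applying the same day twice is a no-op.
    """
    for loc in graph.locations.values():
        effective = loc.kind_at(day)
        if effective is not loc.kind:
            loc.kind = effective
    return graph


def open_neighbours(graph: LocationGraph, name: str, day: int
                    ) -> list[tuple[Link, Location]]:
    """Traversable (link, destination) pairs from ``name`` on ``day``.

    A forwarding hub exposes only its designated redirect route. An empty
    list is a valid return (isolated or fully closed-off location).
    """
    loc = graph.locations[name]
    if loc.kind_at(day) is LocationKind.FORWARD:
        link = graph.redirect_link(name, day)
        if link is None:
            return []
        return [(link, graph.locations[link.other_end(name)])]
    out = []
    for link in graph.links_of(name):
        if link.is_open(day):
            out.append((link, graph.locations[link.other_end(name)]))
    return out
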