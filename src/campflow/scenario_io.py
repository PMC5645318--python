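"""Scenario bundle I/O and registration-data preprocessing.

A scenario is a directory of plain CSV tables:

``locations.csv``
    ``name,country,kind,population,capacity,foreign,conflict_day``
``routes.csv``
    ``name_a,name_b,distance_km,forced_redirection``
``closures.csv`` (optional)
    ``scope,name_a,name_b,start_day,end_day`` with scope in
    {link, location, country}; a link open only from day *d* is written as
    a closure over [0, *d*).
``events.csv`` (optional)
    ``day,action,name`` for camp openings and conflict activations.
``registrations.csv`` (optional)
    long format ``camp,day,count`` — per-camp observed registrations.
``total.csv`` (optional)
    ``day,count`` — the total-arrival curve driving agent insertion; when
    absent it is the aggregate of the interpolated camp registrations.
``config.yaml`` (optional)
    scenario-level settings, currently ``start_date`` (ISO-8601) used to
    convert date columns to 0-based day offsets.

Preprocessing implements the registration-data refinement rules: linear
interpolation between data points with clamping outside the observed
range, rescaling of provisional (level-1) registration segments so that
their last point matches the first verified (level-2) point, day-wise
aggregation into a total curve, and extraction of conflict zones from a
battle-event table (settlements under 10,000 inhabitants omitted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .geography import (Event, EventAction, EventSchedule, Link, Location,
                        LocationGraph, LocationKind)

log = logging.getLogger(__name__)


class ScenarioError(ValueError):
    """Schema violation in a scenario bundle (names file/row/column)."""


# ---------------------------------------------------------------------------
# Registration series


@dataclass(frozen=True)
class RegistrationSeries:
    """Observed counts for one camp over days, with linear interpolation.

    ``days`` are strictly increasing integers; ``counts`` are non-negative
    reals (real-valued after rescaling). ``level_split_day`` is the first
    day whose count is a verified level-2 registration.
    """

    camp_name: str
    days: tuple[int, ...]
    counts: tuple[float, ...]
    level_split_day: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.days) != len(self.counts):
            raise ValueError(f"{self.camp_name}: days/counts length mismatch")
        if len(self.days) == 0:
            raise ValueError(f"{self.camp_name}: empty registration series")
        d = np.asarray(self.days)
        if np.any(np.diff(d) <= 0):
            raise ValueError(f"{self.camp_name}: days must be strictly increasing")
        if any(c < 0 for c in self.counts):
            raise ValueError(f"{self.camp_name}: counts must be >= 0")

    @classmethod
    def from_points(cls, camp_name: str,
                    points: Iterable[tuple[int, float]],
                    level_split_day: Optional[int] = None) -> "RegistrationSeries":
        pts = sorted(points)
        return cls(camp_name, tuple(p[0] for p in pts),
                   tuple(float(p[1]) for p in pts), level_split_day)

    def interpolate(self, day):
        """Linear interpolation at ``day`` (scalar or array), clamped.

        Exact at knots, piecewise linear between them, constant extension
        before the first and after the last knot.
        """
        return np.interp(day, self.days, self.counts)


def interpolate(series: RegistrationSeries, day):
    """Functional alias for :meth:`RegistrationSeries.interpolate`."""
    return series.interpolate(day)


def rescale_level1(series: RegistrationSeries) -> RegistrationSeries:
    """Scale the provisional (level-1) segment onto the verified one.

    All points before ``level_split_day`` are multiplied by
    (first level-2 count) / (last level-1 count) so the two segments meet;
    the level-2 segment is preserved bit-exactly. Identity when there is
    no split, when either segment is empty, or (with a warning) when the
    last level-1 count is zero.
    """
    split = series.level_split_day
    if split is None:
        return series
    days = np.asarray(series.days)
    l1 = days < split
    l2 = ~l1
    if not l1.any() or not l2.any():
        return series
    last_l1 = series.counts[int(np.nonzero(l1)[0][-1])]
    first_l2 = series.counts[int(np.nonzero(l2)[0][0])]
    if last_l1 == 0:
        log.warning("%s: last level-1 count is 0; rescaling skipped",
                    series.camp_name)
        return series
    factor = first_l2 / last_l1
    counts = tuple(c * factor if is_l1 else c
                   for c, is_l1 in zip(series.counts, l1))
    return replace(series, counts=counts)


def aggregate_total(series_set: Sequence[RegistrationSeries],
                    name: str = "total") -> RegistrationSeries:
    """Day-wise sum of interpolated per-camp series over the union of knot days."""
    if not series_set:
        raise ValueError("aggregate_total needs at least one series")
    days = sorted({d for s in series_set for d in s.days})
    totals = np.zeros(len(days))
    for s in series_set:
        totals += s.interpolate(days)
    return RegistrationSeries(name, tuple(days), tuple(totals))


# ---------------------------------------------------------------------------
# Conflict-event filtering


def extract_conflict_zones(events: pd.DataFrame,
                           min_population: int = 10_000,
                           start_date: Optional[date] = None
                           ) -> list[tuple[str, int]]:
    """Conflict zones and their activation days from a battle-event table.

    Expects columns ``location, population, event_type, date``. A location
    becomes a conflict zone on the earliest day of an event labelled
    "battle"; settlements with fewer than ``min_population`` inhabitants
    and locations with no battles are excluded. Malformed rows are skipped
    (a count is logged).
    """
    required = {"location", "population", "event_type", "date"}
    missing = required - set(events.columns)
    if missing:
        raise ScenarioError(f"conflict event table missing columns {sorted(missing)}")
    bad = 0
    first_battle: dict[str, int] = {}
    pops: dict[str, float] = {}
    for row in events.itertuples(index=False):
        try:
            pop = float(row.population)
            day = _to_day(row.date, start_date)
            name = str(row.location)
            etype = str(row.event_type).strip().lower()
        except ScenarioError:
            raise  # missing start_date is a configuration error, not a bad row
        except (TypeError, ValueError):
            bad += 1
            continue
        pops[name] = pop
        if etype != "battle":
            continue
        if name not in first_battle or day < first_battle[name]:
            first_battle[name] = day
    if bad:
        log.info("extract_conflict_zones: skipped %d malformed rows", bad)
    return sorted((name, day) for name, day in first_battle.items()
                  if pops.get(name, 0) >= min_population)


def _to_day(value, start_date: Optional[date]) -> int:
    """Convert an integer day offset or ISO-8601 date to a 0-based day index."""
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, float) and float(value).is_integer():
        return int(value)
    text = str(value).strip()
    try:
        return int(text)
    except ValueError:
        pass
    parsed = datetime.strptime(text, "%Y-%m-%d").date()
    if start_date is None:
        raise ScenarioError(
            f"date {text!r} given but no start_date configured for the scenario")
    return (parsed - start_date).days


# ---------------------------------------------------------------------------
# Scenario bundle


@dataclass
class Scenario:
    """Everything a run needs: the graph, observed data, and the total curve."""

    graph: LocationGraph
    registrations: dict[str, RegistrationSeries] = field(default_factory=dict)
    total: Optional[RegistrationSeries] = None
    start_date: Optional[date] = None

    def total_series(self) -> Optional[RegistrationSeries]:
        """Insertion driver: explicit total curve, else aggregated registrations."""
        if self.total is not None:
            return self.total
        if self.registrations:
            return aggregate_total(list(self.registrations.values()))
        return None


def _read_csv(path: Path, required: set[str]) -> pd.DataFrame:
    if not path.exists():
        raise ScenarioError(f"missing scenario file: {path.name}")
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise ScenarioError(f"{path.name}: missing column(s) {sorted(missing)}")
    return df


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return int(value)


def load_scenario(directory: str | Path) -> Scenario:
    """Load and validate a scenario bundle from ``directory``.

    Schema violations raise :class:`ScenarioError` naming the file and the
    offending row; a connectivity warning (camps unreachable from conflict
    zones at day 0) is logged but not fatal.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ScenarioError(f"scenario directory not found: {directory}")

    start_date = None
    cfg_path = directory / "config.yaml"
    if cfg_path.exists():
        cfg = yaml.safe_load(cfg_path.read_text()) or {}
        if cfg.get("start_date"):
            start_date = date.fromisoformat(str(cfg["start_date"]))

    graph = LocationGraph()
    locs = _read_csv(directory / "locations.csv",
                     {"name", "country", "kind", "population", "capacity",
                      "foreign", "conflict_day"})
    for i, row in enumerate(locs.itertuples(index=False)):
        try:
            graph.add_location(Location(
                name=str(row.name),
                country=str(row.country),
                kind=LocationKind(str(row.kind)),
                population=int(row.population),
                capacity=_opt_int(row.capacity),
                foreign=_parse_bool(row.foreign),
                conflict_day=_opt_int(row.conflict_day),
            ))
        except (ValueError, KeyError) as exc:
            raise ScenarioError(f"locations.csv row {i + 2}: {exc}") from exc

    routes = _read_csv(directory / "routes.csv",
                       {"name_a", "name_b", "distance_km", "forced_redirection"})
    for i, row in enumerate(routes.itertuples(index=False)):
        try:
            graph.add_link(Link(
                endpoint_a=str(row.name_a),
                endpoint_b=str(row.name_b),
                distance_km=float(row.distance_km),
                forced_redirection=_parse_bool(row.forced_redirection),
            ))
        except (ValueError, KeyError) as exc:
            raise ScenarioError(f"routes.csv row {i + 2}: {exc}") from exc

    schedule = EventSchedule()
    closures_path = directory / "closures.csv"
    if closures_path.exists():
        closures = _read_csv(closures_path,
                             {"scope", "name_a", "name_b", "start_day", "end_day"})
        for i, row in enumerate(closures.itertuples(index=False)):
            try:
                _expand_closure(graph, schedule, row, start_date)
            except (ValueError, KeyError, ScenarioError) as exc:
                raise ScenarioError(f"closures.csv row {i + 2}: {exc}") from exc

    events_path = directory / "events.csv"
    if events_path.exists():
        events = _read_csv(events_path, {"day", "action", "name"})
        for i, row in enumerate(events.itertuples(index=False)):
            try:
                action = EventAction(str(row.action))
                if action not in (EventAction.OPEN_CAMP, EventAction.MARK_CONFLICT):
                    raise ValueError(f"action {action.value!r} not allowed in events.csv")
                schedule.add(_to_day(row.day, start_date), action, str(row.name))
            except (ValueError, KeyError) as exc:
                raise ScenarioError(f"events.csv row {i + 2}: {exc}") from exc

    try:
        graph.attach_schedule(schedule)
    except KeyError as exc:
        raise ScenarioError(f"event schedule: {exc}") from exc

    registrations: dict[str, RegistrationSeries] = {}
    reg_path = directory / "registrations.csv"
    if reg_path.exists():
        reg = _read_csv(reg_path, {"camp", "day", "count"})
        for camp, group in reg.groupby("camp", sort=False):
            days = [_to_day(d, start_date) for d in group["day"]]
            registrations[str(camp)] = RegistrationSeries.from_points(
                str(camp), zip(days, group["count"].astype(float)))

    total = None
    total_path = directory / "total.csv"
    if total_path.exists():
        tot = _read_csv(total_path, {"day", "count"})
        days = [_to_day(d, start_date) for d in tot["day"]]
        total = RegistrationSeries.from_points(
            "total", zip(days, tot["count"].astype(float)))

    graph.check_connectivity(day=0)
    return Scenario(graph=graph, registrations=registrations, total=total,
                    start_date=start_date)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float)):
        return bool(int(value))
    return str(value).strip().lower() in ("true", "1", "yes")


def _expand_closure(graph: LocationGraph, schedule: EventSchedule, row,
                    start_date: Optional[date]) -> None:
    """Expand a closure row to link-level close events.

    scope=link closes one link, scope=location closes every link of a
    location, scope=country closes every link joining the two named
    countries. End day may be blank (= forever).
    """
    scope = str(row.scope).strip().lower()
    start = _to_day(row.start_day, start_date)
    end = INF_END if _is_blank(row.end_day) else _to_day(row.end_day, start_date)
    if scope == "link":
        graph.find_link(str(row.name_a), str(row.name_b))
        schedule.add(start, EventAction.CLOSE_LINK,
                     str(row.name_a), str(row.name_b), str(end))
    elif scope == "location":
        name = str(row.name_a)
        if name not in graph.locations:
            raise ScenarioError(f"unknown location {name!r}")
        for link in graph.links_of(name):
            schedule.add(start, EventAction.CLOSE_LINK,
                         link.endpoint_a, link.endpoint_b, str(end))
    elif scope == "country":
        ca, cb = str(row.name_a), str(row.name_b)
        matched = False
        for link in graph.links:
            countries = {graph.locations[link.endpoint_a].country,
                         graph.locations[link.endpoint_b].country}
            if countries == {ca, cb}:
                schedule.add(start, EventAction.CLOSE_LINK,
                             link.endpoint_a, link.endpoint_b, str(end))
                matched = True
        if not matched:
            log.warning("country closure %s-%s matches no links", ca, cb)
    else:
        raise ScenarioError(f"unknown closure scope {scope!r}")


INF_END = 10 ** 9  # sentinel "never reopens" end day


def _is_blank(value) -> bool:
    return value is None or value == "" or (
        isinstance(value, float) and np.isnan(value))


# ---------------------------------------------------------------------------
# Writers


def write_scenario(scenario: Scenario, directory: str | Path) -> Path:
    """Write a scenario bundle; ``load_scenario(write_scenario(x)) == x``
    on the canonical schema (closures already compiled into windows are
    emitted as closure rows)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g = scenario.graph

    pd.DataFrame([{
        "name": l.name, "country": l.country, "kind": l.declared_kind.value,
        "population": l.population,
        "capacity": "" if l.capacity is None else l.capacity,
        "foreign": l.foreign,
        "conflict_day": "" if l.conflict_day is None else l.conflict_day,
    } for l in g.locations.values()]).to_csv(directory / "locations.csv", index=False)

    pd.DataFrame([{
        "name_a": k.endpoint_a, "name_b": k.endpoint_b,
        "distance_km": k.distance_km, "forced_redirection": k.forced_redirection,
    } for k in g.links]).to_csv(directory / "routes.csv", index=False)

    closure_rows = []
    for link in g.links:
        closure_rows.extend(_windows_to_closures(link))
    if closure_rows:
        pd.DataFrame(closure_rows).to_csv(directory / "closures.csv", index=False)

    event_rows = [{"day": e.day, "action": e.action.value, "name": e.payload[0]}
                  for e in g.schedule
                  if e.action in (EventAction.OPEN_CAMP, EventAction.MARK_CONFLICT)]
    if event_rows:
        pd.DataFrame(event_rows).to_csv(directory / "events.csv", index=False)

    if scenario.registrations:
        rows = [{"camp": s.camp_name, "day": d, "count": c}
                for s in scenario.registrations.values()
                for d, c in zip(s.days, s.counts)]
        pd.DataFrame(rows).to_csv(directory / "registrations.csv", index=False)

    if scenario.total is not None:
        pd.DataFrame({"day": scenario.total.days,
                      "count": scenario.total.counts}
                     ).to_csv(directory / "total.csv", index=False)

    if scenario.start_date is not None:
        (directory / "config.yaml").write_text(
            yaml.safe_dump({"start_date": scenario.start_date.isoformat()}))
    return directory


def _windows_to_closures(link: Link) -> list[dict]:
    """Complement the open windows of a link into closure rows."""
    rows = []
    cursor = 0.0
    for a, b in sorted(link.open_windows):
        if a > cursor:
            rows.append({"scope": "link", "name_a": link.endpoint_a,
                         "name_b": link.endpoint_b,
                         "start_day": int(cursor), "end_day": int(a)})
        cursor = max(cursor, b)
    if cursor != np.inf and cursor < INF_END:
        rows.append({"scope": "link", "name_a": link.endpoint_a,
                     "name_b": link.endpoint_b,
                     "start_day": int(cursor), "end_day": ""})
    return rows


def write_output(result: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-day run/validation table to CSV (column order preserved)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.to_csv(path, index=False)
    return path
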