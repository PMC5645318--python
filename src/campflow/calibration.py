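"""Data assimilation: registration-driven insertion, debt, spawn choice, scaling.

The simulation does not model departure decisions; instead the observed
total registration curve dictates how many agents enter the system each
day (the daily increase of the interpolated total). Decreases in the
total accumulate as a "refugee debt" that later increases must pay off
before new agents are inserted — agents are never deleted. Because the
interpolated curve is real-valued, the fractional part of each day's
insertion is carried forward so long-run totals are preserved exactly.

Agents enter at a conflict zone chosen with probability proportional to
its remaining population; the chosen zone's population is decremented by
one per agent (floored at zero, with a uniform fallback once every active
zone is exhausted).

Because agents are inserted on the day of registration but travel takes
time, raw in-camp counts underestimate the observed totals; the reporting
correction multiplies each camp count by N_data_all / N_sim_all. It is a
reporting transform only and never feeds back into the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .geography import Location
from .scenario_io import RegistrationSeries


@dataclass(frozen=True)
class DebtLedger:
    """Insertion bookkeeping: outstanding debt and fractional carry.

    ``debt`` >= 0 is the number of agents owed after registration
    decreases (integral whenever the deltas are integral); ``carry`` in
    [0, 1) is the fractional remainder of interpolated deltas.
    """

    debt: float = 0.0
    carry: float = 0.0

    def __post_init__(self) -> None:
        if self.debt < 0:
            raise ValueError("debt must be >= 0")
        if not 0.0 <= self.carry < 1.0:
            raise ValueError("carry must be in [0, 1)")


def daily_insertions(total_series: RegistrationSeries, day: int,
                     ledger: DebtLedger) -> tuple[int, DebtLedger]:
    """Number of agents to insert on ``day`` and the updated ledger.

    delta = total(day) - total(day-1) + carry. A negative delta adds to
    the debt and inserts nothing; a positive delta first pays the debt,
    then the integer part of the remainder is inserted and the fraction
    carried. Days before the series start contribute delta 0 (the
    interpolation clamps, so the difference vanishes there).
    """
    delta = float(total_series.interpolate(day)
                  - total_series.interpolate(day - 1)) + ledger.carry
    if delta < 0:
        return 0, DebtLedger(debt=ledger.debt - delta, carry=0.0)
    paid = min(delta, ledger.debt)
    remainder = delta - paid
    count = int(np.floor(remainder))
    carry = remainder - count
    if carry >= 1.0:  # guard against float round-up at the boundary
        count, carry = count + 1, 0.0
    return count, DebtLedger(debt=ledger.debt - paid, carry=carry)


def choose_spawn_zone(conflict_zones: Sequence[Location],
                      rng: np.random.Generator) -> Location:
    """Pick an insertion site among active conflict zones.

    The draw is proportional to current population; once all active zones
    are depleted the choice is uniform. The chosen zone's population is
    decremented by one (floored at zero).
    """
    if not conflict_zones:
        raise ValueError("no active conflict zone to spawn from")
    weights = np.array([max(z.population, 0) for z in conflict_zones], dtype=float)
    total = weights.sum()
    if total == 0:
        weights[:] = 1.0
        total = weights.sum()
    # single uniform draw inverted against cumulative weights
    u = rng.random() * total
    idx = int(np.searchsorted(np.cumsum(weights), u, side="right"))
    idx = min(idx, len(conflict_zones) - 1)
    zone = conflict_zones[idx]
    zone.population = max(zone.population - 1, 0)
    return zone


@dataclass(frozen=True)
class ScaledCounts:
    """Per-camp counts after the reporting correction.

    ``scaled`` is False on degenerate days (no agents in camps yet), where
    the raw counts are passed through unchanged.
    """

    counts: dict[str, float]
    scaled: bool = True


def scale_output(camp_counts: Mapping[str, float], n_data_all: float,
                 n_sim_all: float) -> ScaledCounts:
    """Multiply each camp count by N_data_all / N_sim_all.

    Compensates the travel-time lag between insertion and camp arrival.
    With ``n_sim_all`` = 0 the day is flagged unscalable and counts are
    returned unchanged.
    """
    if n_data_all < 0:
        raise ValueError("n_data_all must be >= 0")
    if n_sim_all == 0:
        return ScaledCounts(dict(camp_counts), scaled=False)
    factor = n_data_all / n_sim_all
    return ScaledCounts({k: v * factor for k, v in camp_counts.items()})
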