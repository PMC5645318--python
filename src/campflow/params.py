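"""Simulation parameters.

All behavioural constants of the agent model live in one frozen-by-convention
dataclass so that a run is fully described by (scenario, parameters, seed).
The defaults are the model's published operating point: move chances of
1.0 / 1.0 / 0.001 / 0.3 for agents in transit, in conflict zones, in camps
and everywhere else; destination attractiveness 0.25 / 1.0 / 2.0 for
conflict zones, other in-country locations and locations abroad; and a
travel budget of 200 km per day.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass
class SimulationParameters:
    """Behavioural constants of the displacement model.

    Attributes
    ----------
    movechance_transit:
        Daily probability that an agent partway along a link keeps moving.
    movechance_conflict:
        Daily probability of leaving a conflict zone.
    movechance_camp:
        Daily probability of leaving a camp (1/1000 ~ an average stay of
        1000 days; the model is insensitive to values <= 0.01).
    movechance_default:
        Daily probability of leaving any other location (towns, hubs
        without forced redirection).
    attract_conflict, attract_incountry, attract_abroad:
        Destination-class weights entering route choice as
        attractiveness / distance_km.
    max_km_per_day:
        Travel budget per agent per day; multi-hop journeys are allowed
        until it is spent.
    capacity_rule:
        Optional: a camp at or above capacity behaves like an ordinary
        location (move chance reverts to ``movechance_default``). Off by
        default.
    seed:
        Seed of the single global pseudo-random stream.
    """

    movechance_transit: float = 1.0
    movechance_conflict: float = 1.0
    movechance_camp: float = 0.001
    movechance_default: float = 0.3
    attract_conflict: float = 0.25
    attract_incountry: float = 1.0
    attract_abroad: float = 2.0
    max_km_per_day: float = 200.0
    capacity_rule: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("movechance_transit", "movechance_conflict",
                     "movechance_camp", "movechance_default"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        for name in ("attract_conflict", "attract_incountry", "attract_abroad"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_km_per_day <= 0:
            raise ValueError("max_km_per_day must be > 0")

    def replace(self, **overrides: float | bool | int) -> "SimulationParameters":
        """Return a copy with the given fields overridden.

        Unknown field names raise ``ValueError`` (used by CLI overrides and
        parameter sweeps, where a typo must not silently do nothing).
        """
        valid = {f.name for f in fields(self)}
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data.update(overrides)
        return SimulationParameters(**data)
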