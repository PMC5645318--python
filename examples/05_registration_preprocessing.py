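"""Preprocess camp registration exports into model inputs.

Shows the three refinement rules applied to observed registration data:
linear interpolation between sparse data points, rescaling of
provisional (level-1) counts onto the first verified (level-2) count,
and aggregation of per-camp series into the total curve that drives
agent insertion. Also extracts conflict zones from a battle-event table.
"""

import pandas as pd

from campflow import (RegistrationSeries, aggregate_total,
                      extract_conflict_zones, rescale_level1)

camp = RegistrationSeries.from_points(
    "East", [(0, 60.0), (5, 120.0), (10, 100.0), (15, 130.0)],
    level_split_day=10)
fixed = rescale_level1(camp)
print("level-1 rescaling:", camp.counts, "->", fixed.counts)
print("  (the provisional segment is scaled by 100/120 to meet the first")
print("   verified count; verified points are untouched)")

other = RegistrationSeries.from_points("West", [(3, 30.0), (12, 75.0)])
total = aggregate_total([fixed, other])
print("aggregate total knots:", list(zip(total.days, total.counts)))
print("interpolated total at day 7:", total.interpolate(7))

events = pd.DataFrame({
    "location": ["Capital", "Village", "Capital", "Port"],
    "population": [500_000, 4_000, 500_000, 60_000],
    "event_type": ["battle", "battle", "battle", "riot"],
    "date": [14, 2, 3, 5],
})
zones = extract_conflict_zones(events)
print("conflict zones (name, first-battle day):", zones)
print("  (settlements under 10,000 people and riot-only locations drop out;")
print("   the earliest battle sets the activation day)")
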