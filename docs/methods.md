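# Methods

## Model

campflow is a discrete-time (one step = one day) agent-based model of
forced displacement on a location graph. It deliberately models only the
distribution of arrivals across destination camps, taking the total
number of displaced people over time as a known input; it does not model
the decision to flee, internally displaced people, or demographic
structure.

**Locations** are classified as conflict zones, camps, forwarding hubs or
towns. Classification is time-dependent: a town becomes (and stays) a
conflict zone on the day of its first battle; a camp scheduled to open
later behaves as a town until the opening day. **Links** are undirected,
carry an exogenous length in kilometres, and are traversable only inside
open windows. Closures may be declared per link, per location (all its
links) or per country pair (all cross-border links); they are expanded to
link-level windows at load time, which makes replaying the schedule
idempotent by construction. A link that only opens mid-run is expressed
as a closure over `[0, open_day)`. Agents already on a link when it
closes finish the traversal; closures block new entries only.

**Agents** are inserted at conflict zones (population-proportional
choice, population decremented per spawn, uniform fallback once all
active zones are depleted) and never deleted. Each day an agent in
transit continues forward; an agent at a location draws once against the
class move chance and, on success, chooses among open links with weight
`attractiveness(destination) / distance_km`. Arrival with leftover daily
budget triggers a fresh draw, so multi-hop days occur up to the travel
limit; a forwarding hub compels its single designated onward link with
no draw. An agent can revisit locations on later days — route choice is
Markovian in the stated weights, with no path memory.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `movechance_transit` | 1.0 | daily probability of continuing mid-link |
| `movechance_conflict` | 1.0 | daily probability of leaving a conflict zone |
| `movechance_camp` | 0.001 | daily probability of leaving a camp (mean stay ≥ 1000 days) |
| `movechance_default` | 0.3 | daily probability of leaving any other location |
| `attract_conflict` | 0.25 | route weight of a conflict-zone destination |
| `attract_incountry` | 1.0 | route weight of other in-country destinations |
| `attract_abroad` | 2.0 | route weight of destinations abroad |
| `max_km_per_day` | 200.0 | per-agent daily travel budget (km) |
| `capacity_rule` | off | camp at capacity reverts to `movechance_default` |

The defaults are the model's published operating point and are asserted
field-for-field in the test suite. `capacity_rule` is an optional
extension (off by default): the base rules say nothing about full camps,
but observed outflow from camps near capacity motivates offering the
switch explicitly rather than hiding the behaviour.

## Calibration and reporting

Daily insertions equal the day-over-day increase of the linearly
interpolated total-registration curve. The fractional part of each
interpolated delta is carried forward (a carry in [0,1)) rather than
rounded per day, so long-run insertion totals are preserved exactly.
Negative deltas accumulate a refugee debt that later increases repay
before any insertion; the ledger satisfies the exact identity
`inserted + carry − debt = Σ deltas` after every prefix of days, which a
property test checks over random mixed-sign sequences. The debt is
stored as a real number because a fractional carry can make a negative
delta fractional; with integer deltas it is always integral.

Reported per-camp predictions are multiplied by `N_data,all / N_sim,all`
to correct the travel-time lag between insertion and arrival. This is a
reporting transform only — it never feeds back into the dynamics — and
raw counts are always retained alongside. Days with no agents in camps
are flagged unscalable and passed through unchanged.

## Registration preprocessing

Observed camp series are interpolated linearly between data points, with
constant extension outside the observed range. Provisional (level-1)
registration segments are multiplied by
`first level-2 count / last level-1 count` so the segments meet, leaving
the verified segment bit-identical; a zero last level-1 count skips the
rescale with a warning. The total curve is the day-wise sum of the
interpolated per-camp series over the union of knot days. Conflict zones
come from a battle-event table: the earliest "battle" event sets the
activation day, settlements under 10,000 inhabitants and locations
without battles are dropped, and malformed rows are skipped with a
logged count.

## Validation metrics

`E(t) = Σ_x |n_sim − n_data| / N_data,all` over the union of camps in
the simulation and the data (missing series count as zero; camps not yet
open contribute zero). Days with a zero observed total are defined as
E = 0 when all counts vanish and flagged (NaN, excluded from averages)
otherwise.

MASE is implemented with the literal normalisers `1/T` and `1/(T−w)`
over inclusive sums (t = 0..T has T+1 terms). This printed form slightly
overweights both averages relative to true means; a `true_mean` flag
switches to `T+1` / `T−w+1` denominators for users who prefer unbiased
means. The two agree when w = 0 up to a common factor and are both
covered by tests. Naive forecasters are evaluated only on t ∈ [w, T],
matching the denominator's range, and forecasts are floored at zero. The
fraction model with a zero day-w total falls back to equal shares
(flagged). Weighted aggregation across conflicts is `Σ w·m / Σ w` with
strictly positive weights and exact key matching.

## Synthetic scenarios and twin experiments

The generator emulates the structure of real conflict networks: a
connected interior (conflict zones + towns, random spanning tree plus
roughly n/3 chord links, distances uniform in 40–180 km), camps abroad
each attached to one interior node by a single direct link, optional
forwarding hubs, optional random closures, and a linear or logistic
cumulative arrival curve. Defaults — 3 conflict zones, 4 camps, 8 towns,
5,000 agents over 100 days — are the desk-scale study condition used
throughout the tests: large enough that multinomial route noise is a few
percent of the population, small enough that the whole suite runs in
seconds. Without coordinates, "attach each camp to the nearest interior
node" is emulated by a seeded random choice of anchor; distances are
exogenous per link throughout, so no geometry is implied.

Twin experiments store the *driving* total curve alongside the reference
run's raw in-camp counts as "observed" registrations. Because the
validation run is driven by the same curve, an identical seed reproduces
the reference trajectory bit-exactly (E ≡ 0), and a different seed
isolates pure stochastic error. Twin validation evaluates E(t) on scaled
counts — the quantity the model actually reports — where the scaling
ratio is ≈ 1 by construction. What passing twin tests shows is that the
pipeline is self-consistent and its stochastic noise floor is low
(mean E ≈ 0.03–0.06 at 5,000 agents); it does not show that the
behavioural rules match real decision-making, which requires real
registration data.

## Numerical and design choices

- One global `numpy` PCG64 stream, seeded once per run; agents step in
  creation order, insertion precedes movement each day. Two runs with the
  same scenario, parameters and seed are bit-identical.
- Weighted choices (routes, spawn zones) invert a single uniform draw
  against cumulative weights; candidate order is routes-file load order,
  making tie-breaks deterministic.
- Link completion uses a 1e-9 km tolerance so budget arithmetic cannot
  strand an agent infinitesimally short of a node.
- A simulation deep-copies its graph at construction (populations and
  materialised kinds mutate during a run), so scenarios are reusable.
- Day indices are 0-based; ISO dates in input tables are converted via a
  scenario-level start date.
- The day-0 connectivity check (every camp reachable from every conflict
  zone) warns rather than fails: partially disconnected networks are
  legitimate mid-conflict states.

## Limitations

- Agent behaviour ignores factors known to matter empirically (GDP,
  ethnicity, religion, information access); the model is deliberately
  parameter-light.
- The synthetic generator produces idealised topologies and smooth
  arrival curves; real registration data are bursty, revised
  retroactively, and reported at irregular intervals. Twin-experiment
  results bound stochastic error only.
- Camp capacity handling is a coarse optional rule, not a queueing model.
- The forwarding-hub rule assumes the redirect link stays open; a closed
  redirect strands arrivals at the hub until it reopens.
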