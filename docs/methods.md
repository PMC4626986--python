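# Methods

## Model overview

The region is a lattice of square cells; a cell may hold the hub (one,
where all ambulances are based), a hospital, a town, and/or a road.  A
parallel per-cell *traversal time* in minutes defines the travel metric:
moving from a cell into a 4-neighbour costs the effective traversal time
of the cell entered, so the duration of a path is the sum of the
effective times of the cells entered.  Shortest-time fields and routes
are exact single-source Dijkstra solutions (scipy's sparse-graph solver
over precomputed edge arrays); route reconstruction walks back from the
destination choosing, among cost-consistent predecessors, the
lexicographically smallest cell, which makes tie-breaking deterministic.

Effective traversal times layer penalties on the base time:

| source                | effect                                   |
|-----------------------|------------------------------------------|
| weather event         | × factor (rain 2, snow 3, fog 3, ice 4)  |
| simultaneous weather  | combined by **max**, not product         |
| congestion overlay    | × 2 on the accident cell + 8 neighbours  |
| festivity / closure   | × 2                                      |
| stress multiplier     | × s (sensitivity analysis, default 1)    |

Weather combines by max because no composition rule is published for
overlapping events and multiplying factors (snow + fog = ×9) is
implausible; congestion and festivity each still double on top, as they
are stated independently of weather.  Penalties are frozen at the
departure instant for a whole leg: legs are short relative to event
durations (2–12 h), and freezing keeps each leg deterministic given the
event calendar.  Weather affects the entire road network — the source
data are province-wide day counts with no spatial resolution — and each
tabulated "event day" is realised as one event of the catalogue duration
starting uniformly within its month, with Poisson-many events per month.
A storm day count exists in the meteorology table but no storm penalty
is defined, so storms generate no events unless a user maps them onto a
defined type; ice has a penalty but zero recorded days.

## Stochastic inputs

* **Accidents.** Per (road segment, month) Poisson arrivals: exponential
  inter-arrival times with rate λ/month-length, re-drawn at month
  rollovers (memorylessness makes monthly counts exactly Poisson(λ)).
  The accident cell is uniform over the segment's cells.
* **Service times** (minutes): preparation ~ lognormal with log-scale
  parameters (2.5, 1) — the conventional reading of "lognormal(2.5, 1)",
  giving a median of e^2.5 ≈ 12.2 min; an alternative mean/sd reading is
  a config switch.  On-scene ~ uniform(23.2, 37.2); hospital hand-over ~
  triangular(12.7, 13.7, 21.9), read as (min, mode, max) since that is
  the only ascending assignment.
* **Population.**  Each town's population is concentrated in its single
  cell.  On weekends and local holidays the month's hotel stays — split
  across towns proportionally to static population and spread uniformly
  over that month's weekend/holiday days — are added, and the result is
  raised 20% for floating population; plain weekdays carry the static
  population.  Weekends follow the real 2014 calendar; holiday and
  road-closure day *counts* per month are turned into concrete days by
  even spreading, since the sources publish counts, not dates.

Randomness is organised as four named substreams (accidents, weather,
service, population) seeded from (master seed, replication).  Accident
times, accident cells and service triples are drawn independently of the
dispatch process, so configurations differing only in the ambulance
count consume identical randomness — the common-random-numbers contract
that underlies all cross-staffing comparisons.

## The event engine

A future-event list drives the run: month rollovers (rate re-pricing),
day rollovers (population and festivity updates), weather starts/ends,
congestion expiries, stage ends and accidents, with simultaneous events
ordered by that fixed type priority.  Dispatch is FIFO over accidents;
among free units the one with the smallest current travel time to the
scene wins, ties by unit id.  A unit serves the six-task cycle and, by
default, becomes dispatchable only on returning to the hub; a
dispatch-from-hospital variant is a config flag (default off; in that
variant the unit simply waits at the hospital until the next call).
Congestion around a scene lasts from the accident until 60 minutes
(configurable) after the serving unit leaves it.  An accident whose cell
cannot be reached from the hub is flagged "uncoverable" rather than
silently dropped.  Each accident requires a fixed configurable number of
units (default 1).

The dynamic rescue field is, per cell, the minimum over units of travel
time from the unit's location (free units) or remaining-time-to-
availability plus travel from the availability cell (busy units).  The
published description of the busy-unit penalty is ambiguous; the
remaining-time reading matches the surrounding text's intent, and the
literal alternative (travel from the unit's current position to its
availability point) is a config variant.

Indicator collection is piecewise: at every state-changing event plus a
5-minute tick grid.  Between events the hub field is constant and the
waiting penalty decays linearly, so tick values are evaluated vectorised
per inter-event interval — numerically identical to queueing individual
tick events, at a fraction of the cost.  φ_k uses the instantaneous
effective populations; time averages are left-constant between
collection points.  Cross-replication aggregation reports means and
standard deviations; availability is the mean free-time fraction across
units.

## Fixture design

The real travel-time matrix of the province was originally extracted
from an online routing service and never published, so the bundled
scenario uses a synthetic star network: 18 arms of 50 one-minute cells
(one arm per rated road, joined by a near-zero-cost connector), hub and
hospital co-located.  Placements honour every published band — the
capital (58,933 inhabitants) at 5 min, Navaluenga in (30, 40] at 35 min,
Hoyo de Pinares in (40, 50] at 45 min — and the unpublished ones are
declared fixture choices: El Tiemblo 15, El Barraco 25, Piedrahita 45
min.  The six named towns hold 90% of the total population; the
remaining 10% sits in three synthetic settlements at 12, 22 and 32 min,
outside the 10-minute and inside the 50-minute isochrone.  This
reproduces the static indicators exactly (φ_10 rounds to 75%, φ_50 =
100%) while dynamic headline percentages are only qualitatively
comparable: the synthetic network is more compact than the real one, so
simulated availability and coverage run higher than the published
values, but their orderings across staffing levels (the substance of the
deployment analysis) are preserved and asserted by the test suite.

A known inconsistency in the published accident table: its TOTAL row
does not equal the sum of its 18 road rows in any month (January: rows
sum to 60, the total prints 53).  The per-road rows are the model's
input — the generator is calibrated and tested per (segment, month) —
and the redundant printed total is reported as computed, not rescaled.

## Numerical choices and limitations

* Shortest-path cost is "cells entered"; fields from two cells with
  different traversal times are therefore asymmetric by the difference
  of the endpoint weights — symmetric on uniform-weight grids.
* Route reconstruction tolerates 1e-9 relative slack in cost equality.
* Accumulated coverage fractions are clipped to [0, 1] to absorb
  summation round-off (~1e-12 over ~10^5 intervals).
* Busy-unit availability times are estimates (remaining legs priced at
  the current instant, replaced by actuals as each leg starts); they
  only affect the indicator's waiting penalty, never the event logic.
* Per-accident response-time monotonicity in the ambulance count holds
  for all but ~0.03% of accidents under common random numbers: because
  legs are priced at departure, an earlier dispatch can fall inside a
  weather penalty that a later one would have avoided.  This is a
  property of time-varying travel prices, not of the queueing logic.
* The simulation does not model spatially heterogeneous weather,
  day-of-week accident modulation, redeployment/diversion decisions, or
  geographic fidelity to the real road map; the GeoJSON export uses
  abstract grid coordinates with a configurable cell size and claims no
  real-world CRS.
* Default problem sizes: 365-day horizon, 20 replications, 1,000
  simulated months for generator calibration, 30-day static runs for
  town-coverage checks; all are the package's standard experiment
  conditions and complete in minutes on a single core.
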