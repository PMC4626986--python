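"""Seeded random generators calibrated to the scenario tables.

Four named substreams (accidents, weather, service, population) are
derived from a (master seed, replication) pair via ``numpy`` seed
sequences.  The same master seed therefore yields bit-identical event
calendars, and because accident occurrences, accident cells and service
triples are all drawn independently of the dispatch process, runs that
differ only in the ambulance count share identical randomness — the
common-random-numbers contract used to compare staffing levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import PenaltyOverlay
from .scenario import (
    AccidentRateTable,
    Calendar,
    ServiceTimeSpec,
    TownRecord,
    WeatherSpec,
)

_STREAM_NAMES = ("accidents", "weather", "service", "population")


class RandomStream:
    """Named independent substreams derived from (master seed, replication)."""

    def __init__(self, master_seed: int, replication: int = 0):
        self.master_seed = int(master_seed)
        self.replication = int(replication)
        self._rngs = {
            name: np.random.default_rng(
                np.random.SeedSequence([self.master_seed, self.replication, i])
            )
            for i, name in enumerate(_STREAM_NAMES)
        }

    def rng(self, name: str) -> np.random.Generator:
        return self._rngs[name]

    @property
    def accidents(self) -> np.random.Generator:
        return self._rngs["accidents"]

    @property
    def weather(self) -> np.random.Generator:
        return self._rngs["weather"]

    @property
    def service(self) -> np.random.Generator:
        return self._rngs["service"]

    @property
    def population(self) -> np.random.Generator:
        return self._rngs["population"]


# -- accidents ----------------------------------------------------------------

def next_accident_time(
    now: float,
    segment: str,
    month: int,
    rates: AccidentRateTable,
    month_length_minutes: float,
    rng: np.random.Generator,
) -> float:
    """Next accident instant on ``segment`` after ``now`` (sim-minutes).

    Arrivals within a month form a Poisson process whose monthly count has
    the tabulated mean, i.e. exponential inter-arrivals with rate
    lambda / month-length.  A zero rate yields +inf (no accident).
    """
    lam = rates.rates[segment][month]
    if lam < 0:
        raise ValueError(f"negative rate for {segment}")
    if lam == 0:
        return np.inf
    return now + rng.exponential(month_length_minutes / lam)


def simulate_monthly_accident_counts(
    rates: AccidentRateTable,
    month: int,
    n_months: int,
    rng: np.random.Generator,
    month_length_minutes: float = 31 * 1440.0,
) -> np.ndarray:
    """Accident counts per simulated month, (n_months, n_segments).

    Runs the inter-arrival generator for each segment over ``n_months``
    independent months — the calibration-recovery experiment.
    """
    segs = rates.segments
    out = np.zeros((n_months, len(segs)), dtype=np.int64)
    for j, seg in enumerate(segs):
        for i in range(n_months):
            t, n = 0.0, 0
            while True:
                t = next_accident_time(t, seg, month, rates, month_length_minutes, rng)
                if t >= month_length_minutes:
                    break
                n += 1
            out[i, j] = n
    return out


# -- weather ------------------------------------------------------------------

def sample_weather_calendar(
    month: int,
    spec: WeatherSpec,
    rng: np.random.Generator,
    month_start_minutes: float,
    month_length_minutes: float,
) -> list[PenaltyOverlay]:
    """Adverse-weather overlays for one month.

    Each tabulated event-day counts as one event of the catalogue
    duration: the number of events in the month is Poisson with the
    tabulated mean, each starting uniformly within the month and covering
    the whole road network.  Types without a penalty definition are
    skipped.  Overlays are returned sorted by start time.
    """
    overlays: list[PenaltyOverlay] = []
    for etype in spec.active_types:
        mean = spec.monthly_days[etype][month]
        if mean <= 0:
            continue
        ev = spec.events[etype]
        if ev.penalty_factor == 1:  # the "static" baseline is not an event
            continue
        n = int(rng.poisson(mean))
        starts = month_start_minutes + rng.uniform(0, month_length_minutes, size=n)
        overlays.extend(
            PenaltyOverlay(
                cells=None,
                factor=ev.penalty_factor,
                start=float(s),
                end=float(s) + ev.duration_minutes,
                cause=etype,
            )
            for s in starts
        )
    overlays.sort(key=lambda ov: (ov.start, ov.cause))
    return overlays


# -- service times ------------------------------------------------------------

def sample_service_times(
    spec: ServiceTimeSpec,
    stress: float,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """(prep, on-scene, hospital) minutes; the stress multiplier scales each."""
    if spec.prep_log_scale:
        mu, sigma = spec.prep_mu, spec.prep_sigma
    else:  # convert mean/sd of the lognormal itself to log-scale parameters
        m, s = spec.prep_mu, spec.prep_sigma
        sigma = float(np.sqrt(np.log1p((s / m) ** 2)))
        mu = float(np.log(m) - 0.5 * sigma**2)
    prep = rng.lognormal(mu, sigma)
    on_scene = rng.uniform(spec.on_scene_low, spec.on_scene_high)
    hospital = rng.triangular(spec.hospital_min, spec.hospital_mode, spec.hospital_max)
    return prep * stress, on_scene * stress, hospital * stress


# -- population dynamics ------------------------------------------------------

@dataclass(frozen=True)
class PopulationSnapshot:
    """Effective per-town population at one instant."""

    town_names: tuple[str, ...]
    populations: np.ndarray        # persons, aligned with town_names
    instant: float                 # sim-minutes

    @property
    def total(self) -> float:
        return float(self.populations.sum())


def population_at(
    day: int,
    towns: list[TownRecord],
    calendar: Calendar,
) -> PopulationSnapshot:
    """Effective populations on a given day (0-based from Jan 1).

    Weekends and local holidays receive the month's hotel stays — spread
    uniformly over the month's weekend/holiday days, already split per
    town proportionally to population — and a 20% floating-population
    uplift; plain weekdays carry the static populations.
    """
    if not 0 <= day < calendar.n_days:
        raise ValueError(f"day {day} outside the calendar year")
    month = int(calendar.month_of_day[day])
    pops = np.array([t.static_population for t in towns], dtype=float)
    if calendar.is_uplift_day(day):
        n_event_days = max(int(calendar.event_days_in_month[month]), 1)
        shares = np.array(
            [t.monthly_hotel_share[month] for t in towns], dtype=float
        )
        pops = (pops + shares / n_event_days) * 1.2
    return PopulationSnapshot(
        town_names=tuple(t.name for t in towns),
        populations=pops,
        instant=day * 1440.0,
    )
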