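"""Scenario parameterisation: towns, rates, weather, service times, calendar.

A :class:`Scenario` bundles everything a simulation run needs: the road
grid, per-road monthly accident rates, town populations with monthly hotel
stays, the weather event model, service-time distributions, the day
calendar (weekends, local holidays, road closures), the ambulance count
and the isochrone thresholds.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace

import numpy as np

from .grid import Cell, RoadGrid

MONTHS = ("JAN", "FEB", "MAR", "APR", "MAY", "JUN",
          "JUL", "AUG", "SEP", "OCT", "NOV", "DEC")

MINUTES_PER_DAY = 1440.0


class ScenarioError(ValueError):
    """Invalid scenario configuration or tables."""


@dataclass(frozen=True)
class TownRecord:
    """A populated cell: static inhabitants plus a monthly hotel-stay share.

    ``monthly_hotel_share`` holds, per calendar month, the persons of the
    province-wide hotel stays assigned to this town (proportional to its
    static population at bundle-build time).
    """

    name: str
    cell: Cell
    static_population: float
    monthly_hotel_share: tuple[float, ...] = (0.0,) * 12

    def __post_init__(self) -> None:
        if self.static_population <= 0:
            raise ScenarioError(f"{self.name}: static population must be > 0")
        if len(self.monthly_hotel_share) != 12:
            raise ScenarioError(f"{self.name}: need 12 monthly hotel shares")
        if any(s < 0 for s in self.monthly_hotel_share):
            raise ScenarioError(f"{self.name}: hotel share must be >= 0")


@dataclass(frozen=True)
class AccidentRateTable:
    """Per (road segment, month) mean accident counts and segment geometry."""

    rates: dict[str, tuple[float, ...]]          # segment -> 12 monthly means
    segment_cells: dict[str, tuple[Cell, ...]]   # segment -> road cells

    def __post_init__(self) -> None:
        bad = [s for s, lam in self.rates.items() if any(x < 0 for x in lam)]
        if bad:
            raise ScenarioError(f"negative accident rate for segments {bad}")
        short = [s for s, lam in self.rates.items() if len(lam) != 12]
        if short:
            raise ScenarioError(f"segments without 12 monthly rates: {short}")
        empty = [s for s in self.rates if not self.segment_cells.get(s)]
        if empty:
            raise ScenarioError(f"segments without cells: {empty}")

    @property
    def segments(self) -> list[str]:
        return sorted(self.rates)

    def monthly_total(self, month: int) -> float:
        return float(sum(lam[month] for lam in self.rates.values()))


@dataclass(frozen=True)
class WeatherEvent:
    """One adverse event type: fixed duration and travel-time factor."""

    duration_minutes: float
    penalty_factor: float

    def __post_init__(self) -> None:
        if self.duration_minutes <= 0:
            raise ScenarioError("weather event duration must be > 0")
        if self.penalty_factor < 1:
            raise ScenarioError("weather penalty factor must be >= 1")


@dataclass(frozen=True)
class WeatherSpec:
    """Event catalogue plus mean event-days per (type, month).

    ``monthly_days`` rows without a matching catalogue entry (the data
    source may count phenomena, e.g. storms, for which no penalty is
    defined) are carried but never generate events.
    """

    events: dict[str, WeatherEvent]              # e.g. rain/snow/fog/ice
    monthly_days: dict[str, tuple[float, ...]]   # type -> 12 mean event-days

    def __post_init__(self) -> None:
        for name, days in self.monthly_days.items():
            if len(days) != 12:
                raise ScenarioError(f"weather type {name}: need 12 monthly values")
            if any(d < 0 for d in days):
                raise ScenarioError(f"weather type {name}: negative mean days")

    @property
    def active_types(self) -> list[str]:
        """Types that both have a penalty definition and monthly day counts."""
        return sorted(set(self.events) & set(self.monthly_days))


@dataclass(frozen=True)
class ServiceTimeSpec:
    """Distributions of the three stationary service stages, in minutes.

    ``prep`` is lognormal with *log-scale* parameters (mu, sigma); on-scene
    time is uniform; hospital drop-off is triangular (min, mode, max).
    ``prep_log_scale=False`` reads (mu, sigma) as the mean/sd of the
    distribution itself instead.
    """

    prep_mu: float = 2.5
    prep_sigma: float = 1.0
    prep_log_scale: bool = True
    on_scene_low: float = 23.2
    on_scene_high: float = 37.2
    hospital_min: float = 12.7
    hospital_mode: float = 13.7
    hospital_max: float = 21.9

    def __post_init__(self) -> None:
        if not self.on_scene_low < self.on_scene_high:
            raise ScenarioError("on-scene uniform bounds must satisfy low < high")
        if not (self.hospital_min <= self.hospital_mode <= self.hospital_max):
            raise ScenarioError("triangular parameters must satisfy min <= mode <= max")
        if min(self.on_scene_low, self.hospital_min) <= 0:
            raise ScenarioError("service times must be positive")


class Calendar:
    """Per-day flags over the horizon: weekend, local holiday, road closure.

    Local-holiday and road-closure day counts are given per month and
    assigned to concrete days by spreading them evenly through the month
    (a deterministic rule, since the sources publish counts, not dates).
    Weekends follow the real year (default 2014).
    """

    def __init__(
        self,
        year: int = 2014,
        holidays_per_month: tuple[int, ...] = (0,) * 12,
        closures_per_month: tuple[int, ...] = (0,) * 12,
    ):
        self.year = year
        self.holidays_per_month = tuple(int(x) for x in holidays_per_month)
        self.closures_per_month = tuple(int(x) for x in closures_per_month)
        first = _dt.date(year, 1, 1)
        self.month_days = tuple(
            ((_dt.date(year + (m == 11), (m + 1) % 12 + 1, 1) - _dt.date(year, m + 1, 1)).days)
            for m in range(12)
        )
        self.n_days = sum(self.month_days)
        self.month_of_day = np.repeat(np.arange(12), self.month_days)
        self.month_start_day = np.concatenate([[0], np.cumsum(self.month_days)[:-1]])
        weekday = np.array(
            [(first + _dt.timedelta(d)).weekday() for d in range(self.n_days)]
        )
        self.is_weekend = weekday >= 5
        self.is_holiday = np.zeros(self.n_days, dtype=bool)
        self.is_closure = np.zeros(self.n_days, dtype=bool)
        for m in range(12):
            self._spread(self.is_holiday, m, holidays_per_month[m])
            self._spread(self.is_closure, m, closures_per_month[m])
        uplift = self.is_weekend | self.is_holiday
        self.event_days_in_month = np.array(
            [int(uplift[self.days_of_month(m)].sum()) for m in range(12)]
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Calendar)
            and self.year == other.year
            and self.holidays_per_month == other.holidays_per_month
            and self.closures_per_month == other.closures_per_month
        )

    def _spread(self, flags: np.ndarray, month: int, count: int) -> None:
        n = self.month_days[month]
        if count > n:
            raise ScenarioError(f"month {month + 1}: {count} event days > {n} days")
        start = self.month_start_day[month]
        for i in range(count):
            flags[start + int((i + 0.5) * n / count)] = True

    def days_of_month(self, month: int) -> slice:
        s = int(self.month_start_day[month])
        return slice(s, s + self.month_days[month])

    def month_start_minutes(self, month: int) -> float:
        return float(self.month_start_day[month]) * MINUTES_PER_DAY

    def month_length_minutes(self, month: int) -> float:
        return self.month_days[month] * MINUTES_PER_DAY

    def is_uplift_day(self, day: int) -> bool:
        """Weekend or local holiday: floating-population uplift applies."""
        return bool(self.is_weekend[day] or self.is_holiday[day])


@dataclass
class Scenario:
    """Full parameterisation of one EMS deployment experiment."""

    name: str
    grid: RoadGrid
    towns: list[TownRecord]
    accident_rates: AccidentRateTable
    weather: WeatherSpec
    service_times: ServiceTimeSpec
    calendar: Calendar
    horizon_days: int = 365
    replications: int = 20
    seed: int = 1
    ambulance_count: int = 1
    thresholds: tuple[float, ...] = (10, 20, 30, 40, 50, 60)
    stress_multiplier: float = 1.0
    required_units: int = 1
    dispatch_from_hospital: bool = False
    congestion_extra_minutes: float = 60.0
    collection_tick_minutes: float = 5.0
    busy_penalty_mode: str = "remaining_time"  # or "travel_from_position"
    cell_size: float = 1.0                     # GeoJSON export scale

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ks = tuple(float(k) for k in self.thresholds)
        if not ks or any(k <= 0 for k in ks) or any(
            a >= b for a, b in zip(ks, ks[1:])
        ):
            raise ScenarioError("thresholds must be strictly ascending and > 0")
        if self.ambulance_count < 1:
            raise ScenarioError("ambulance count must be >= 1")
        if self.replications < 1:
            raise ScenarioError("replications must be >= 1")
        if self.stress_multiplier <= 0:
            raise ScenarioError("stress multiplier must be > 0")
        if self.horizon_days < 1 or self.horizon_days > self.calendar.n_days:
            raise ScenarioError("horizon must be within the calendar year")
        if self.required_units < 1:
            raise ScenarioError("required units must be >= 1")
        if self.busy_penalty_mode not in ("remaining_time", "travel_from_position"):
            raise ScenarioError(f"unknown busy penalty mode {self.busy_penalty_mode!r}")
        for town in self.towns:
            if not self.grid.is_road(town.cell):
                raise ScenarioError(f"town {town.name} cell {town.cell} not on grid")
        for seg, cells in self.accident_rates.segment_cells.items():
            off = [c for c in cells if not self.grid.is_road(c)]
            if off:
                raise ScenarioError(f"segment {seg} references non-road cells {off}")

    @property
    def horizon_minutes(self) -> float:
        return self.horizon_days * MINUTES_PER_DAY

    def with_(self, **changes) -> "Scenario":
        """A modified copy (ambulance count, stress, seed, ...)."""
        return replace(self, **changes)

    def static_populations(self) -> np.ndarray:
        return np.array([t.static_population for t in self.towns])

    def total_static_population(self) -> float:
        return float(self.static_populations().sum())
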