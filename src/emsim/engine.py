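"""Event-driven EMS core: future-event list, monthly/daily data updating,
accident generation, FIFO dispatch of the closest free ambulance, the
six-task ambulance lifecycle, and indicator accumulation.

The simulation clock runs in minutes.  Randomness comes from the named
substreams of :class:`~emsim.stochastics.RandomStream`; accident
occurrences, accident cells and service-time triples are drawn
independently of the dispatch process, so runs that differ only in the
ambulance count see identical random inputs (common random numbers).

Indicator accumulation is piecewise: between consecutive state-changing
events the rescue-time field from the hub is constant up to the waiting
penalty, which decays linearly, so the collection grid (every event plus
a fixed 5-minute tick) is evaluated vectorised per inter-event interval.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Cell, PenaltyOverlay, RoadGrid, UnreachableError
from .indicators import (
    IsochroneField,
    OccupationReport,
    occupation,
)
from .scenario import MINUTES_PER_DAY, Scenario
from .stochastics import (
    RandomStream,
    next_accident_time,
    population_at,
    sample_service_times,
    sample_weather_calendar,
)

# event type priorities for simultaneous events
_PRI = {
    "month": 0,
    "day": 1,
    "weather_start": 2,
    "weather_end": 3,
    "congestion_end": 4,
    "stage_end": 5,
    "accident": 6,
}

_STAGE_CYCLE = ("prep", "to_scene", "on_scene", "to_hospital", "at_hospital",
                "returning")


@dataclass
class AmbulanceState:
    """One unit: task stage, location, and when/where it next frees."""

    id: int
    cell: Cell
    stage: str = "free"
    stage_end: float = 0.0
    availability_time: float = 0.0
    availability_cell: Cell = None  # type: ignore[assignment]
    accident_id: int | None = None
    # estimated durations of the remaining lifecycle components; actuals
    # replace estimates as each leg is priced at its departure instant
    remaining: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.availability_cell is None:
            self.availability_cell = self.cell

    @property
    def free(self) -> bool:
        return self.stage == "free"


@dataclass
class AccidentRecord:
    """One accident: where/when it happened and how it was served."""

    id: int
    segment: str
    cell: Cell
    occurrence: float
    required_units: int = 1
    service: tuple[float, float, float] = (0.0, 0.0, 0.0)
    assignment_time: float | None = None
    ambulance_ids: list[int] = field(default_factory=list)
    scene_arrival: float | None = None
    clearance_time: float | None = None
    uncoverable: bool = False

    @property
    def response_time(self) -> float | None:
        if self.scene_arrival is None:
            return None
        return self.scene_arrival - self.occurrence


class EventQueue:
    """Time-ordered future events; ties by type priority, then insertion."""

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, int, str, tuple]] = []
        self._seq = itertools.count()

    def push(self, time: float, kind: str, payload: tuple = ()) -> None:
        heapq.heappush(self._heap, (time, _PRI[kind], next(self._seq), kind, payload))

    def pop(self) -> tuple[float, str, tuple]:
        time, _, _, kind, payload = heapq.heappop(self._heap)
        return time, kind, payload

    def __len__(self) -> int:
        return len(self._heap)


@dataclass
class SimulationResult:
    """One replication's indicators and event history."""

    scenario_name: str
    ambulance_count: int
    stress: float
    seed: int
    replication: int
    horizon: float
    thresholds: tuple[float, ...]
    phi: dict[float, float]                 # time-averaged phi_k
    pi: pd.DataFrame                        # towns x thresholds
    occupation: OccupationReport
    availability: float
    response_times: np.ndarray              # per served accident, minutes
    accidents: list[AccidentRecord]
    n_uncoverable: int
    event_log: list[tuple[float, str, str]]
    mean_field: IsochroneField | None = None

    @property
    def mean_phi(self) -> dict[float, float]:
        return self.phi


class _Run:
    """Mutable state of a single replication."""

    def __init__(self, scenario: Scenario, stream: RandomStream,
                 collect_field: bool = True):
        self.sc = scenario
        self.grid: RoadGrid = scenario.grid
        self.stream = stream
        self.collect_field = collect_field
        self.stress = scenario.stress_multiplier
        self.horizon = scenario.horizon_minutes
        self.K = np.asarray(scenario.thresholds, dtype=float)
        self.queue = EventQueue()
        self.units = [
            AmbulanceState(i, cell=self.grid.hub) for i in range(scenario.ambulance_count)
        ]
        self.waiting: list[AccidentRecord] = []
        self.accidents: list[AccidentRecord] = []
        self.stage_log: dict[int, list[tuple[float, float, str]]] = {
            u.id: [] for u in self.units
        }
        self.log: list[tuple[float, str, str]] = []
        self.now = 0.0
        self.month = 0
        self.day = 0
        self._acc_seq = itertools.count()
        self._seg_gen: dict[str, int] = {}
        # overlays
        self.weather_active: list[PenaltyOverlay] = []
        self.congestion_active: dict[int, PenaltyOverlay] = {}  # accident id -> ov
        self.fest_overlay: PenaltyOverlay | None = None
        self._fields_dirty = True
        self._full_field: np.ndarray | None = None
        self._unit_fields: list[np.ndarray] | None = None
        self._unit_waits: np.ndarray | None = None
        self._avail_times = np.zeros(len(self.units))
        # static (base-weight) fields per source, for the uniform-scaling path
        self._static_fields: dict[Cell, np.ndarray] = {}
        # town data
        self.town_cells = [t.cell for t in scenario.towns]
        self._town_rr = tuple(c[0] for c in self.town_cells)
        self._town_cc = tuple(c[1] for c in self.town_cells)
        self.pop = population_at(0, scenario.towns, scenario.calendar)
        # accumulators
        self.phi_acc = np.zeros(len(self.K))
        self.pi_acc = np.zeros((len(self.town_cells), len(self.K)))
        self.field_acc = (
            np.zeros(self.grid.shape) if collect_field else None
        )
        self.acc_time = 0.0

    # -- logging -------------------------------------------------------------

    def _log(self, kind: str, detail: str) -> None:
        self.log.append((round(self.now, 6), kind, detail))

    # -- overlays and fields ---------------------------------------------------

    def active_overlays(self) -> list[PenaltyOverlay]:
        ovs = [ov for ov in self.weather_active if ov.active_at(self.now)]
        ovs.extend(
            ov for ov in self.congestion_active.values() if ov.active_at(self.now)
        )
        if self.fest_overlay is not None and self.fest_overlay.active_at(self.now):
            ovs.append(self.fest_overlay)
        return ovs

    def _weather_factor(self) -> float:
        f = 1.0
        for ov in self.weather_active:
            if ov.active_at(self.now):
                f = max(f, ov.factor)
        return f

    def _field_from(self, source: Cell) -> np.ndarray:
        """Full travel-time field from ``source`` under the current overlays."""
        congested = any(
            ov.active_at(self.now) for ov in self.congestion_active.values()
        )
        if not congested:
            # uniform multiplier: the field scales linearly
            scale = self.stress * self._weather_factor()
            if self.fest_overlay is not None and self.fest_overlay.active_at(self.now):
                scale *= 2.0
            if source not in self._static_fields:
                self._static_fields[source] = self.grid.shortest_time_field(
                    source
                ).values
            return self._static_fields[source] * scale
        return self.grid.shortest_time_field(
            source, self.now, self.active_overlays(), self.stress
        ).values

    def _refresh_fields(self) -> None:
        """Recompute the rescue-time state under the current overlays.

        With every unit based at the hub (the default dispatch policy)
        one field suffices and the waiting penalty is the scalar
        min-remaining-time; the dispatch-from-hospital variant keeps one
        field per distinct source cell instead.
        """
        free_units = [u for u in self.units if u.free]
        if free_units:
            fields = [self._field_from(u.cell) for u in free_units]
            self._full_field = (
                fields[0] if len(fields) == 1 else np.minimum.reduce(fields)
            )
            self._unit_fields = None
        else:
            sources = [u.availability_cell for u in self.units]
            cache = {c: self._field_from(c) for c in set(sources)}
            if self.sc.busy_penalty_mode == "remaining_time":
                self._unit_waits = None  # time-decaying, computed per point
            else:  # travel from the unit's current position
                self._unit_waits = np.array([
                    self._field_from(u.cell)[u.availability_cell]
                    if u.cell != u.availability_cell else 0.0
                    for u in self.units
                ])
            if len(cache) == 1:
                self._full_field = next(iter(cache.values()))
                self._unit_fields = None
            else:
                self._full_field = None
                self._unit_fields = [cache[c] for c in sources]
        self._avail_times = np.array([u.availability_time for u in self.units])
        self._fields_dirty = False

    # -- indicator accumulation ------------------------------------------------

    def accumulate(self, until: float) -> None:
        """Advance indicator accumulators over [self.now, until)."""
        t0, t1 = self.now, min(until, self.horizon)
        if t1 <= t0 or t0 >= self.horizon:
            return
        if self._fields_dirty:
            self._refresh_fields()
        tick = self.sc.collection_tick_minutes
        first = math.floor(t0 / tick) * tick + tick
        points = np.concatenate([[t0], np.arange(first, t1, tick)])
        widths = np.diff(np.concatenate([points, [t1]]))
        any_free = any(u.free for u in self.units)
        if any_free:
            waits = np.zeros_like(points)                     # (P,)
        elif self._unit_waits is not None:
            waits = np.full_like(points, float(self._unit_waits.min()))
        else:
            t_free = float(self._avail_times.min())
            waits = np.maximum(t_free - points, 0.0)
        if self._unit_fields is None:
            town_vals = self._full_field[self._town_rr, self._town_cc]
            r = town_vals[:, None] + waits[None, :]           # towns x points
            full_for_acc = self._full_field
            full_extra = float(widths @ waits)
        else:
            # distinct availability cells: cellwise min over units
            D = np.stack([f[self._town_rr, self._town_cc]
                          for f in self._unit_fields])        # units x towns
            if self._unit_waits is not None:
                uw = np.repeat(self._unit_waits[:, None], len(points), axis=1)
            else:
                uw = np.maximum(self._avail_times[:, None] - points[None, :], 0.0)
            r = (D[:, :, None] + uw[:, None, :]).min(axis=0)  # towns x points
            full_for_acc = None
            full_extra = 0.0
        covered = (r[:, None, :] <= self.K[None, :, None]).astype(float)
        pops = self.pop.populations
        total = pops.sum()
        self.phi_acc += (
            np.einsum("t,tkp,p->k", pops, covered, widths) / total
        )
        self.pi_acc += covered @ widths
        if self.field_acc is not None:
            if full_for_acc is not None:
                self.field_acc += full_for_acc * widths.sum()
                if full_extra:
                    self.field_acc += np.where(
                        np.isfinite(full_for_acc), full_extra, 0.0
                    )
            else:
                stack = np.stack(self._unit_fields)           # units x R x C
                for p, wdt in enumerate(widths):
                    self.field_acc += wdt * (
                        stack + uw[:, p][:, None, None]
                    ).min(axis=0)
        self.acc_time += t1 - t0

    # -- setup -----------------------------------------------------------------

    def schedule_initial(self) -> None:
        cal = self.sc.calendar
        for m in range(1, 12):
            t = cal.month_start_minutes(m)
            if t < self.horizon:
                self.queue.push(t, "month", (m,))
        for d in range(1, self.sc.horizon_days):
            self.queue.push(d * MINUTES_PER_DAY, "day", (d,))
        # whole-year weather calendar, drawn up front in month order
        rng = self.stream.weather
        for m in range(12):
            t = cal.month_start_minutes(m)
            if t >= self.horizon:
                break
            for ov in sample_weather_calendar(
                m, self.sc.weather, rng, t, cal.month_length_minutes(m)
            ):
                if ov.start < self.horizon:
                    self.queue.push(ov.start, "weather_start", (ov,))
                    self.queue.push(ov.end, "weather_end", (ov,))
        for seg in self.sc.accident_rates.segments:
            self._seg_gen[seg] = 0
            self._schedule_arrival(seg, 0.0)
        self._set_festivity(0)

    def _schedule_arrival(self, segment: str, now: float) -> None:
        cal = self.sc.calendar
        t = next_accident_time(
            now, segment, self.month, self.sc.accident_rates,
            cal.month_length_minutes(self.month), self.stream.accidents,
        )
        if t < self.horizon:
            self.queue.push(t, "accident", (segment, self._seg_gen[segment]))

    def _set_festivity(self, day: int) -> None:
        if self.sc.calendar.is_closure[day]:
            self.fest_overlay = PenaltyOverlay(
                cells=None, factor=1.0,
                start=day * MINUTES_PER_DAY, end=(day + 1) * MINUTES_PER_DAY,
                cause="festivity",
            )
        else:
            self.fest_overlay = None
        self._fields_dirty = True

    # -- event handlers --------------------------------------------------------

    def on_month(self, m: int) -> None:
        self.month = m
        # memoryless re-pricing: re-draw every segment's next arrival
        for seg in self.sc.accident_rates.segments:
            self._seg_gen[seg] += 1
            self._schedule_arrival(seg, self.now)
        self._log("month", f"rollover to month {m + 1}")

    def on_day(self, d: int) -> None:
        self.day = d
        self.pop = population_at(d, self.sc.towns, self.sc.calendar)
        self._set_festivity(d)

    def on_accident(self, segment: str, gen: int) -> None:
        if gen != self._seg_gen[segment]:
            return  # superseded by a month rollover
        cells = self.sc.accident_rates.segment_cells[segment]
        cell = cells[int(self.stream.accidents.integers(len(cells)))]
        service = sample_service_times(
            self.sc.service_times, self.stress, self.stream.service
        )
        acc = AccidentRecord(
            id=next(self._acc_seq), segment=segment, cell=cell,
            occurrence=self.now, required_units=self.sc.required_units,
            service=service,
        )
        self.accidents.append(acc)
        self.waiting.append(acc)
        r, c = cell
        box = frozenset(
            (r + dr, c + dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
        )
        self.congestion_active[acc.id] = PenaltyOverlay(
            cells=box, factor=1.0, start=self.now, end=np.inf, cause="congestion"
        )
        self._fields_dirty = True
        self._log("accident", f"#{acc.id} on {segment} at {cell}")
        self._schedule_arrival(segment, self.now)
        self.try_dispatch()

    def on_weather(self, ov: PenaltyOverlay, starting: bool) -> None:
        if starting:
            self.weather_active.append(ov)
            self._log("weather", f"{ov.cause} starts (factor {ov.factor})")
        else:
            if ov in self.weather_active:
                self.weather_active.remove(ov)
            self._log("weather", f"{ov.cause} ends")
        self._fields_dirty = True

    def on_congestion_end(self, acc_id: int) -> None:
        self.congestion_active.pop(acc_id, None)
        self._fields_dirty = True

    # -- dispatch and the ambulance lifecycle ----------------------------------

    def try_dispatch(self) -> None:
        """FIFO over waiting accidents; closest free unit, ties by id."""
        while self.waiting:
            acc = self.waiting[0]
            free = [u for u in self.units if u.free]
            if not free:
                return
            ovs = self.active_overlays()
            travel: dict[int, float] = {}
            for u in free:
                try:
                    _, dur = self.grid.route(u.cell, acc.cell, self.now, ovs, self.stress)
                except UnreachableError:
                    dur = np.inf
                travel[u.id] = dur
            best = min(free, key=lambda u: (travel[u.id], u.id))
            if not np.isfinite(travel[best.id]):
                acc.uncoverable = True
                self.waiting.pop(0)
                self._log("uncoverable", f"#{acc.id} at {acc.cell}")
                continue
            self._assign(acc, best)
            if len(acc.ambulance_ids) >= acc.required_units:
                self.waiting.pop(0)

    def _assign(self, acc: AccidentRecord, unit: AmbulanceState) -> None:
        if acc.assignment_time is None:
            acc.assignment_time = self.now
        acc.ambulance_ids.append(unit.id)
        prep, on_scene, hospital = acc.service
        # availability estimate: remaining legs priced at the current instant
        ovs = self.active_overlays()
        try:
            _, leg1 = self.grid.route(unit.cell, acc.cell, self.now, ovs, self.stress)
        except UnreachableError:
            leg1 = np.inf
        scene_field = self.grid.shortest_time_field(acc.cell, self.now, ovs, self.stress)
        hosp = min(self.grid.hospitals, key=lambda h: (scene_field.at(h), h))
        leg2 = scene_field.at(hosp)
        try:
            _, leg3 = self.grid.route(hosp, self.grid.hub, self.now, ovs, self.stress)
        except UnreachableError:
            leg3 = np.inf
        unit.accident_id = acc.id
        unit.remaining = [prep, leg1, on_scene, leg2, hospital, leg3]
        unit.availability_cell = (
            hosp if self.sc.dispatch_from_hospital else self.grid.hub
        )
        self._start_stage(unit, "prep", prep)
        self._log("assign", f"unit {unit.id} -> accident #{acc.id}")

    def _start_stage(self, unit: AmbulanceState, stage: str, duration: float) -> None:
        unit.stage = stage
        unit.stage_end = self.now + duration
        idx = _STAGE_CYCLE.index(stage)
        unit.remaining[idx] = duration
        if self.sc.dispatch_from_hospital:
            pending = unit.remaining[idx: _STAGE_CYCLE.index("returning")]
            pending = pending or [duration]
        else:
            pending = unit.remaining[idx:]
        unit.availability_time = self.now + float(sum(pending))
        self.stage_log[unit.id].append((self.now, unit.stage_end, stage))
        self.queue.push(unit.stage_end, "stage_end", (unit.id, stage))
        self._fields_dirty = True

    def on_stage_end(self, unit_id: int, stage: str) -> None:
        unit = self.units[unit_id]
        if unit.stage != stage or unit.stage_end != self.now:
            return  # stale event
        acc = self.accidents[unit.accident_id]
        ovs = self.active_overlays()
        if stage == "prep":
            path, dur = self.grid.route(unit.cell, acc.cell, self.now, ovs, self.stress)
            self._start_stage(unit, "to_scene", dur)
        elif stage == "to_scene":
            unit.cell = acc.cell
            if acc.scene_arrival is None:
                acc.scene_arrival = self.now
                self._log("scene", f"unit {unit.id} reaches #{acc.id}")
            self._start_stage(unit, "on_scene", acc.service[1])
        elif stage == "on_scene":
            # congestion clears a fixed interval after leaving the scene
            old = self.congestion_active.get(acc.id)
            if old is not None and not np.isfinite(old.end):
                end = self.now + self.sc.congestion_extra_minutes
                self.congestion_active[acc.id] = PenaltyOverlay(
                    cells=old.cells, factor=1.0, start=old.start, end=end,
                    cause="congestion",
                )
                self.queue.push(end, "congestion_end", (acc.id,))
            scene_field = self.grid.shortest_time_field(acc.cell, self.now, ovs, self.stress)
            hosp = min(self.grid.hospitals, key=lambda h: (scene_field.at(h), h))
            unit.availability_cell = (
                hosp if self.sc.dispatch_from_hospital else self.grid.hub
            )
            self._start_stage(unit, "to_hospital", scene_field.at(hosp))
            unit._dest = hosp  # type: ignore[attr-defined]
        elif stage == "to_hospital":
            unit.cell = unit._dest  # type: ignore[attr-defined]
            self._start_stage(unit, "at_hospital", acc.service[2])
        elif stage == "at_hospital":
            acc.clearance_time = self.now
            if self.sc.dispatch_from_hospital:
                self._free(unit)
            else:
                _, dur = self.grid.route(unit.cell, self.grid.hub, self.now, ovs, self.stress)
                self._start_stage(unit, "returning", dur)
                unit._dest = self.grid.hub  # type: ignore[attr-defined]
        elif stage == "returning":
            unit.cell = self.grid.hub
            self._free(unit)

    def _free(self, unit: AmbulanceState) -> None:
        unit.stage = "free"
        unit.accident_id = None
        unit.availability_time = self.now
        unit.availability_cell = unit.cell
        unit.remaining = []
        self._fields_dirty = True
        self._log("free", f"unit {unit.id} available at {unit.cell}")
        self.try_dispatch()

    # -- main loop -------------------------------------------------------------

    def run(self) -> SimulationResult:
        self.schedule_initial()
        while len(self.queue):
            t, kind, payload = self.queue.pop()
            if t >= self.horizon and kind not in ("stage_end", "congestion_end"):
                continue
            self.accumulate(t)
            self.now = t
            if kind == "month":
                self.on_month(*payload)
            elif kind == "day":
                self.on_day(*payload)
            elif kind == "weather_start":
                self.on_weather(payload[0], True)
            elif kind == "weather_end":
                self.on_weather(payload[0], False)
            elif kind == "congestion_end":
                self.on_congestion_end(*payload)
            elif kind == "stage_end":
                self.on_stage_end(*payload)
            elif kind == "accident":
                self.on_accident(*payload)
        self.accumulate(self.horizon)
        self.now = max(self.now, self.horizon)
        return self._finalize()

    def _finalize(self) -> SimulationResult:
        if abs(self.acc_time - self.horizon) > 1e-6:
            raise RuntimeError("indicator accumulation does not span the horizon")
        # clip summation round-off: fractions are exact up to ~1e-12
        phi = {
            float(k): float(np.clip(v / self.horizon, 0.0, 1.0))
            for k, v in zip(self.K, self.phi_acc)
        }
        pi = pd.DataFrame(
            np.clip(self.pi_acc / self.horizon, 0.0, 1.0),
            index=[t.name for t in self.sc.towns],
            columns=[float(k) for k in self.K],
        )
        occ = occupation(self.stage_log, self.horizon, len(self.units))
        served = [a for a in self.accidents if a.response_time is not None]
        rts = np.array([a.response_time for a in served])
        mean_field = None
        if self.field_acc is not None:
            mean_field = IsochroneField(
                values=self.field_acc / self.horizon,
                thresholds=tuple(float(k) for k in self.K),
                kind="time-averaged",
            )
        return SimulationResult(
            scenario_name=self.sc.name,
            ambulance_count=self.sc.ambulance_count,
            stress=self.stress,
            seed=self.stream.master_seed,
            replication=self.stream.replication,
            horizon=self.horizon,
            thresholds=tuple(float(k) for k in self.K),
            phi=phi,
            pi=pi,
            occupation=occ,
            availability=occ.availability,
            response_times=rts,
            accidents=self.accidents,
            n_uncoverable=sum(a.uncoverable for a in self.accidents),
            event_log=self.log,
            mean_field=mean_field,
        )


def run(
    scenario: Scenario,
    seed: int | None = None,
    replication: int = 0,
    collect_field: bool = True,
) -> SimulationResult:
    """Simulate one horizon of the scenario and return its indicators."""
    stream = RandomStream(seed if seed is not None else scenario.seed, replication)
    return _Run(scenario, stream, collect_field=collect_field).run()


def dispatch(
    waiting: list[AccidentRecord],
    units: list[AmbulanceState],
    now: float,
    grid: RoadGrid,
    overlays: list[PenaltyOverlay] = [],
    stress: float = 1.0,
) -> list[tuple[int, int]]:
    """Pure FIFO/closest-unit assignment: (accident id, unit id) pairs.

    Serves the waiting queue in occurrence order; for each accident the
    free unit with minimal current travel time to the scene wins, ties by
    unit id.  Assignment stops when the head of the queue cannot be
    (fully) served.  Inputs are not mutated.
    """
    free = [u for u in units if u.free]
    out: list[tuple[int, int]] = []
    for acc in waiting:
        needed = acc.required_units - len(acc.ambulance_ids)
        for _ in range(needed):
            if not free:
                return out
            durs = {}
            for u in free:
                try:
                    _, durs[u.id] = grid.route(u.cell, acc.cell, now, overlays, stress)
                except UnreachableError:
                    durs[u.id] = np.inf
            best = min(free, key=lambda u: (durs[u.id], u.id))
            if not np.isfinite(durs[best.id]):
                return out
            out.append((acc.id, best.id))
            free.remove(best)
        if acc.required_units - len(acc.ambulance_ids) - sum(
            1 for a, _ in out if a == acc.id
        ) > 0:
            return out  # head not fully served: strict FIFO blocks
    return out


@dataclass
class ReplicationSet:
    """Cross-replication aggregate of one deployment configuration."""

    results: list[SimulationResult]
    thresholds: tuple[float, ...]

    @property
    def phi_matrix(self) -> np.ndarray:
        return np.array([[r.phi[k] for k in self.thresholds] for r in self.results])

    @property
    def mean_phi(self) -> dict[float, float]:
        m = self.phi_matrix.mean(axis=0)
        return {k: float(v) for k, v in zip(self.thresholds, m)}

    @property
    def sd_phi(self) -> dict[float, float]:
        s = self.phi_matrix.std(axis=0, ddof=1) if len(self.results) > 1 else np.zeros(
            len(self.thresholds)
        )
        return {k: float(v) for k, v in zip(self.thresholds, s)}

    @property
    def availability(self) -> float:
        return float(np.mean([r.availability for r in self.results]))

    @property
    def mean_pi(self) -> pd.DataFrame:
        return sum(r.pi for r in self.results) / len(self.results)


def replicate(
    scenario: Scenario,
    n: int | None = None,
    master_seed: int | None = None,
    collect_field: bool = False,
) -> ReplicationSet:
    """Run ``n`` replications; replication r derives its substreams from
    (master seed, r), so the same pair is comparable across ambulance
    counts (common random numbers)."""
    n = n if n is not None else scenario.replications
    if n < 1:
        raise ValueError("need at least one replication")
    seed = master_seed if master_seed is not None else scenario.seed
    results = [
        _Run(scenario, RandomStream(seed, r), collect_field=collect_field).run()
        for r in range(n)
    ]
    return ReplicationSet(results, tuple(float(k) for k in scenario.thresholds))
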