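"""The isochrone-based indicator family.

* dynamic rescue field — per-cell minutes until the first ambulance could
  reach the cell, accounting for busy units and travel penalties;
* population coverage ``phi_k`` — fraction of the (time-varying)
  population within the k-minute isochrone;
* town coverage ``pi_k`` — fraction of a timeframe during which a town's
  cell lies within the k-minute isochrone;
* occupation — partition of each ambulance's horizon into travelling /
  preparation / assistance / free;
* time averaging of piecewise-constant timelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .grid import Cell, PenaltyOverlay, RoadGrid
from .scenario import TownRecord
from .stochastics import PopulationSnapshot


class IndicatorError(ValueError):
    """Ill-posed indicator request (empty timeline, zero population, ...)."""


# -- isochrone field ----------------------------------------------------------

@dataclass
class IsochroneField:
    """Per-cell rescue time in minutes, banded into ISOCHRONE-K classes."""

    values: np.ndarray                 # (rows, cols), +inf off network
    thresholds: tuple[float, ...]
    kind: str = "instantaneous"        # or "time-averaged"

    def at(self, cell: Cell) -> float:
        return float(self.values[cell])

    def band_index(self, cell: Cell) -> int:
        """0-based band of the cell: band i is (K_{i-1}, K_i]; len(K) = beyond."""
        v = self.at(cell)
        for i, k in enumerate(self.thresholds):
            if v <= k:
                return i
        return len(self.thresholds)


class UnitLike(Protocol):
    """What the rescue field needs to know about an ambulance."""

    cell: Cell
    free: bool
    availability_time: float
    availability_cell: Cell


def dynamic_rescue_field(
    grid: RoadGrid,
    units: Sequence[UnitLike],
    now: float,
    overlays: Sequence[PenaltyOverlay] = (),
    stress: float = 1.0,
    thresholds: tuple[float, ...] = (10, 20, 30, 40, 50, 60),
    busy_penalty_mode: str = "remaining_time",
) -> IsochroneField:
    """Instantaneous rescue time from the first available ambulance.

    Free units contribute the travel time from their location.  A busy
    unit contributes a waiting penalty plus the travel time from the cell
    where it next becomes available: the penalty is its remaining time to
    availability (default), or — variant reading — the travel time from
    its current position to that availability cell.  The cellwise minimum
    over all units is taken.
    """
    if not units:
        raise IndicatorError("need at least one ambulance")
    fields = []
    free_units = [u for u in units if u.free]
    if free_units:
        for u in free_units:
            f = grid.shortest_time_field(u.cell, now, overlays, stress)
            fields.append(f.values)
    else:
        for u in units:
            f = grid.shortest_time_field(u.availability_cell, now, overlays, stress)
            if busy_penalty_mode == "remaining_time":
                wait = max(u.availability_time - now, 0.0)
            elif busy_penalty_mode == "travel_from_position":
                _, wait = grid.route(u.cell, u.availability_cell, now, overlays, stress)
            else:
                raise IndicatorError(f"unknown busy penalty mode {busy_penalty_mode!r}")
            fields.append(f.values + wait)
    return IsochroneField(
        values=np.minimum.reduce(fields), thresholds=tuple(thresholds)
    )


# -- population coverage (phi) ------------------------------------------------

@dataclass
class CoverageCurve:
    """phi_k for each threshold k, with the population total used."""

    thresholds: tuple[float, ...]
    phi: np.ndarray
    population_total: float

    def as_dict(self) -> dict[float, float]:
        return {k: float(p) for k, p in zip(self.thresholds, self.phi)}


def phi_k(
    field: IsochroneField,
    towns: Sequence[TownRecord],
    k: float,
    populations: PopulationSnapshot | None = None,
) -> float:
    """Fraction of population in cells whose rescue time is <= k minutes.

    ``populations`` supplies the effective (time-varying) populations;
    omitted, the towns' static populations are used.
    """
    pops = (
        populations.populations
        if populations is not None
        else np.array([t.static_population for t in towns], dtype=float)
    )
    total = float(pops.sum())
    if total <= 0:
        raise IndicatorError("total population must be > 0")
    covered = sum(
        float(p) for t, p in zip(towns, pops) if field.at(t.cell) <= k
    )
    return covered / total


def coverage_curve(
    field: IsochroneField,
    towns: Sequence[TownRecord],
    thresholds: Sequence[float],
    populations: PopulationSnapshot | None = None,
) -> CoverageCurve:
    pops = (
        populations.populations
        if populations is not None
        else np.array([t.static_population for t in towns], dtype=float)
    )
    phi = np.array([phi_k(field, towns, k, populations) for k in thresholds])
    return CoverageCurve(tuple(float(k) for k in thresholds), phi, float(pops.sum()))


# -- town coverage (pi) -------------------------------------------------------

Timeline = Sequence[tuple[float, float | np.ndarray]]
"""Piecewise-constant timeline: (t, value) pairs; each value holds from its
t until the next entry's t."""


def _segments(timeline: Timeline, frame: tuple[float, float]):
    t0, t1 = frame
    if t1 <= t0:
        raise IndicatorError("empty timeframe")
    if not timeline:
        raise IndicatorError("empty timeline")
    times = [t for t, _ in timeline]
    if times[0] > t0 or any(a > b for a, b in zip(times, times[1:])):
        raise IndicatorError("timeline must be time-sorted and span the frame")
    for i, (t, v) in enumerate(timeline):
        nxt = timeline[i + 1][0] if i + 1 < len(timeline) else t1
        lo, hi = max(t, t0), min(nxt, t1)
        if hi > lo:
            yield (hi - lo), v


def time_average(timeline: Timeline, frame: tuple[float, float]):
    """Time-weighted mean of a piecewise-constant timeline over ``frame``.

    Chaining is exact: splitting the frame into sub-frames and combining
    the sub-averages weighted by length reproduces the full average.
    """
    total = frame[1] - frame[0]
    acc = None
    for dt, v in _segments(timeline, frame):
        acc = (dt / total) * np.asarray(v, dtype=float) + (0 if acc is None else acc)
    if acc is None:
        raise IndicatorError("timeline does not intersect the frame")
    return float(acc) if np.ndim(acc) == 0 else acc


def pi_k(
    rescue_times: Timeline,
    k: float,
    frame: tuple[float, float],
) -> float:
    """Fraction of ``frame`` during which the rescue time is <= k minutes."""
    total = frame[1] - frame[0]
    covered = sum(dt for dt, v in _segments(rescue_times, frame) if float(v) <= k)
    return covered / total


@dataclass
class TownCoverage:
    """pi_k per threshold for one town over a timeframe."""

    town: str
    thresholds: tuple[float, ...]
    pi: np.ndarray
    timeframe: float


# -- ambulance occupation -----------------------------------------------------

#: stage -> occupation category
STAGE_CATEGORY = {
    "prep": "preparation",
    "to_scene": "travelling",
    "on_scene": "assistance",
    "to_hospital": "travelling",
    "at_hospital": "assistance",
    "returning": "travelling",
}

OCCUPATION_CATEGORIES = ("travelling", "preparation", "assistance", "free")


@dataclass
class OccupationReport:
    """Per-unit fractions of the horizon in each occupation category."""

    fractions: pd.DataFrame    # index: unit id; columns: OCCUPATION_CATEGORIES

    @property
    def availability(self) -> float:
        """Mean free-time fraction across units."""
        return float(self.fractions["free"].mean())


def occupation(
    stage_log: dict[int, list[tuple[float, float, str]]],
    horizon: float,
    n_units: int,
) -> OccupationReport:
    """Exact partition of each unit's horizon into the four categories.

    ``stage_log`` maps unit id to (start, end, stage) intervals.  Overlapping
    intervals violate conservation and raise.
    """
    rows = {}
    for uid in range(n_units):
        totals = dict.fromkeys(OCCUPATION_CATEGORIES, 0.0)
        last_end = -np.inf
        for start, end, stage in sorted(stage_log.get(uid, [])):
            if start < last_end - 1e-9:
                raise IndicatorError(f"unit {uid}: overlapping stages at t={start}")
            last_end = end
            lo, hi = max(start, 0.0), min(end, horizon)
            if hi > lo:
                totals[STAGE_CATEGORY[stage]] += hi - lo
        busy = sum(totals.values())
        if busy > horizon + 1e-6:
            raise IndicatorError(f"unit {uid}: busy time exceeds horizon")
        totals["free"] = horizon - busy
        rows[uid] = {c: totals[c] / horizon for c in OCCUPATION_CATEGORIES}
    return OccupationReport(
        fractions=pd.DataFrame.from_dict(rows, orient="index")[
            list(OCCUPATION_CATEGORIES)
        ]
    )


# -- deployment summaries -----------------------------------------------------

def availability_vs_coverage(results_by_c: dict[int, "object"]) -> pd.DataFrame:
    """Availability and the mean phi_k curve side by side, one row per c.

    Accepts any objects exposing ``availability`` (scalar) and
    ``mean_phi`` (mapping threshold -> phi).
    """
    rows = []
    for c in sorted(results_by_c):
        res = results_by_c[c]
        row = {"ambulances": c, "availability": float(res.availability)}
        for k, v in dict(res.mean_phi).items():
            row[f"phi_{int(k)}"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows).set_index("ambulances")
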