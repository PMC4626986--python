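"""Scenario builders: the Ávila-like bundle and randomised small scenarios.

The Ávila-like scenario reproduces the published inputs for the province
of Ávila in 2014 — per-road monthly accident counts, town populations and
province hotel stays, festivity/closure day counts, monthly weather-day
counts and the weather penalty catalogue — on a *synthetic* radial road
network.  The real travel-time matrix of the province (originally
extracted from an online routing service) is unpublished, so the network
here is a star of 18 arms (one per rated road) around the hub whose
travel-time bands honour every documented figure: the capital inside the
10-minute isochrone, Navaluenga in (30, 40], Hoyo de Pinares in (40, 50],
and everything within 50 minutes.  Static indicators are therefore
reproduced exactly; dynamic headline percentages only qualitatively.
"""

from __future__ import annotations

import numpy as np

from .grid import Cell, RoadGrid
from .scenario import (
    AccidentRateTable,
    Calendar,
    Scenario,
    ScenarioError,
    ServiceTimeSpec,
    TownRecord,
    WeatherEvent,
    WeatherSpec,
)

# -- published 2014 input tables ----------------------------------------------

#: monthly accidents per road (JAN..DEC)
ACCIDENTS_2014: dict[str, tuple[int, ...]] = {
    "A-50":   (3, 3, 3, 2, 6, 1, 4, 2, 3, 0, 1, 3),
    "A-51":   (0, 2, 0, 2, 1, 0, 2, 1, 0, 2, 1, 1),
    "A-6":    (2, 4, 2, 3, 3, 3, 3, 4, 8, 2, 2, 3),
    "AP-51":  (0, 0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 2),
    "AP-6":   (3, 0, 2, 2, 0, 1, 1, 1, 2, 1, 1, 1),
    "AV-110": (1, 2, 4, 0, 0, 0, 1, 0, 3, 2, 1, 2),
    "AV-500": (1, 0, 0, 0, 1, 1, 1, 2, 2, 1, 3, 2),
    "AV-502": (0, 4, 5, 2, 0, 1, 3, 7, 1, 1, 1, 0),
    "AV-503": (1, 0, 0, 0, 0, 0, 0, 0, 1, 1, 2, 4),
    "AV-804": (1, 0, 1, 3, 2, 0, 1, 2, 4, 0, 3, 1),
    "AV-900": (4, 1, 1, 0, 0, 0, 3, 2, 2, 2, 1, 2),
    "AV-902": (1, 1, 1, 4, 0, 0, 2, 3, 0, 1, 1, 0),
    "CL-501": (8, 7, 4, 7, 8, 4, 6, 10, 4, 4, 15, 9),
    "CL-505": (2, 4, 4, 2, 1, 0, 4, 3, 4, 2, 6, 1),
    "N-110":  (15, 10, 11, 10, 7, 9, 11, 8, 9, 7, 9, 7),
    "N-403":  (8, 7, 5, 5, 4, 4, 5, 5, 7, 13, 6, 5),
    "N-501":  (0, 1, 0, 0, 1, 0, 3, 1, 0, 1, 1, 3),
    "N-502":  (10, 8, 2, 1, 5, 6, 5, 5, 5, 5, 2, 8),
}

#: static populations of the six towns above 1000 inhabitants (persons);
#: together they hold 90% of the population covered by the EMS hub
TOWN_POPULATIONS: dict[str, int] = {
    "Avila": 58933,
    "El Tiemblo": 4000,
    "Hoyo de Pinares": 2000,
    "Navaluenga": 2000,
    "Piedrahita": 2000,
    "El Barraco": 2000,
}

#: province-wide monthly hotel stays (persons), JAN..DEC
HOTEL_STAYS_2014: tuple[int, ...] = (
    18000, 24000, 38000, 45000, 42000, 37000,
    46000, 61000, 48000, 46000, 31000, 32000,
)

#: festivity day counts per month: local events and road closures
LOCAL_EVENT_DAYS_2014 = (0, 4, 0, 1, 10, 12, 1, 6, 19, 11, 0, 0)
ROAD_CLOSURE_DAYS_2014 = (0, 2, 12, 11, 10, 29, 13, 12, 20, 6, 0, 0)

#: weather catalogue: event durations (minutes) and travel-time factors
WEATHER_EVENTS: dict[str, WeatherEvent] = {
    "static": WeatherEvent(720, 1),
    "rain": WeatherEvent(120, 2),
    "snow": WeatherEvent(240, 3),
    "fog": WeatherEvent(120, 3),
    "ice": WeatherEvent(240, 4),
}

#: mean event-days per month (JAN..DEC); storms have no defined penalty and
#: therefore never generate events, ice has a penalty but no recorded days
WEATHER_DAYS_2014: dict[str, tuple[float, ...]] = {
    "rain":   (5.9, 5.0, 4.2, 7.8, 9.0, 4.7, 1.9, 2.6, 4.4, 7.6, 7.1, 6.7),
    "snow":   (4.5, 4.3, 2.3, 2.2, 0.4, 0.0, 0.0, 0.0, 0.0, 0.1, 1.9, 3.2),
    "storms": (4.5, 2.3, 1.5, 1.2, 1.0, 0.6, 0.3, 0.3, 0.7, 1.3, 3.4, 4.1),
    "fog":    (20.1, 16.4, 12.6, 6.6, 1.7, 0.1, 0.0, 0.0, 0.3, 1.7, 11.5, 16.3),
    "ice":    (0.0,) * 12,
}

#: fixture placements in minutes from the hub.  Bands for the capital,
#: Navaluenga and Hoyo de Pinares are published; the other three towns and
#: the small settlements (synthetic, holding the remaining 10% of the
#: population outside the 10-minute and inside the 50-minute isochrone)
#: are declared fixture choices.
TOWN_MINUTES: dict[str, int] = {
    "Avila": 5,
    "El Tiemblo": 15,
    "El Barraco": 25,
    "Navaluenga": 35,
    "Piedrahita": 45,
    "Hoyo de Pinares": 45,
}
SETTLEMENT_MINUTES: dict[str, int] = {
    "Settlement A (synthetic)": 12,
    "Settlement B (synthetic)": 22,
    "Settlement C (synthetic)": 32,
}

SIX_TOWN_POPULATION_SHARE = 0.90
ARM_LENGTH_MINUTES = 50
SPINE_MINUTES = 1e-6  # near-zero connector column joining the arms


def make_avila_like_scenario(**overrides) -> Scenario:
    """The Ávila-like scenario on the synthetic radial network.

    Keyword overrides are forwarded to :class:`Scenario` (e.g.
    ``ambulance_count=2``, ``stress_multiplier=2.0``, ``seed=...``).
    """
    roads = list(ACCIDENTS_2014)
    n_arms = len(roads)
    rows, cols = n_arms, ARM_LENGTH_MINUTES + 1
    contents: dict[Cell, set[str]] = {}
    base: dict[Cell, float] = {}
    # connector spine down column 0; the hub (with the hospital by it) at its top
    for r in range(rows):
        contents.setdefault((r, 0), set()).add("road")
        base[(r, 0)] = SPINE_MINUTES
    contents[(0, 0)] |= {"hub", "hospital"}
    # one arm per rated road, one minute per cell
    segment_cells: dict[str, tuple[Cell, ...]] = {}
    for r, road in enumerate(roads):
        cells = tuple((r, c) for c in range(1, cols))
        for cell in cells:
            contents.setdefault(cell, set()).add("road")
            base[cell] = 1.0
        segment_cells[road] = cells

    # populated cells: six towns on arms 0..5, settlements on arms 6..8
    total = sum(TOWN_POPULATIONS.values()) / SIX_TOWN_POPULATION_SHARE
    rest = total - sum(TOWN_POPULATIONS.values())
    placements = list(TOWN_MINUTES.items()) + [
        (name, minutes) for name, minutes in SETTLEMENT_MINUTES.items()
    ]
    pops = dict(TOWN_POPULATIONS)
    each = round(rest / len(SETTLEMENT_MINUTES))
    for name in SETTLEMENT_MINUTES:
        pops[name] = each
    town_cells: dict[str, Cell] = {}
    for arm, (name, minutes) in enumerate(placements):
        cell = (arm, minutes)
        contents[cell].add("town")
        town_cells[name] = cell

    grid = RoadGrid((rows, cols), contents, base)

    # hotel stays split proportionally to static population
    all_pop = sum(pops.values())
    towns = [
        TownRecord(
            name=name,
            cell=town_cells[name],
            static_population=pops[name],
            monthly_hotel_share=tuple(
                stays * pops[name] / all_pop for stays in HOTEL_STAYS_2014
            ),
        )
        for name, _ in placements
    ]
    rates = AccidentRateTable(
        rates={r: tuple(float(x) for x in v) for r, v in ACCIDENTS_2014.items()},
        segment_cells=segment_cells,
    )
    weather = WeatherSpec(events=dict(WEATHER_EVENTS),
                          monthly_days=dict(WEATHER_DAYS_2014))
    calendar = Calendar(
        year=2014,
        holidays_per_month=LOCAL_EVENT_DAYS_2014,
        closures_per_month=ROAD_CLOSURE_DAYS_2014,
    )
    kwargs = dict(
        name="avila-like",
        grid=grid,
        towns=towns,
        accident_rates=rates,
        weather=weather,
        service_times=ServiceTimeSpec(),
        calendar=calendar,
    )
    kwargs.update(overrides)
    return Scenario(**kwargs)


def make_random_scenario(
    seed: int,
    rows: int = 6,
    cols: int = 6,
    n_towns: int = 2,
    n_segments: int = 3,
    max_rate: float = 5.0,
    horizon_days: int = 14,
    **overrides,
) -> Scenario:
    """A small random but valid scenario for property testing.

    Deterministic per seed: a connected random road component grown from a
    random cell, hub and hospital on it, towns on road cells, small random
    monthly accident rates, and light weather.
    """
    if rows * cols < 4:
        raise ScenarioError("grid too small for a connected scenario")
    rng = np.random.default_rng(seed)
    start = (int(rng.integers(rows)), int(rng.integers(cols)))
    road: set[Cell] = {start}
    frontier = [start]
    target = max(4, (rows * cols) // 2)
    while frontier and len(road) < target:
        r, c = frontier[rng.integers(len(frontier))]
        nbrs = [
            (r + dr, c + dc)
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
            if 0 <= r + dr < rows and 0 <= c + dc < cols
        ]
        new = [n for n in nbrs if n not in road]
        if not new:
            frontier.remove((r, c))
            continue
        nxt = new[rng.integers(len(new))]
        road.add(nxt)
        frontier.append(nxt)
    cells = sorted(road)
    base = {cell: float(rng.uniform(0.5, 3.0)) for cell in cells}
    contents: dict[Cell, set[str]] = {cell: {"road"} for cell in cells}
    picks = rng.choice(len(cells), size=min(len(cells), 2 + n_towns), replace=False)
    contents[cells[picks[0]]].add("hub")
    contents[cells[picks[1]]].add("hospital")
    towns = []
    for i, p in enumerate(picks[2:]):
        contents[cells[p]].add("town")
        towns.append(
            TownRecord(
                name=f"town-{i}",
                cell=cells[p],
                static_population=float(rng.integers(100, 5000)),
                monthly_hotel_share=tuple(float(rng.uniform(0, 500)) for _ in range(12)),
            )
        )
    if not towns:
        raise ScenarioError("need at least one town")
    seg_rates, seg_cells = {}, {}
    for s in range(n_segments):
        k = int(rng.integers(1, max(2, len(cells) // 2)))
        chosen = rng.choice(len(cells), size=k, replace=False)
        seg_cells[f"R-{s}"] = tuple(cells[i] for i in sorted(chosen))
        seg_rates[f"R-{s}"] = tuple(float(rng.uniform(0, max_rate)) for _ in range(12))
    weather = WeatherSpec(
        events=dict(WEATHER_EVENTS),
        monthly_days={
            "rain": tuple(float(rng.uniform(0, 4)) for _ in range(12)),
            "snow": tuple(float(rng.uniform(0, 2)) for _ in range(12)),
        },
    )
    calendar = Calendar(
        year=2014,
        holidays_per_month=tuple(int(rng.integers(0, 4)) for _ in range(12)),
        closures_per_month=tuple(int(rng.integers(0, 4)) for _ in range(12)),
    )
    kwargs = dict(
        name=f"random-{seed}",
        grid=RoadGrid((rows, cols), contents, base),
        towns=towns,
        accident_rates=AccidentRateTable(rates=seg_rates, segment_cells=seg_cells),
        weather=weather,
        service_times=ServiceTimeSpec(),
        calendar=calendar,
        horizon_days=horizon_days,
        replications=2,
        seed=seed,
    )
    kwargs.update(overrides)
    return Scenario(**kwargs)
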