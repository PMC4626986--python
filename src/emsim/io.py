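"""Scenario bundle I/O, indicator CSV export, and GeoJSON isochrone bands.

A scenario bundle is a directory holding one structured config file
(``config.yaml``) plus plain CSV tables whose headers mirror the published
input tables (accident counts per road and month, town populations and
hotel-stay shares, festivity/closure day counts, mean weather days, the
weather event catalogue) and a grid description.  Grid coordinates are
0-based (row, col), row-major.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .engine import ReplicationSet
from .grid import Cell, RoadGrid
from .indicators import OCCUPATION_CATEGORIES, IsochroneField
from .scenario import (
    MONTHS,
    AccidentRateTable,
    Calendar,
    Scenario,
    ScenarioError,
    ServiceTimeSpec,
    WeatherEvent,
    WeatherSpec,
    TownRecord,
)

_TABLES = (
    "grid.csv",
    "accidents.csv",
    "segments.csv",
    "towns.csv",
    "festivities.csv",
    "meteorology.csv",
    "weather_events.csv",
)

#: band colours, short to long rescue times (green -> red), last = beyond
BAND_COLORS = (
    "#1a9850", "#91cf60", "#d9ef8b", "#fee08b", "#fc8d59", "#d73027", "#7f0000",
)


class BundleError(ScenarioError):
    """Missing or malformed bundle file."""


def _cells_to_str(cells) -> str:
    return ";".join(f"{r}:{c}" for r, c in cells)


def _cells_from_str(s: str) -> tuple[Cell, ...]:
    return tuple(
        (int(r), int(c))
        for r, c in (tok.split(":") for tok in str(s).split(";") if tok)
    )


# -- scenario bundles ---------------------------------------------------------

def save_scenario(scenario: Scenario, bundle_path: str | Path) -> Path:
    """Write a scenario as a bundle directory; returns the path."""
    path = Path(bundle_path)
    path.mkdir(parents=True, exist_ok=True)
    sc = scenario
    st = sc.service_times
    config = {
        "name": sc.name,
        "horizon_days": sc.horizon_days,
        "replications": sc.replications,
        "seed": sc.seed,
        "ambulances": sc.ambulance_count,
        "thresholds": [float(k) for k in sc.thresholds],
        "stress_multiplier": sc.stress_multiplier,
        "required_units": sc.required_units,
        "dispatch_from_hospital": sc.dispatch_from_hospital,
        "congestion_extra_minutes": sc.congestion_extra_minutes,
        "collection_tick_minutes": sc.collection_tick_minutes,
        "busy_penalty_mode": sc.busy_penalty_mode,
        "cell_size": sc.cell_size,
        "calendar_year": sc.calendar.year,
        "service_times": {
            "prep_mu": st.prep_mu,
            "prep_sigma": st.prep_sigma,
            "prep_log_scale": st.prep_log_scale,
            "on_scene": [st.on_scene_low, st.on_scene_high],
            "hospital": [st.hospital_min, st.hospital_mode, st.hospital_max],
        },
    }
    (path / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))

    grid = sc.grid
    rows = [
        {
            "row": r,
            "col": c,
            "contents": "|".join(sorted(grid.contents.get((r, c), {"road"}))),
            "minutes": grid.base[r, c],
        }
        for (r, c) in grid.road_cells
    ]
    with open(path / "grid.csv", "w") as fh:
        fh.write(f"# 0-based (row, col), row-major; grid shape {grid.shape}\n")
        pd.DataFrame(rows).to_csv(fh, index=False, float_format="%.17g")

    acc = pd.DataFrame(
        [{"Roads": seg, **dict(zip(MONTHS, lam))}
         for seg, lam in sorted(sc.accident_rates.rates.items())],
        columns=["Roads", *MONTHS],
    )
    acc.to_csv(path / "accidents.csv", index=False, float_format="%.17g")
    pd.DataFrame(
        [{"road": seg, "cells": _cells_to_str(cells)}
         for seg, cells in sorted(sc.accident_rates.segment_cells.items())],
        columns=["road", "cells"],
    ).to_csv(path / "segments.csv", index=False)

    pd.DataFrame(
        [
            {
                "name": t.name,
                "row": t.cell[0],
                "col": t.cell[1],
                "static_population": t.static_population,
                **dict(zip(MONTHS, t.monthly_hotel_share)),
            }
            for t in sc.towns
        ]
    ).to_csv(path / "towns.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [
            {"Type": "Local events",
             **dict(zip(MONTHS, sc.calendar.holidays_per_month))},
            {"Type": "Roads closed",
             **dict(zip(MONTHS, sc.calendar.closures_per_month))},
        ]
    ).to_csv(path / "festivities.csv", index=False)

    pd.DataFrame(
        [{"Days/Month": name, **dict(zip(MONTHS, days))}
         for name, days in sorted(sc.weather.monthly_days.items())]
    ).to_csv(path / "meteorology.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [
            {"Event": name,
             "Duration (minutes)": ev.duration_minutes,
             "Penalty factor": ev.penalty_factor}
            for name, ev in sorted(sc.weather.events.items())
        ]
    ).to_csv(path / "weather_events.csv", index=False, float_format="%.17g")
    return path


def load_scenario(bundle_path: str | Path) -> Scenario:
    """Read and validate a scenario bundle directory."""
    path = Path(bundle_path)
    if not (path / "config.yaml").exists():
        raise BundleError(f"missing config.yaml in {path}")
    for name in _TABLES:
        if not (path / name).exists():
            raise BundleError(f"missing table {name} in {path}")
    config = yaml.safe_load((path / "config.yaml").read_text())

    gdf = pd.read_csv(path / "grid.csv", comment="#", float_precision="round_trip")
    contents = {
        (int(r.row), int(r.col)): set(str(r.contents).split("|"))
        for r in gdf.itertuples()
    }
    base = {(int(r.row), int(r.col)): float(r.minutes) for r in gdf.itertuples()}
    shape = (int(gdf["row"].max()) + 1, int(gdf["col"].max()) + 1)
    grid = RoadGrid(shape, contents, base)

    acc = pd.read_csv(path / "accidents.csv", float_precision="round_trip")
    bad = acc[(acc[list(MONTHS)] < 0).any(axis=1)]
    if len(bad):
        raise BundleError(
            f"negative accident rates for roads {bad['Roads'].tolist()}"
        )
    seg = pd.read_csv(path / "segments.csv")
    rates = AccidentRateTable(
        rates={
            r.Roads: tuple(float(getattr(r, m)) for m in MONTHS)
            for r in acc.itertuples()
        },
        segment_cells={
            r.road: _cells_from_str(r.cells) for r in seg.itertuples()
        },
    )

    tdf = pd.read_csv(path / "towns.csv", float_precision="round_trip")
    towns = [
        TownRecord(
            name=str(r.name),
            cell=(int(r.row), int(r.col)),
            static_population=float(r.static_population),
            monthly_hotel_share=tuple(float(getattr(r, m)) for m in MONTHS),
        )
        for r in tdf.itertuples(index=False)
    ]

    fdf = pd.read_csv(path / "festivities.csv").set_index("Type")
    calendar = Calendar(
        year=int(config.get("calendar_year", 2014)),
        holidays_per_month=tuple(int(x) for x in fdf.loc["Local events", list(MONTHS)]),
        closures_per_month=tuple(int(x) for x in fdf.loc["Roads closed", list(MONTHS)]),
    )

    wev = pd.read_csv(path / "weather_events.csv", float_precision="round_trip")
    bad = wev[wev["Penalty factor"] < 1]
    if len(bad):
        raise BundleError(
            f"weather penalty factors below 1 for events {bad['Event'].tolist()}"
        )
    events = {
        str(row["Event"]): WeatherEvent(
            duration_minutes=float(row["Duration (minutes)"]),
            penalty_factor=float(row["Penalty factor"]),
        )
        for _, row in wev.iterrows()
    }
    mdf = pd.read_csv(path / "meteorology.csv", float_precision="round_trip")
    weather = WeatherSpec(
        events=events,
        monthly_days={
            str(row["Days/Month"]): tuple(float(row[m]) for m in MONTHS)
            for _, row in mdf.iterrows()
        },
    )

    st = config.get("service_times", {})
    service = ServiceTimeSpec(
        prep_mu=float(st.get("prep_mu", 2.5)),
        prep_sigma=float(st.get("prep_sigma", 1.0)),
        prep_log_scale=bool(st.get("prep_log_scale", True)),
        on_scene_low=float(st.get("on_scene", [23.2, 37.2])[0]),
        on_scene_high=float(st.get("on_scene", [23.2, 37.2])[1]),
        hospital_min=float(st.get("hospital", [12.7, 13.7, 21.9])[0]),
        hospital_mode=float(st.get("hospital", [12.7, 13.7, 21.9])[1]),
        hospital_max=float(st.get("hospital", [12.7, 13.7, 21.9])[2]),
    )

    return Scenario(
        name=str(config["name"]),
        grid=grid,
        towns=towns,
        accident_rates=rates,
        weather=weather,
        service_times=service,
        calendar=calendar,
        horizon_days=int(config.get("horizon_days", 365)),
        replications=int(config.get("replications", 20)),
        seed=int(config.get("seed", 1)),
        ambulance_count=int(config.get("ambulances", 1)),
        thresholds=tuple(float(k) for k in config.get(
            "thresholds", (10, 20, 30, 40, 50, 60))),
        stress_multiplier=float(config.get("stress_multiplier", 1.0)),
        required_units=int(config.get("required_units", 1)),
        dispatch_from_hospital=bool(config.get("dispatch_from_hospital", False)),
        congestion_extra_minutes=float(config.get("congestion_extra_minutes", 60.0)),
        collection_tick_minutes=float(config.get("collection_tick_minutes", 5.0)),
        busy_penalty_mode=str(config.get("busy_penalty_mode", "remaining_time")),
        cell_size=float(config.get("cell_size", 1.0)),
    )


# -- indicator results --------------------------------------------------------

def export_indicators(results: ReplicationSet, out_dir: str | Path) -> Path:
    """Write phi (per replication + mean), per-town pi, and occupation CSVs."""
    if not results.results:
        raise ValueError("no replications to export")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ks = results.thresholds
    phi = pd.DataFrame(
        results.phi_matrix,
        index=[r.replication for r in results.results],
        columns=[f"phi_{int(k)}" for k in ks],
    )
    phi.index.name = "replication"
    phi.loc["mean"] = phi.mean(axis=0)
    phi.to_csv(out / "phi.csv", float_format="%.17g")

    pi = results.mean_pi.copy()
    pi.columns = [f"pi_{int(k)}" for k in ks]
    pi.index.name = "town"
    pi.to_csv(out / "pi.csv", float_format="%.17g")

    rows = []
    for r in results.results:
        frac = r.occupation.fractions
        for uid, row in frac.iterrows():
            rows.append({"replication": r.replication, "unit": uid,
                         **{c: row[c] for c in OCCUPATION_CATEGORIES}})
    pd.DataFrame(rows).to_csv(out / "occupation.csv", index=False,
                              float_format="%.17g")
    return out


def load_indicators(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Reload the three indicator CSVs written by :func:`export_indicators`."""
    out = Path(out_dir)
    return {
        "phi": pd.read_csv(out / "phi.csv", float_precision="round_trip", index_col="replication"),
        "pi": pd.read_csv(out / "pi.csv", float_precision="round_trip", index_col="town"),
        "occupation": pd.read_csv(out / "occupation.csv", float_precision="round_trip"),
    }


# -- GeoJSON isochrone bands --------------------------------------------------

def export_isochrone_bands(
    field: IsochroneField,
    thresholds=None,
    path: str | Path | None = None,
    cell_size: float = 1.0,
) -> dict:
    """Isochrone bands as a GeoJSON FeatureCollection.

    Each feature is the union of the cells whose rescue time falls in one
    band (K_{i-1}, K_i]; a final band collects everything beyond the last
    threshold (including unreachable cells).  Coordinates are abstract
    grid units scaled by ``cell_size`` — no real-world CRS is claimed.
    """
    ks = tuple(float(k) for k in (thresholds or field.thresholds))
    values = field.values
    if values.size == 0:
        raise ValueError("empty grid")
    n_bands = len(ks) + 1
    edges = np.array([-np.inf, *ks])
    features = []
    for b in range(n_bands):
        if b < len(ks):
            mask = (values > edges[b]) & (values <= edges[b + 1])
            label = f"({max(edges[b], 0):g}, {edges[b + 1]:g}] min"
        else:
            mask = values > edges[-1]
            label = f"> {edges[-1]:g} min"
        rr, cc = np.nonzero(mask)
        if len(rr) == 0:
            continue
        cellboxes = [
            box(c * cell_size, r * cell_size, (c + 1) * cell_size, (r + 1) * cell_size)
            for r, c in zip(rr.tolist(), cc.tolist())
        ]
        geom = unary_union(cellboxes)
        color = BAND_COLORS[min(b, len(BAND_COLORS) - 1)]
        features.append(
            {
                "type": "Feature",
                "properties": {"band": b, "label": label, "color": color,
                               "cells": int(mask.sum())},
                "geometry": mapping(geom),
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(collection))
    return collection
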