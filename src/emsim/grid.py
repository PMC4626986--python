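"""Grid road model: penalty overlays and shortest-time fields/routes.

The region is a lattice of square cells with 4-neighbour adjacency.  Each
road cell carries a base traversal time in minutes; non-road cells are
impassable (+inf).  Travelling from cell ``u`` into an adjacent cell ``v``
costs the *effective* traversal time of ``v`` at the departure instant, so
the duration of a path is the sum of the effective times of the cells
entered (the source cell is free).

Effective times layer time-dependent penalties on the base time:
weather events multiply by a factor (simultaneous events combine by max),
an active congestion overlay doubles, an active festivity/road-closure
overlay doubles, and a global stress multiplier scales everything.
Penalties are frozen at the evaluation instant for a whole leg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

Cell = tuple[int, int]

#: cell contents recognised by the model
CONTENT_KINDS = frozenset({"hub", "town", "road", "hospital", "empty"})

#: overlay causes that act as weather factors (combine by max)
WEATHER_CAUSES = frozenset({"rain", "snow", "fog", "ice"})

#: overlay causes that each double the traversal time on top of weather
DOUBLING_CAUSES = frozenset({"congestion", "festivity"})


class GridError(ValueError):
    """A structurally invalid road grid."""


class UnreachableError(RuntimeError):
    """Requested route endpoints are not connected on the road component."""


@dataclass(frozen=True)
class PenaltyOverlay:
    """A transient travel-time penalty.

    ``cells is None`` means the overlay covers the whole road network
    (how weather and region-wide road closures are modelled).  ``factor``
    is only meaningful for weather causes; congestion and festivity
    always double.
    """

    cells: frozenset[Cell] | None
    factor: float
    start: float
    end: float
    cause: str

    def __post_init__(self) -> None:
        if self.cause in WEATHER_CAUSES and self.factor < 1:
            raise ValueError(f"weather penalty factor must be >= 1, got {self.factor}")
        if self.end <= self.start:
            raise ValueError("overlay must have end > start")

    def active_at(self, t: float) -> bool:
        return self.start <= t < self.end

    def covers(self, cell: Cell) -> bool:
        return self.cells is None or cell in self.cells


class RoadGrid:
    """Cell lattice with contents and base per-cell traversal minutes.

    Parameters
    ----------
    shape
        (rows, cols) of the lattice.
    contents
        Mapping cell -> iterable of content tokens from :data:`CONTENT_KINDS`.
        Cells not listed are empty.
    base_minutes
        Mapping cell -> base traversal minutes (> 0).  Every cell with a
        non-empty content set except pure ``empty`` must appear here.
    """

    def __init__(
        self,
        shape: tuple[int, int],
        contents: Mapping[Cell, Iterable[str]],
        base_minutes: Mapping[Cell, float],
    ):
        self.shape = (int(shape[0]), int(shape[1]))
        self.contents: dict[Cell, frozenset[str]] = {}
        for cell, toks in contents.items():
            toks = frozenset(toks)
            unknown = toks - CONTENT_KINDS
            if unknown:
                raise GridError(f"unknown cell contents {sorted(unknown)} at {cell}")
            if toks - {"empty"}:
                self.contents[cell] = frozenset(toks - {"empty"})
        self.base = np.full(self.shape, np.inf)
        for cell, minutes in base_minutes.items():
            if minutes <= 0 or not np.isfinite(minutes):
                raise GridError(f"base traversal minutes must be finite > 0 at {cell}")
            self._check_bounds(cell)
            self.base[cell] = float(minutes)
        self._index_cells()
        self.validate()

    # -- construction helpers -------------------------------------------------

    def _check_bounds(self, cell: Cell) -> None:
        r, c = cell
        if not (0 <= r < self.shape[0] and 0 <= c < self.shape[1]):
            raise GridError(f"cell {cell} outside grid {self.shape}")

    def _index_cells(self) -> None:
        # road cells = any cell with a finite base time; hubs/towns/hospitals
        # sit on the road network
        rr, cc = np.nonzero(np.isfinite(self.base))
        self.road_cells: list[Cell] = list(zip(rr.tolist(), cc.tolist()))
        self.cell_index: dict[Cell, int] = {c: i for i, c in enumerate(self.road_cells)}
        self.n_road = len(self.road_cells)
        self.base_vec = self.base[rr, cc]
        # directed edge list u -> v among adjacent road cells (4-neighbour)
        us, vs = [], []
        for (r, c), i in self.cell_index.items():
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                j = self.cell_index.get((r + dr, c + dc))
                if j is not None:
                    us.append(i)
                    vs.append(j)
        self._edge_u = np.asarray(us, dtype=np.int32)
        self._edge_v = np.asarray(vs, dtype=np.int32)
        self._cells_arr = np.asarray(self.road_cells, dtype=np.int64)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RoadGrid)
            and self.shape == other.shape
            and self.contents == other.contents
            and np.array_equal(self.base, other.base)
        )

    # -- content queries ------------------------------------------------------

    def cells_with(self, kind: str) -> list[Cell]:
        return sorted(c for c, toks in self.contents.items() if kind in toks)

    @property
    def hub(self) -> Cell:
        return self.cells_with("hub")[0]

    @property
    def hospitals(self) -> list[Cell]:
        return self.cells_with("hospital")

    def is_road(self, cell: Cell) -> bool:
        r, c = cell
        return (
            0 <= r < self.shape[0]
            and 0 <= c < self.shape[1]
            and np.isfinite(self.base[cell])
        )

    def validate(self) -> None:
        hubs = self.cells_with("hub")
        if len(hubs) != 1:
            raise GridError(f"grid must contain exactly one hub, found {len(hubs)}")
        if not self.hospitals:
            raise GridError("grid must contain at least one hospital")
        for kind in ("hub", "town", "hospital"):
            for cell in self.cells_with(kind):
                if not self.is_road(cell):
                    raise GridError(f"{kind} cell {cell} has no traversal time")
        # single connected road component containing hub, hospitals, towns
        reach = np.isfinite(self.static_field_from(self.hub).values)
        rr, cc = np.nonzero(np.isfinite(self.base))
        if not reach[rr, cc].all():
            bad = [c for c in self.road_cells if not reach[c]]
            raise GridError(f"road cells disconnected from hub, e.g. {bad[:5]}")

    # -- effective times ------------------------------------------------------

    def effective_weight_vector(
        self,
        t: float = 0.0,
        overlays: Sequence[PenaltyOverlay] = (),
        stress: float = 1.0,
    ) -> np.ndarray:
        """Per-road-cell effective traversal minutes at instant ``t``."""
        w = self.base_vec * float(stress)
        wf = 1.0
        # per doubling cause: None = whole network, else union of covered cells
        doubled: dict[str, frozenset[Cell] | None] = {}
        for ov in overlays:
            if not ov.active_at(t):
                continue
            if ov.cause in WEATHER_CAUSES:
                wf = max(wf, ov.factor)
            elif ov.cause in DOUBLING_CAUSES:
                if ov.cells is None or doubled.get(ov.cause, frozenset()) is None:
                    doubled[ov.cause] = None
                else:
                    doubled[ov.cause] = doubled.get(ov.cause, frozenset()) | ov.cells
            else:
                raise ValueError(f"unknown overlay cause {ov.cause!r}")
        if wf != 1.0:
            w = w * wf
        for cells in doubled.values():
            if cells is None:
                w = w * 2.0
            else:
                idx = [self.cell_index[c] for c in cells if c in self.cell_index]
                w = w.copy()
                w[idx] *= 2.0
        return w

    def effective_traversal_time(
        self,
        cell: Cell,
        t: float = 0.0,
        overlays: Sequence[PenaltyOverlay] = (),
        stress: float = 1.0,
    ) -> float:
        """Minutes to traverse ``cell`` at instant ``t``; +inf off-road."""
        if not self.is_road(cell):
            return np.inf
        masked = [ov for ov in overlays if ov.covers(cell)]
        w = self.effective_weight_vector(t, masked, stress)
        return float(w[self.cell_index[cell]])

    # -- shortest-time fields and routes --------------------------------------

    def _dijkstra(self, source: Cell, w: np.ndarray) -> np.ndarray:
        i = self.cell_index.get(source)
        if i is None:
            raise GridError(f"source {source} is not on the road network")
        data = w[self._edge_v]
        mat = csr_matrix(
            (data, (self._edge_u, self._edge_v)), shape=(self.n_road, self.n_road)
        )
        return _csgraph_dijkstra(mat, directed=True, indices=i)

    def static_field_from(self, source: Cell) -> "TravelTimeField":
        return self.shortest_time_field(source)

    def shortest_time_field(
        self,
        source: Cell,
        t: float = 0.0,
        overlays: Sequence[PenaltyOverlay] = (),
        stress: float = 1.0,
    ) -> "TravelTimeField":
        """Exact single-source shortest times with penalties frozen at ``t``."""
        w = self.effective_weight_vector(t, overlays, stress)
        dist = self._dijkstra(source, w)
        values = np.full(self.shape, np.inf)
        values[self._cells_arr[:, 0], self._cells_arr[:, 1]] = dist
        return TravelTimeField(source=source, values=values, instant=t)

    def route(
        self,
        start: Cell,
        goal: Cell,
        t: float = 0.0,
        overlays: Sequence[PenaltyOverlay] = (),
        stress: float = 1.0,
    ) -> tuple[list[Cell], float]:
        """Shortest path ``start -> goal`` and its duration in minutes.

        The returned path lists the cells *entered* (``start`` excluded,
        ``goal`` included); ``start == goal`` gives an empty path.  Ties are
        broken deterministically by lexicographic cell order during the
        backward walk from ``goal``.
        """
        if not self.is_road(start) or not self.is_road(goal):
            raise GridError("route endpoints must be road cells")
        if start == goal:
            return [], 0.0
        w = self.effective_weight_vector(t, overlays, stress)
        dist = self._dijkstra(start, w)
        d_goal = dist[self.cell_index[goal]]
        if not np.isfinite(d_goal):
            raise UnreachableError(f"{goal} unreachable from {start}")
        path: list[Cell] = [goal]
        cur = goal
        while cur != start:
            i = self.cell_index[cur]
            best: Cell | None = None
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nb = (cur[0] + dr, cur[1] + dc)
                j = self.cell_index.get(nb)
                if j is None:
                    continue
                if abs(dist[j] + w[i] - dist[i]) <= 1e-9 * max(1.0, dist[i]):
                    if best is None or nb < best:
                        best = nb
            if best is None:  # numerically impossible on a valid field
                raise UnreachableError(f"route reconstruction failed at {cur}")
            cur = best
            if cur != start:
                path.append(cur)
        path.reverse()
        return path, float(d_goal)


@dataclass
class TravelTimeField:
    """Per-cell minimal travel time from ``source`` at ``instant`` (minutes)."""

    source: Cell
    values: np.ndarray
    instant: float = 0.0

    def at(self, cell: Cell) -> float:
        return float(self.values[cell])
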