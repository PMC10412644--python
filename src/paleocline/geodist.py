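"""Cost-surface construction and anisotropic least-cost-path analysis.

Reproduces a GIS-style "path distance" workflow on regular grids: water-
cover percentages are reclassified to friction classes on a 1-16 scale,
ice-sheet cells add a large penalty (+999), and movement between adjacent
cells is modulated by a vertical factor computed from the slope angle
(the vertical relative moving angle, VRMA) with an inverse-linear profile
that favours gentle downhill movement and forbids slopes beyond a cutoff
(default 5 degrees).

Accumulated cost is computed by multi-source Dijkstra over the
8-connected grid; a backlink raster records, for every cell, the
direction of the next cell on the way back to the nearest source, from
which least-cost paths are traced. Costs are abstract accumulated travel
cost; no conversion to kilometres is attempted.

Rasters are read and written as ESRI ASCII grids (.asc).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Water-percentage class boundaries -> friction cost. 0% maps to 1,
#: (0,20] to 2, (20,40] to 4, (40,60] to 6, (60,80] to 8, (80,100] to 16.
WATER_CLASS_BOUNDS = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
WATER_CLASS_COSTS = (1.0, 2.0, 4.0, 6.0, 8.0, 16.0)

ICE_PENALTY = 999.0
DEFAULT_VRMA_DEG = 5.0
DEFAULT_SLOPE_PARAM = 1.0 / 45.0
VF_FLOOR = 0.05

# 8-neighbour offsets and backlink direction codes (1=E clockwise to 8=NE);
# 0 marks a source cell.
_NEIGHBOURS = (
    (0, 1, 1), (1, 1, 2), (1, 0, 3), (1, -1, 4),
    (0, -1, 5), (-1, -1, 6), (-1, 0, 7), (-1, 1, 8),
)


@dataclass
class Raster:
    """Regular grid in the ESRI ASCII dialect; row 0 is the top row."""

    values: np.ndarray
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("raster must be a non-empty 2-D grid")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def congruent(self, other: "Raster") -> bool:
        return (self.values.shape == other.values.shape
                and math.isclose(self.xllcorner, other.xllcorner)
                and math.isclose(self.yllcorner, other.yllcorner)
                and math.isclose(self.cellsize, other.cellsize))

    def is_nodata(self) -> np.ndarray:
        return self.values == self.nodata

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing world coordinates (x, y)."""
        col = int(math.floor((x - self.xllcorner) / self.cellsize))
        row = self.nrows - 1 - int(math.floor((y - self.yllcorner) / self.cellsize))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) outside the grid")
        return row, col

    def like(self, values: np.ndarray) -> "Raster":
        return Raster(values, self.xllcorner, self.yllcorner,
                      self.cellsize, self.nodata)


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key}")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: body shape {values.shape} does not match header")
    return Raster(values, header["xllcorner"], header["yllcorner"],
                  header["cellsize"], header.get("nodata_value", -9999.0))


def write_ascii_grid(raster: Raster, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner:.10g}\n")
        fh.write(f"yllcorner {raster.yllcorner:.10g}\n")
        fh.write(f"cellsize {raster.cellsize:.10g}\n")
        fh.write(f"NODATA_value {raster.nodata:.10g}\n")
        for row in raster.values:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Cost-surface construction
# ---------------------------------------------------------------------------

def reclassify_water(water: Raster) -> Raster:
    """Reclassify water-cover percentages to the six 1-16 friction classes."""
    v = water.values
    nodata = water.is_nodata()
    valid = ~nodata
    bad = valid & ((v < 0) | (v > 100))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"water percentage {v[r, c]} out of [0, 100] at cell ({r}, {c})")
    out = np.full_like(v, water.nodata)
    prev = -np.inf
    for bound, cost in zip(WATER_CLASS_BOUNDS, WATER_CLASS_COSTS):
        sel = valid & (v > prev) & (v <= bound)
        out[sel] = cost
        prev = bound
    return water.like(out)


def add_ice(cost: Raster, ice: Raster) -> Raster:
    """Add the ice-sheet penalty (+999) where the ice mask is 1."""
    if not cost.congruent(ice):
        raise ValueError("cost and ice rasters are not congruent")
    out = cost.values.copy()
    sel = (~cost.is_nodata()) & (ice.values == 1)
    out[sel] += ICE_PENALTY
    return cost.like(out)


def vertical_factor(elev_from: float, elev_to: float,
                    horizontal_distance: float,
                    vrma_cut: float = DEFAULT_VRMA_DEG,
                    slope_param: float = DEFAULT_SLOPE_PARAM) -> float:
    """Inverse-linear vertical factor for one move.

    theta = atan2(rise, run) in degrees, positive uphill. Moves steeper
    than ``vrma_cut`` in either direction are impassable (factor inf);
    otherwise VF = 1 + theta * slope_param, floored at a small positive
    constant, so gentle downhill is cheaper than flat.
    """
    if horizontal_distance <= 0:
        raise ValueError("horizontal distance must be positive")
    theta = math.degrees(math.atan2(elev_to - elev_from, horizontal_distance))
    if abs(theta) > vrma_cut:
        return math.inf
    return max(VF_FLOOR, 1.0 + theta * slope_param)


# ---------------------------------------------------------------------------
# Path distance (multi-source Dijkstra) and LCP extraction
# ---------------------------------------------------------------------------

@dataclass
class PathDistanceResult:
    accumulated: Raster
    backlink: Raster
    sources: list[tuple[int, int]]


def path_distance(cost: Raster, elevation: Raster | None,
                  sources: list[tuple[float, float]], *,
                  vrma_cut: float = DEFAULT_VRMA_DEG,
                  slope_param: float = DEFAULT_SLOPE_PARAM,
                  geographic: bool = False,
                  sources_are_cells: bool = False) -> PathDistanceResult:
    """Accumulated cost and backlink rasters from one or more sources.

    The move cost from cell u to 8-neighbour v is
    ``d(u, v) * (cost_u + cost_v) / 2 * VF(u -> v)`` with d the cell-centre
    distance (cellsize for orthogonal moves, cellsize * sqrt(2) diagonal).
    With ``geographic`` the east-west component of d is scaled by
    cos(latitude) of the row centre, a local spherical correction for
    grids in degrees.

    ``sources`` are world (x, y) coordinates, or (row, col) cells with
    ``sources_are_cells``.
    """
    if elevation is not None and not cost.congruent(elevation):
        raise ValueError("cost and elevation rasters are not congruent")
    if not sources:
        raise ValueError("need at least one source")
    nrows, ncols = cost.nrows, cost.ncols
    cv = cost.values
    nod = cost.is_nodata()
    if elevation is not None:
        nod = nod | elevation.is_nodata()
        ev = elevation.values
    cells: list[tuple[int, int]] = []
    for p in sources:
        rc = tuple(int(v) for v in p) if sources_are_cells else cost.cell_of(*p)
        if nod[rc]:
            raise ValueError(f"source cell {rc} is nodata")
        cells.append(rc)

    cs = cost.cellsize
    if geographic:
        lat = (cost.yllcorner
               + (nrows - 0.5 - np.arange(nrows)) * cs) * math.pi / 180.0
        ew = cs * np.cos(lat)
    acc = np.full((nrows, ncols), math.inf)
    back = np.full((nrows, ncols), -1, dtype=np.int16)
    heap: list[tuple[float, int, int]] = []
    for r, c in cells:
        acc[r, c] = 0.0
        back[r, c] = 0
        heapq.heappush(heap, (0.0, r, c))
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > acc[r, c]:
            continue
        for dr, dc, code in _NEIGHBOURS:
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < nrows and 0 <= c2 < ncols) or nod[r2, c2]:
                continue
            if geographic:
                dx = ew[r] * abs(dc) if dr == 0 else (
                    0.0 if dc == 0 else 0.5 * (ew[r] + ew[r2]))
                dist = math.hypot(dx, cs * abs(dr)) if dr else dx
            else:
                dist = cs * math.sqrt(2) if (dr and dc) else cs
            vf = 1.0
            if elevation is not None:
                vf = vertical_factor(ev[r, c], ev[r2, c2], dist,
                                     vrma_cut, slope_param)
                if math.isinf(vf):
                    continue
            step = dist * 0.5 * (cv[r, c] + cv[r2, c2]) * vf
            nd = d + step
            if nd < acc[r2, c2]:
                acc[r2, c2] = nd
                back[r2, c2] = code
                heapq.heappush(heap, (nd, r2, c2))
    return PathDistanceResult(cost.like(acc), cost.like(back.astype(float)),
                              cells)


def least_cost_path(result: PathDistanceResult,
                    destination: tuple[float, float] | tuple[int, int], *,
                    destination_is_cell: bool = False,
                    ) -> tuple[list[tuple[int, int]], float]:
    """Backlink-traced path from a destination back to the nearest source.

    Returns the cell path (destination first) and the total accumulated
    cost at the destination.
    """
    acc = result.accumulated
    if destination_is_cell:
        r, c = (int(v) for v in destination)
    else:
        r, c = acc.cell_of(*destination)
    total = float(acc.values[r, c])
    if math.isinf(total):
        raise ValueError(f"destination cell ({r}, {c}) is unreachable")
    back = result.backlink.values.astype(int)
    # invert the move codes: backlink points to the cell to move into
    inverse = {code: (-dr, -dc) for dr, dc, code in _NEIGHBOURS}
    path = [(r, c)]
    while back[r, c] != 0:
        dr, dc = inverse[back[r, c]]
        r, c = r + dr, c + dc
        path.append((r, c))
        if len(path) > acc.values.size:
            raise RuntimeError("backlink cycle detected")
    return path, total


def multi_source_summary(cost: Raster, elevation: Raster | None,
                         source_sets: dict[str, list[tuple[float, float]]],
                         destinations: list[tuple[str, float, float]], *,
                         vrma_cut: float = DEFAULT_VRMA_DEG,
                         slope_param: float = DEFAULT_SLOPE_PARAM,
                         geographic: bool = False,
                         points_are_cells: bool = False) -> pd.DataFrame:
    """Min / median / total accumulated cost per destination per source set.

    One path-distance run per source point, then a per-destination
    reduction across the points of each named set (e.g. the five-point
    WHG core set and the single AfontovaGora3 point).
    """
    rows = []
    for set_name, points in source_sets.items():
        per_point = []
        for p in points:
            res = path_distance(cost, elevation, [p], vrma_cut=vrma_cut,
                                slope_param=slope_param, geographic=geographic,
                                sources_are_cells=points_are_cells)
            per_point.append(res.accumulated)
        for dest_name, x, y in destinations:
            if points_are_cells:
                r, c = int(x), int(y)
            else:
                r, c = cost.cell_of(x, y)
            vals = np.array([a.values[r, c] for a in per_point])
            rows.append({"source_set": set_name, "destination": dest_name,
                         "min": float(vals.min()),
                         "median": float(np.median(vals)),
                         "total": float(vals.sum()),
                         "n_sources": len(points)})
    return pd.DataFrame(rows)
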