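"""Species range construction from occurrence points.

A species range is the union of up to four convex polygons — one convex hull
per world quadrant, so that disjunct distributions (e.g., separated by a
hemisphere boundary or a continental barrier) are not bridged by a single
global hull. Polygons are rasterized onto an equal-area grid by cell-center
inclusion, then refined by removing cells whose maximal depth falls outside
the species' known depth range. Range size in km² is the occupied cell count
times the cell area.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon, box, mapping


class InsufficientOccurrencesError(ValueError):
    """Raised when a species has too few occurrence points to build a range."""


class GridAlignmentError(ValueError):
    """Raised when a raster does not align with the grid it is used against."""


@dataclass(frozen=True)
class GridSpec:
    """Equal-area analysis grid.

    The grid lives in projected (equal-area) kilometre coordinates with the
    origin at the lower-left corner. Cell ``(row, col)`` spans
    ``[col*cell_km, (col+1)*cell_km] x [row*cell_km, (row+1)*cell_km]`` and is
    identified by its center. Linear cell indices are row-major and 0-based,
    so every cell's area is exactly ``cell_km**2``.
    """

    rows: int
    cols: int
    cell_km: float = 10.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_km <= 0:
            raise ValueError("cell size must be positive")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    @property
    def width_km(self) -> float:
        return self.cols * self.cell_km

    @property
    def height_km(self) -> float:
        return self.rows * self.cell_km

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km**2

    def index(self, row: int, col: int) -> int:
        return row * self.cols + col

    def rc(self, index: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        return np.divmod(index, self.cols)

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of (x, y) centers in row-major order."""
        xs = (np.arange(self.cols) + 0.5) * self.cell_km
        ys = (np.arange(self.rows) + 0.5) * self.cell_km
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class RangePolygonSet:
    """Up to four convex polygons, one per world quadrant."""

    species_id: str
    polygons: list[Polygon] = field(default_factory=list)

    def __iter__(self):
        return iter(self.polygons)

    def __len__(self) -> int:
        return len(self.polygons)

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"species_id": self.species_id, "quadrant": i},
                    "geometry": mapping(poly),
                }
                for i, poly in enumerate(self.polygons)
            ],
        }


@dataclass
class RangeRaster:
    """Occupied cells of one species on a :class:`GridSpec`."""

    species_id: str
    grid: GridSpec
    cells: np.ndarray  # sorted linear cell indices, dtype int

    def __post_init__(self) -> None:
        self.cells = np.unique(np.asarray(self.cells, dtype=np.int64))
        if self.cells.size and (self.cells.min() < 0 or self.cells.max() >= self.grid.n_cells):
            raise ValueError("cell index outside grid extent")

    @property
    def n_cells(self) -> int:
        return int(self.cells.size)

    @property
    def area_km2(self) -> float:
        return self.n_cells * self.grid.cell_area_km2

    def as_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid.n_cells, dtype=bool)
        mask[self.cells] = True
        return mask.reshape(self.grid.rows, self.grid.cols)


def _quadrant_assign(points: np.ndarray, x_split: float, y_split: float) -> np.ndarray:
    """Quadrant index per point: 0=SW, 1=SE, 2=NW, 3=NE (boundary goes east/north)."""
    east = points[:, 0] >= x_split
    north = points[:, 1] >= y_split
    return east.astype(int) + 2 * north.astype(int)


def _convex_polygon(points: np.ndarray, buffer_radius: float) -> Polygon:
    """Convex polygon from a quadrant's points.

    Three or more non-collinear points give their convex hull. Degenerate
    configurations (1–2 points, or collinear points) are inflated by
    ``buffer_radius`` so that every retained species gets a usable polygon.
    """
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    if isinstance(hull, Polygon) and hull.area > 0:
        return hull
    return hull.buffer(buffer_radius, quad_segs=8).convex_hull


def hull_by_quadrant(
    occurrences: np.ndarray,
    quadrant_bounds: tuple[float, float],
    species_id: str = "",
    buffer_radius: float = 5.0,
) -> RangePolygonSet:
    """Build per-quadrant convex hulls around a species' occurrence points.

    Parameters
    ----------
    occurrences
        (n, 2) array of projected (x, y) points, n >= 2.
    quadrant_bounds
        ``(x_split, y_split)`` — the two lines dividing the world into four
        quadrants (the analogue of the equator and an ocean-dividing
        meridian). Points on a split line belong to the east/north quadrant.
    buffer_radius
        Inflation radius (km) for quadrants whose points are too few or
        collinear to span a polygon; default is half a 10 km cell.
    """
    pts = np.asarray(occurrences, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("occurrences must be an (n, 2) array")
    pts = np.unique(pts, axis=0)
    if pts.shape[0] < 2:
        raise InsufficientOccurrencesError(
            f"species {species_id!r}: need >= 2 distinct occurrence points, got {pts.shape[0]}"
        )
    x_split, y_split = quadrant_bounds
    quad = _quadrant_assign(pts, x_split, y_split)
    # Quadrant half-planes, bounded generously by the point cloud extent so
    # degenerate (buffered) polygons can be clipped back into their quadrant.
    pad = 4.0 * buffer_radius + 1.0
    x0, y0 = pts.min(axis=0) - pad
    x1, y1 = pts.max(axis=0) + pad
    quad_boxes = {
        0: box(x0, y0, x_split, y_split),
        1: box(x_split, y0, x1, y_split),
        2: box(x0, y_split, x_split, y1),
        3: box(x_split, y_split, x1, y1),
    }
    polygons: list[Polygon] = []
    for q in range(4):
        qpts = pts[quad == q]
        if qpts.shape[0] == 0:
            continue
        poly = _convex_polygon(qpts, buffer_radius)
        if poly.area == 0:
            continue
        clipped = poly.intersection(quad_boxes[q])
        if not clipped.is_empty and clipped.area > 0:
            polygons.append(clipped.convex_hull)
    return RangePolygonSet(species_id=species_id, polygons=polygons)


def rasterize(polygons: RangePolygonSet, grid: GridSpec) -> RangeRaster:
    """Rasterize polygons onto the grid: a cell is occupied iff its center
    lies inside or on the boundary of any polygon."""
    occupied = np.zeros(grid.n_cells, dtype=bool)
    centers = grid.cell_centers()
    for poly in polygons:
        minx, miny, maxx, maxy = poly.bounds
        cand = np.nonzero(
            (centers[:, 0] >= minx - 1e-12)
            & (centers[:, 0] <= maxx + 1e-12)
            & (centers[:, 1] >= miny - 1e-12)
            & (centers[:, 1] <= maxy + 1e-12)
        )[0]
        if cand.size == 0:
            continue
        hit = shapely.intersects_xy(poly, centers[cand, 0], centers[cand, 1])
        occupied[cand[hit]] = True
    if len(polygons) > 0 and not occupied.any():
        warnings.warn(
            f"species {polygons.species_id!r}: polygons cover no cell center "
            "(outside grid extent?); empty raster",
            stacklevel=2,
        )
    return RangeRaster(
        species_id=polygons.species_id, grid=grid, cells=np.nonzero(occupied)[0]
    )


def depth_refine(
    range_raster: RangeRaster,
    depth_raster: np.ndarray,
    dmin_m: float,
    dmax_m: float,
) -> RangeRaster:
    """Drop cells whose maximal depth lies outside ``[dmin_m, dmax_m]``.

    ``depth_raster`` holds one maximal-depth value (m, positive down) per
    grid cell, shaped ``(rows, cols)``. The result is always a subset of the
    input range.
    """
    grid = range_raster.grid
    depth = np.asarray(depth_raster, dtype=float)
    if depth.shape != (grid.rows, grid.cols):
        raise GridAlignmentError(
            f"depth raster shape {depth.shape} does not match grid ({grid.rows}, {grid.cols})"
        )
    if dmin_m > dmax_m:
        raise ValueError("dmin_m must not exceed dmax_m")
    flat = depth.ravel()
    keep = range_raster.cells[
        (flat[range_raster.cells] >= dmin_m) & (flat[range_raster.cells] <= dmax_m)
    ]
    return RangeRaster(species_id=range_raster.species_id, grid=grid, cells=keep)


def build_range(
    occurrences: np.ndarray,
    grid: GridSpec,
    quadrant_bounds: tuple[float, float] | None = None,
    depth_raster: np.ndarray | None = None,
    dmin_m: float | None = None,
    dmax_m: float | None = None,
    species_id: str = "",
) -> RangeRaster:
    """Hull -> rasterize -> (optional) depth refinement for one species.

    ``quadrant_bounds`` defaults to the grid center, the synthetic analogue of
    the equator plus a dividing meridian. The cells containing the occurrence
    points themselves are always part of the pre-refinement range (a hull
    vertex can sit so close to a cell corner that the cell's center falls
    outside the hull; the observation still belongs to the range).
    """
    if quadrant_bounds is None:
        quadrant_bounds = (grid.width_km / 2.0, grid.height_km / 2.0)
    polys = hull_by_quadrant(
        occurrences, quadrant_bounds, species_id=species_id, buffer_radius=grid.cell_km / 2.0
    )
    rr = rasterize(polys, grid)
    pts = np.asarray(occurrences, dtype=float)
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= grid.width_km)
        & (pts[:, 1] >= 0) & (pts[:, 1] <= grid.height_km)
    )
    if inside.any():
        cols = np.clip((pts[inside, 0] // grid.cell_km).astype(int), 0, grid.cols - 1)
        rows = np.clip((pts[inside, 1] // grid.cell_km).astype(int), 0, grid.rows - 1)
        occ_cells = rows * grid.cols + cols
        rr = RangeRaster(species_id, grid, np.union1d(rr.cells, occ_cells))
    if depth_raster is not None and dmin_m is not None and dmax_m is not None:
        rr = depth_refine(rr, depth_raster, dmin_m, dmax_m)
    return rr


def build_ranges_for_pool(
    occurrences: pd.DataFrame,
    grid: GridSpec,
    quadrant_bounds: tuple[float, float] | None = None,
    depth_raster: np.ndarray | None = None,
    depth_limits: pd.DataFrame | None = None,
) -> tuple[dict[str, RangeRaster], list[str]]:
    """Build ranges for every species in an occurrence table.

    Parameters
    ----------
    occurrences
        Long table with columns ``species_id, x, y``.
    depth_limits
        Optional frame indexed by species id with columns
        ``depth_min_m, depth_max_m``; when given (with ``depth_raster``),
        ranges are depth-refined. Missing limits skip refinement for that
        species.

    Returns the ranges plus the ids of species flagged unbuildable (fewer
    than 2 distinct points) or emptied by depth refinement.
    """
    ranges: dict[str, RangeRaster] = {}
    flagged: list[str] = []
    for sid, sub in occurrences.groupby("species_id", sort=True):
        pts = sub[["x", "y"]].to_numpy(dtype=float)
        dmin = dmax = None
        if depth_limits is not None and sid in depth_limits.index:
            row = depth_limits.loc[sid]
            if pd.notna(row["depth_min_m"]) and pd.notna(row["depth_max_m"]):
                dmin, dmax = float(row["depth_min_m"]), float(row["depth_max_m"])
        try:
            rr = build_range(
                pts,
                grid,
                quadrant_bounds,
                depth_raster if dmin is not None else None,
                dmin,
                dmax,
                species_id=str(sid),
            )
        except InsufficientOccurrencesError:
            flagged.append(str(sid))
            continue
        if rr.n_cells == 0:
            flagged.append(str(sid))
        ranges[str(sid)] = rr
    return ranges, flagged


# ---------------------------------------------------------------- text I/O

def ranges_to_csv(ranges: dict[str, RangeRaster], path) -> None:
    """Sparse long-format export: one row per (species_id, cell_index)."""
    rows = [
        {"species_id": sid, "cell_index": int(c)}
        for sid, rr in sorted(ranges.items())
        for c in rr.cells
    ]
    pd.DataFrame(rows, columns=["species_id", "cell_index"]).to_csv(path, index=False)


def ranges_from_csv(path, grid: GridSpec) -> dict[str, RangeRaster]:
    df = pd.read_csv(path, dtype={"species_id": str})
    return {
        str(sid): RangeRaster(str(sid), grid, sub["cell_index"].to_numpy())
        for sid, sub in df.groupby("species_id", sort=True)
    }


def polygons_to_geojson(polysets: list[RangePolygonSet], path) -> None:
    features = []
    for ps in polysets:
        features.extend(ps.to_geojson()["features"])
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
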