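"""Plot boundaries to polygons, zone rasterization, and per-plot class areas.

This mirrors the standard GIS workflow for plot-level extraction from a
classified ortho-mosaic: digitized boundary polylines are noded and closed
into plot polygons, the polygons are burned into an integer zone raster on
the mosaic grid, and class pixels are tabulated per zone and converted to
areas in m^2.

Rasterization uses the centre-point rule: a cell belongs to the polygon
containing its centre. Cells whose centre falls exactly on a shared edge
are assigned to the polygon with the lower id (a deterministic tie rule).
The same rule is used everywhere pixels are matched to polygons (training
regions, rendered plots, zones), so pixel sets are consistent across the
pipeline.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon
from shapely.ops import polygonize, unary_union
from shapely.strtree import STRtree

from .grids import GridSpec, ZoneRaster, ClassifiedRaster, CLASSES, CLASS_IDS, same_grid

log = logging.getLogger(__name__)

#: fixed column order of the exported plot table
PLOT_TABLE_COLUMNS = [
    "plot_id", "trial", "variety", "rep", "block", "plot_area_m2",
    "area_soil_m2", "area_green_m2", "area_yellow_m2", "area_dry_m2",
]


def _snap_endpoints(lines: list[LineString], tol: float) -> list[LineString]:
    """Cluster line endpoints within ``tol`` and move each to its cluster mean."""
    endpoints = []
    for line in lines:
        coords = np.asarray(line.coords)
        endpoints.append(coords[0])
        endpoints.append(coords[-1])
    endpoints = np.asarray(endpoints)

    # greedy clustering; endpoint counts are small (hand-digitized boundaries)
    cluster_of = np.full(len(endpoints), -1, dtype=int)
    centers: list[np.ndarray] = []
    for i, pt in enumerate(endpoints):
        for ci, c in enumerate(centers):
            if np.hypot(*(pt - c)) <= tol:
                cluster_of[i] = ci
                break
        else:
            cluster_of[i] = len(centers)
            centers.append(pt.copy())

    members: dict[int, list[int]] = {}
    for i, ci in enumerate(cluster_of):
        members.setdefault(ci, []).append(i)
    mean_of = {ci: endpoints[idx].mean(axis=0) for ci, idx in members.items()}

    snapped = []
    for k, line in enumerate(lines):
        coords = np.asarray(line.coords, dtype=float).copy()
        coords[0] = mean_of[cluster_of[2 * k]]
        coords[-1] = mean_of[cluster_of[2 * k + 1]]
        snapped.append(LineString(coords))
    return snapped


def polylines_to_polygons(
    lines: list[LineString], snap_tol: float = 0.01
) -> list[tuple[int, Polygon, float]]:
    """Close digitized boundary polylines into plot polygons.

    Endpoints within ``snap_tol`` metres are snapped together, the line
    arrangement is noded, and every bounded face becomes a polygon. Faces
    that fail to close (dangling lines) simply yield no polygon; the
    shortfall is logged, not fatal.

    Returns ``(object_id, polygon, area_m2)`` triples with auto-incrementing
    ids assigned in row-major (north to south, west to east) centroid order.
    """
    if snap_tol < 0:
        raise ValueError("snap_tol must be non-negative")
    lines = [l for l in lines if l.length > 0]
    if not lines:
        return []
    if snap_tol > 0:
        lines = _snap_endpoints(lines, snap_tol)
    noded = unary_union(lines)
    faces = list(polygonize(noded))
    if not faces:
        log.warning("no closed faces found among %d polylines", len(lines))
    faces.sort(key=lambda p: (-p.centroid.y, p.centroid.x))
    return [(i + 1, poly, poly.area) for i, poly in enumerate(faces)]


def _check_no_overlap(ids: list[int], polys: list[Polygon]) -> None:
    tree = STRtree(polys)
    offenders = set()
    for i, poly in enumerate(polys):
        for j in tree.query(poly):
            j = int(j)
            if j <= i:
                continue
            inter = polys[j].intersection(poly)
            if inter.area > 1e-9:
                offenders.update((ids[i], ids[j]))
    if offenders:
        raise ValueError(
            f"overlapping plot polygons (ids {sorted(offenders)}); "
            "zones must be pairwise disjoint")


def rasterize_polygons(
    polys: list[Polygon], ids: list[int], grid: GridSpec,
    check_overlap: bool = True,
) -> np.ndarray:
    """Burn polygons into an int32 raster by the centre-point rule.

    Polygons are processed in ascending id order and a cell is only written
    once, so a centre lying exactly on a shared edge goes to the lower id.
    """
    if len(polys) != len(ids):
        raise ValueError("polys and ids must have equal length")
    if check_overlap:
        _check_no_overlap(list(ids), list(polys))
    out = np.zeros(grid.shape, dtype=np.int32)
    order = np.argsort(ids, kind="stable")
    for k in order:
        poly, pid = polys[k], int(ids[k])
        row0, row1, col0, col1 = grid.window(poly.bounds)
        if row1 <= row0 or col1 <= col0:
            continue
        rows = np.arange(row0, row1)
        cols = np.arange(col0, col1)
        cgrid, rgrid = np.meshgrid(cols, rows)
        x, y = grid.cell_centers(rgrid.ravel(), cgrid.ravel())
        # intersects includes the boundary, so edge centres are candidates
        hit = shapely.intersects_xy(poly, x, y).reshape(rgrid.shape)
        window = out[row0:row1, col0:col1]
        write = hit & (window == 0)
        window[write] = pid
    return out


def rasterize_zones(
    polygons: list[tuple[int, Polygon]], grid: GridSpec
) -> ZoneRaster:
    """Convert plot polygons into a zone raster on the mosaic grid."""
    ids = [pid for pid, _ in polygons]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate zone ids {dupes}")
    polys = [p for _, p in polygons]
    zones = rasterize_polygons(polys, ids, grid)
    return ZoneRaster(zones, grid, ids=sorted(int(i) for i in ids))


def tabulate_area(
    zones: ZoneRaster, classes: ClassifiedRaster, gsd: float | None = None
) -> pd.DataFrame:
    """Per-plot class areas in m^2 (pixel count x gsd^2), one row per zone.

    Zones that rasterized to zero cells are retained as all-zero rows, so
    downstream joins stay complete.
    """
    if not same_grid(zones.grid, classes.grid):
        raise ValueError("zone raster and classified raster are on different grids")
    gsd = zones.grid.gsd if gsd is None else gsd
    px_area = gsd * gsd

    zflat = zones.zones.ravel()
    lflat = classes.labels.ravel().astype(np.int64)
    n_codes = max(CLASS_IDS.values()) + 1  # labels 0..4
    inside = zflat > 0
    combo = zflat[inside].astype(np.int64) * n_codes + lflat[inside]
    max_zone = int(zflat.max(initial=0))
    counts = np.bincount(combo, minlength=(max_zone + 1) * n_codes)
    counts = counts.reshape(max_zone + 1, n_codes)

    rows = []
    for zid in zones.ids:
        c = counts[zid] if zid <= max_zone else np.zeros(n_codes, dtype=int)
        row = {"plot_id": int(zid), "plot_area_m2": float(c.sum() * px_area)}
        for name in CLASSES:
            row[f"area_{name}_m2"] = float(c[CLASS_IDS[name]] * px_area)
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["plot_id", "plot_area_m2"]
        + [f"area_{n}_m2" for n in CLASSES])


def join_attributes(areas: pd.DataFrame, layout) -> pd.DataFrame:
    """Join tabulated areas to layout attributes on plot_id.

    Returns the plot table in :data:`PLOT_TABLE_COLUMNS` order. Duplicate or
    unmatched plot ids are integrity errors.
    """
    if areas.empty:
        log.warning("empty area table; joined plot table is empty")
        return pd.DataFrame(columns=PLOT_TABLE_COLUMNS)
    dup = areas["plot_id"][areas["plot_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate plot_id in area table: {sorted(set(dup))}")
    attrs = layout.frame()[["plot_id", "trial", "variety", "rep", "block"]]
    missing = set(areas["plot_id"]) - set(attrs["plot_id"])
    if missing:
        raise ValueError(f"plot ids absent from layout: {sorted(missing)}")
    joined = areas.merge(attrs, on="plot_id", how="left")
    return joined[PLOT_TABLE_COLUMNS]
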