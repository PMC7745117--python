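"""Raster grid conventions and in-memory raster containers.

World coordinates are projected metres. Rasters are row-major from the
north-west corner: row 0 is the northernmost row, column 0 the westernmost
column, pixels are square with side ``gsd`` metres, and a cell is addressed
by its centre point. The centre of cell (row, col) sits at

    x = origin_x + (col + 0.5) * gsd
    y = origin_y - (row + 0.5) * gsd

where (origin_x, origin_y) is the world coordinate of the NW raster corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

#: class legend shared by every labelled raster in the pipeline
NODATA = 0
LEGEND = {1: "soil", 2: "green", 3: "yellow", 4: "dry"}
CLASS_IDS = {v: k for k, v in LEGEND.items()}
CLASSES = ("soil", "green", "yellow", "dry")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid (metres, square pixels)."""

    origin_x: float
    origin_y: float
    gsd: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.gsd <= 0:
            raise ValueError(f"gsd must be positive, got {self.gsd}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("raster must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area(self) -> float:
        """Ground area of one pixel in m^2."""
        return self.gsd * self.gsd

    @classmethod
    def from_extent(
        cls, width_m: float, height_m: float, gsd: float,
        origin_x: float = 0.0, origin_y: float | None = None,
    ) -> "GridSpec":
        """Grid covering a width_m x height_m rectangle; dims = ceil(extent/gsd).

        By default the NW origin is placed at (0, height_m) so the rectangle
        [0, width_m] x [0, height_m] is covered from its top edge down.
        """
        if width_m <= 0 or height_m <= 0:
            raise ValueError("extent must be positive")
        n_cols = math.ceil(width_m / gsd)
        n_rows = math.ceil(height_m / gsd)
        if origin_y is None:
            origin_y = height_m
        return cls(origin_x, origin_y, gsd, n_rows, n_cols)

    def cell_centers(
        self, rows: np.ndarray, cols: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of the centres of the given cells."""
        x = self.origin_x + (np.asarray(cols) + 0.5) * self.gsd
        y = self.origin_y - (np.asarray(rows) + 0.5) * self.gsd
        return x, y

    def window(
        self, bounds: tuple[float, float, float, float]
    ) -> tuple[int, int, int, int]:
        """Half-open (row0, row1, col0, col1) covering a world bbox, clipped."""
        minx, miny, maxx, maxy = bounds
        col0 = max(0, int(math.floor((minx - self.origin_x) / self.gsd)))
        col1 = min(self.n_cols, int(math.ceil((maxx - self.origin_x) / self.gsd)))
        row0 = max(0, int(math.floor((self.origin_y - maxy) / self.gsd)))
        row1 = min(self.n_rows, int(math.ceil((self.origin_y - miny) / self.gsd)))
        return row0, row1, col0, col1


@dataclass
class Mosaic:
    """Georeferenced 3-band 8-bit image on a :class:`GridSpec`."""

    data: np.ndarray  # (n_rows, n_cols, 3) uint8
    grid: GridSpec
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("mosaic data must be (rows, cols, 3)")
        if self.data.shape[:2] != self.grid.shape:
            raise ValueError("mosaic data shape does not match its grid")


@dataclass
class ClassifiedRaster:
    """Single-band label raster; 0 is nodata, labels follow :data:`LEGEND`."""

    labels: np.ndarray  # (n_rows, n_cols) uint8
    grid: GridSpec
    legend: dict[int, str] = field(default_factory=lambda: dict(LEGEND))
    nodata: int = NODATA

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label raster shape does not match its grid")


@dataclass
class ZoneRaster:
    """Integer zone-id raster; 0 means 'no zone'. ``ids`` lists every zone,
    including zones that rasterized to zero cells."""

    zones: np.ndarray  # (n_rows, n_cols) int32
    grid: GridSpec
    ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.zones = np.asarray(self.zones)
        if self.zones.shape != self.grid.shape:
            raise ValueError("zone raster shape does not match its grid")
        if not self.ids:
            present = np.unique(self.zones)
            self.ids = [int(z) for z in present if z != 0]


def same_grid(a: GridSpec, b: GridSpec, tol: float = 1e-9) -> bool:
    return (
        a.shape == b.shape
        and abs(a.gsd - b.gsd) <= tol
        and abs(a.origin_x - b.origin_x) <= tol
        and abs(a.origin_y - b.origin_y) <= tol
    )
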