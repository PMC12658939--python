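"""Equal-area analysis grid: rasterization, mask algebra, and raster I/O.

Every layer in the pipeline lives on one shared planar lattice of square
pixels (nominally 10 km, i.e. ~100 km^2 per pixel). Row 0 is the northern
edge; coordinates are planar kilometres on an assumed equal-area projection.

Rasterization uses the center-containment dialect: a pixel is set iff its
center point falls strictly inside the polygon. This mirrors the default
vector-to-raster behaviour of the GDAL toolchain and is fixed (not an
option) so that all downstream pixel counts are reproducible.

Rasters serialize to the ESRI ASCII grid format (plain text), the portable
single-band exchange format used here in place of GeoTIFF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon, shape as shapely_shape, mapping as shapely_mapping

__all__ = [
    "GridSpec",
    "BoolRaster",
    "rasterize",
    "area_km2",
    "dilate_one_pixel",
    "write_ascii_grid",
    "read_ascii_grid",
    "polygon_to_geojson",
    "polygon_from_geojson",
]


@dataclass(frozen=True)
class GridSpec:
    """Shared equal-area pixel lattice.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions; row 0 is the northernmost row.
    pixel_size_km
        Side length of the square pixels in km. The default 10 km gives
        the ~100 km^2 pixels all analyses assume.
    origin_x_km, origin_y_km
        Planar coordinates of the north-west corner of the grid.
    """

    n_rows: int
    n_cols: int
    pixel_size_km: float = 10.0
    origin_x_km: float = 0.0
    origin_y_km: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.pixel_size_km <= 0:
            raise ValueError("pixel_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area_km2(self) -> float:
        return self.pixel_size_km**2

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates as 2-D arrays of shape (n_rows, n_cols)."""
        h = self.pixel_size_km
        cols = self.origin_x_km + (np.arange(self.n_cols) + 0.5) * h
        rows = self.origin_y_km - (np.arange(self.n_rows) + 0.5) * h
        x, y = np.meshgrid(cols, rows)
        return x, y


@dataclass
class BoolRaster:
    """Boolean lattice layer (presence mask) on a :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @classmethod
    def zeros(cls, grid: GridSpec) -> "BoolRaster":
        return cls(grid, np.zeros(grid.shape, dtype=bool))

    def copy(self) -> "BoolRaster":
        return BoolRaster(self.grid, self.values.copy())

    def __and__(self, other: "BoolRaster") -> "BoolRaster":
        _check_same_grid(self, other)
        return BoolRaster(self.grid, self.values & other.values)

    def __or__(self, other: "BoolRaster") -> "BoolRaster":
        _check_same_grid(self, other)
        return BoolRaster(self.grid, self.values | other.values)

    def __invert__(self) -> "BoolRaster":
        return BoolRaster(self.grid, ~self.values)

    def count(self) -> int:
        return int(self.values.sum())


def _check_same_grid(a: BoolRaster, b: BoolRaster) -> None:
    if a.grid != b.grid:
        raise ValueError("rasters live on different grids")


def _validate_polygon(poly: Polygon) -> Polygon:
    if not isinstance(poly, Polygon):
        raise TypeError(f"expected a shapely Polygon, got {type(poly).__name__}")
    if poly.is_empty or len(poly.exterior.coords) < 4:
        raise ValueError("degenerate polygon: fewer than 3 vertices")
    if not poly.is_valid:
        raise ValueError("invalid polygon (self-intersecting or malformed ring)")
    if poly.area <= 0:
        raise ValueError("degenerate polygon: zero area")
    return poly


def rasterize(poly: Polygon, grid: GridSpec) -> BoolRaster:
    """Burn a polygon onto the grid with the center-containment rule.

    A pixel is TRUE iff its center lies strictly inside the polygon
    (boundary centers are excluded; the half-pixel offset between centers
    and typical geometry edges makes this tie-break immaterial in practice).
    """
    _validate_polygon(poly)
    out = np.zeros(grid.shape, dtype=bool)
    h = grid.pixel_size_km
    minx, miny, maxx, maxy = poly.bounds
    # Candidate window: only pixels whose centers can fall in the bbox.
    c0 = max(0, int(np.floor((minx - grid.origin_x_km) / h - 0.5)))
    c1 = min(grid.n_cols - 1, int(np.ceil((maxx - grid.origin_x_km) / h - 0.5)))
    r0 = max(0, int(np.floor((grid.origin_y_km - maxy) / h - 0.5)))
    r1 = min(grid.n_rows - 1, int(np.ceil((grid.origin_y_km - miny) / h - 0.5)))
    if c0 > c1 or r0 > r1:
        return BoolRaster(grid, out)
    xs = grid.origin_x_km + (np.arange(c0, c1 + 1) + 0.5) * h
    ys = grid.origin_y_km - (np.arange(r0, r1 + 1) + 0.5) * h
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    out[r0 : r1 + 1, c0 : c1 + 1] = inside
    return BoolRaster(grid, out)


def area_km2(mask: BoolRaster) -> float:
    """Area of the TRUE set: pixel count times the (constant) pixel area."""
    return mask.count() * mask.grid.pixel_area_km2


_MOORE = np.ones((3, 3), dtype=bool)


def dilate_one_pixel(mask: BoolRaster) -> BoolRaster:
    """Moore (8-neighbour) dilation by one pixel, clamped at grid edges.

    One pixel corresponds to the 10-km buffer band drawn around protected
    areas to probe spillover.
    """
    return BoolRaster(mask.grid, ndimage.binary_dilation(mask.values, structure=_MOORE))


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (text raster exchange format)
# ---------------------------------------------------------------------------

def write_ascii_grid(
    path: str | Path,
    values: np.ndarray | BoolRaster,
    grid: GridSpec | None = None,
    nodata: float = -1.0,
    fmt: str = "%.10g",
) -> None:
    """Write a single-band raster as an ESRI ASCII grid.

    Boolean rasters are written as 0/1 integers. NaNs become ``nodata``.
    """
    if isinstance(values, BoolRaster):
        grid = values.grid
        arr = values.values.astype(np.int64)
        fmt = "%d"
        nodata_repr = "255"
    else:
        if grid is None:
            raise ValueError("grid is required when writing a bare array")
        arr = np.asarray(values)
        if arr.shape != grid.shape:
            raise ValueError("array shape does not match grid")
        if np.issubdtype(arr.dtype, np.integer):
            fmt = "%d"
        else:
            arr = np.where(np.isnan(arr.astype(float)), nodata, arr)
        nodata_repr = fmt % nodata
    h = grid.pixel_size_km
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x_km!r}\n"
        f"yllcorner {(grid.origin_y_km - grid.n_rows * h)!r}\n"
        f"cellsize {h!r}\n"
        f"NODATA_value {nodata_repr}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec, float]:
    """Read an ESRI ASCII grid; returns (values, grid, nodata)."""
    with open(path) as fh:
        hdr: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(hdr["nrows"]), int(hdr["ncols"])
    values = values.reshape(n_rows, n_cols)
    h = hdr["cellsize"]
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        pixel_size_km=h,
        origin_x_km=hdr["xllcorner"],
        origin_y_km=hdr["yllcorner"] + n_rows * h,
    )
    return values, grid, hdr["nodata_value"]


def polygon_to_geojson(poly: Polygon) -> dict:
    return shapely_mapping(poly)


def polygon_from_geojson(obj: dict) -> Polygon:
    geom = shapely_shape(obj)
    return _validate_polygon(geom)
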