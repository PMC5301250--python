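"""Planar raster grids: nearest-neighbour resampling, block aggregation, zonal statistics.

All grids live in one shared planar, equal-area coordinate frame (lengths in
metres unless a caller chooses otherwise).  Rows run top-down: the grid origin
is the upper-left corner, and the centre of pixel ``(row, col)`` sits at
``(x0 + (col + 0.5) * dx,  y0 - (row + 0.5) * dy)``.

Zonal statistics use a centre-point membership rule: a pixel belongs to a
polygon zone iff its centre lies inside the polygon.  Centres exactly on the
polygon boundary are resolved deterministically — they count as inside on the
bottom and left edges and outside on the top and right edges (a half-open
convention), which makes zonal sums additive across polygons that tile a
region along pixel-boundary-free seams.

Raster files are read and written in the ESRI ASCII grid format (plain text,
square pixels), which round-trips every grid this package produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

GridKind = Literal["categorical", "continuous", "fraction"]

__all__ = [
    "Grid",
    "ZonalResult",
    "read_ascii_grid",
    "write_ascii_grid",
    "resample_nearest",
    "aggregate_fraction",
    "zone_mask",
    "zonal_stats",
]


@dataclass
class Grid:
    """A single-band raster on a regular grid.

    Parameters
    ----------
    values
        2-D array, row 0 at the top.
    origin
        ``(x, y)`` of the upper-left corner of the upper-left pixel.
    pixel_size
        ``(dx, dy)``, both positive.
    kind
        ``"categorical"`` (integer classes), ``"continuous"``, or
        ``"fraction"`` (values in [0, 1]).
    nodata
        Sentinel marking missing pixels; ``NaN`` is accepted for float grids.
    meta
        Free-form provenance flags (e.g. ``{"padded": True}``).
    """

    values: np.ndarray
    origin: tuple[float, float]
    pixel_size: tuple[float, float]
    kind: GridKind = "continuous"
    nodata: float | int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got shape {self.values.shape}")
        dx, dy = self.pixel_size
        if dx <= 0 or dy <= 0:
            raise ValueError(f"pixel sizes must be positive, got {self.pixel_size}")
        if self.kind == "categorical" and not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("categorical grid requires an integer dtype")
        if self.kind == "fraction":
            valid = self.valid_mask()
            v = self.values[valid]
            if v.size and (v.min() < 0 or v.max() > 1):
                raise ValueError("fraction grid has values outside [0, 1]")

    # -- geometry ----------------------------------------------------------
    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def pixel_area(self) -> float:
        return self.pixel_size[0] * self.pixel_size[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full extent."""
        x0, y0 = self.origin
        dx, dy = self.pixel_size
        return (x0, y0 - self.height * dy, x0 + self.width * dx, y0)

    def x_centres(self) -> np.ndarray:
        x0 = self.origin[0]
        dx = self.pixel_size[0]
        return x0 + (np.arange(self.width) + 0.5) * dx

    def y_centres(self) -> np.ndarray:
        y0 = self.origin[1]
        dy = self.pixel_size[1]
        return y0 - (np.arange(self.height) + 0.5) * dy

    def valid_mask(self) -> np.ndarray:
        if self.nodata is None:
            return np.ones(self.values.shape, dtype=bool)
        if isinstance(self.nodata, float) and np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def copy(self) -> "Grid":
        return Grid(self.values.copy(), self.origin, self.pixel_size,
                    self.kind, self.nodata, dict(self.meta))


@dataclass(frozen=True)
class ZonalResult:
    """Summary of raster pixels whose centres fall inside one polygon zone.

    ``count`` is the number of valid (non-nodata, unmasked) zone pixels;
    statistics are over those pixels only.  ``mean`` is ``None`` — never a
    silent 0 — when the zone holds no valid pixel.
    """

    count: int
    predicate_count: int | None
    mean: float | None
    sum: float
    covered_area: float


# ---------------------------------------------------------------------------
# ASCII grid I/O
# ---------------------------------------------------------------------------

_DEFAULT_NODATA = -9999


def write_ascii_grid(grid: Grid, path: str | Path) -> Path:
    """Write a grid as an ESRI ASCII raster (requires square pixels)."""
    dx, dy = grid.pixel_size
    if not np.isclose(dx, dy):
        raise ValueError("ASCII grid format requires square pixels")
    path = Path(path)
    nodata = grid.nodata if grid.nodata is not None else _DEFAULT_NODATA
    x0, y0 = grid.origin
    yll = y0 - grid.height * dy
    header = (
        f"ncols {grid.width}\n"
        f"nrows {grid.height}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {dx!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    vals = grid.values
    fmt = "%d" if np.issubdtype(vals.dtype, np.integer) else "%.17g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)
    return path


def read_ascii_grid(path: str | Path, kind: GridKind = "continuous") -> Grid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    values = values.reshape(nrows, ncols)
    if kind == "categorical":
        values = values.astype(np.int64)
        nodata: float | int = int(header["nodata_value"])
    else:
        nodata = header["nodata_value"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return Grid(values, origin, (cell, cell), kind=kind, nodata=nodata)


# ---------------------------------------------------------------------------
# Resampling and aggregation
# ---------------------------------------------------------------------------

def resample_nearest(grid: Grid, target_pixel_size: float | tuple[float, float]) -> Grid:
    """Resample to a new pixel size by nearest-neighbour centre lookup.

    Each output pixel takes the value of the input pixel containing the output
    pixel's centre, so the output value set is a subset of the input's — the
    underlying values are never altered.  The output covers the same extent
    (the number of output pixels is rounded to best match it).
    """
    if grid.values.size == 0:
        raise ValueError("cannot resample an empty grid")
    if np.isscalar(target_pixel_size):
        tdx = tdy = float(target_pixel_size)  # type: ignore[arg-type]
    else:
        tdx, tdy = map(float, target_pixel_size)  # type: ignore[misc]
    if tdx <= 0 or tdy <= 0:
        raise ValueError("target pixel size must be positive")
    dx, dy = grid.pixel_size
    out_w = max(1, round(grid.width * dx / tdx))
    out_h = max(1, round(grid.height * dy / tdy))
    x0, y0 = grid.origin
    xc = x0 + (np.arange(out_w) + 0.5) * tdx
    yc = y0 - (np.arange(out_h) + 0.5) * tdy
    cols = np.clip(np.floor((xc - x0) / dx).astype(int), 0, grid.width - 1)
    rows = np.clip(np.floor((y0 - yc) / dy).astype(int), 0, grid.height - 1)
    values = grid.values[np.ix_(rows, cols)]
    return Grid(values, grid.origin, (tdx, tdy), grid.kind, grid.nodata,
                dict(grid.meta))


def aggregate_fraction(fine: Grid, factor: int) -> Grid:
    """Aggregate a binary grid into per-block means (area-averaged fractions).

    Each coarse output cell is the arithmetic mean of its ``factor x factor``
    block of fine cells, i.e. the fraction of the coarse cell that is 1.  If
    the fine dimensions are not divisible by ``factor`` the grid is padded
    with zeros on the bottom/right and ``meta["padded"]`` is set.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"aggregation factor must be a positive integer, got {factor}")
    factor = int(factor)
    vals = fine.values
    bad = np.setdiff1d(np.unique(vals), [0, 1])
    if bad.size:
        raise ValueError(f"aggregate_fraction requires a binary grid; found value {bad[0]!r}")
    padded = False
    pad_h = (-vals.shape[0]) % factor
    pad_w = (-vals.shape[1]) % factor
    if pad_h or pad_w:
        vals = np.pad(vals, ((0, pad_h), (0, pad_w)))
        padded = True
    h, w = vals.shape[0] // factor, vals.shape[1] // factor
    coarse = vals.reshape(h, factor, w, factor).mean(axis=(1, 3))
    dx, dy = fine.pixel_size
    meta = dict(fine.meta)
    meta["padded"] = padded
    return Grid(coarse, fine.origin, (dx * factor, dy * factor),
                kind="fraction", nodata=None, meta=meta)


# ---------------------------------------------------------------------------
# Zonal statistics
# ---------------------------------------------------------------------------

def zone_mask(grid: Grid, polygon: BaseGeometry) -> np.ndarray:
    """Boolean mask of pixels whose centre lies in ``polygon``.

    Boundary centres follow the half-open rule documented in the module
    docstring: a centre sitting exactly on the polygon outline is classified
    by nudging it by +eps in x and +y (towards the upper right), so bottom and
    left edges include, top and right edges exclude.
    """
    if polygon.is_empty:
        return np.zeros(grid.values.shape, dtype=bool)
    if not polygon.is_valid:
        raise ValueError("invalid polygon geometry for zonal statistics")
    mask = np.zeros(grid.values.shape, dtype=bool)
    xmin, ymin, xmax, ymax = polygon.bounds
    gxmin, gymin, gxmax, gymax = grid.bounds
    if xmax < gxmin or xmin > gxmax or ymax < gymin or ymin > gymax:
        return mask
    dx, dy = grid.pixel_size
    x0, y0 = grid.origin
    c0 = max(0, int(np.floor((xmin - x0) / dx)) - 1)
    c1 = min(grid.width, int(np.ceil((xmax - x0) / dx)) + 1)
    r0 = max(0, int(np.floor((y0 - ymax) / dy)) - 1)
    r1 = min(grid.height, int(np.ceil((y0 - ymin) / dy)) + 1)
    if c0 >= c1 or r0 >= r1:
        return mask
    xc = x0 + (np.arange(c0, c1) + 0.5) * dx
    yc = y0 - (np.arange(r0, r1) + 0.5) * dy
    X, Y = np.meshgrid(xc, yc)
    inside = shapely.contains_xy(polygon, X, Y)
    # resolve centres lying exactly on the outline with the half-open rule
    pts = shapely.points(X, Y)
    on_edge = shapely.covers(polygon, pts) & ~inside
    if on_edge.any():
        eps = 1e-9 * min(dx, dy)
        xb = X[on_edge] + eps
        yb = Y[on_edge] + eps
        inside[on_edge] = shapely.contains_xy(polygon, xb, yb)
    mask[r0:r1, c0:c1] = inside
    return mask


def zonal_stats(
    grid: Grid,
    polygon: BaseGeometry,
    predicate: Callable[[np.ndarray], np.ndarray] | None = None,
    mask: np.ndarray | None = None,
) -> ZonalResult:
    """Count / mean / sum of the pixels whose centres fall inside ``polygon``.

    ``predicate`` (a vectorised boolean function of the values, e.g. a
    forest-class test) yields ``predicate_count``; ``mask`` restricts the
    statistics to pixels where it is True (used to average one layer over
    the zone defined jointly with another layer, such as biomass over forest
    pixels).  No-data pixels never contribute; a polygon disjoint from the
    grid gives a zero-count result rather than an error.
    """
    zmask = zone_mask(grid, polygon)
    sel = zmask & grid.valid_mask()
    if mask is not None:
        if mask.shape != grid.values.shape:
            raise ValueError("mask shape does not match grid shape")
        sel &= mask
    vals = grid.values[sel]
    count = int(vals.size)
    pred_count = None
    if predicate is not None:
        pred_count = int(np.count_nonzero(predicate(vals))) if count else 0
    total = float(vals.sum()) if count else 0.0
    mean = total / count if count else None
    return ZonalResult(
        count=count,
        predicate_count=pred_count,
        mean=mean,
        sum=total,
        covered_area=count * grid.pixel_area,
    )
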