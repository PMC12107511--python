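"""Equal-area raster grids and the landscape habitat operations built on them.

Grids live on an axis-aligned equal-area plane with coordinates in kilometres
(the synthetic analogue of a Behrmann-projected map).  Cells are registered to
their lower-left edge with half-open extents ``[edge, edge + grain)``; a point
on a shared edge therefore belongs to the higher-index cell.  Values are stored
row-major as ``values[iy, ix]`` with y increasing along axis 0.

Rasters are serialised as ESRI ASCII grids (plain text), the one standard
raster format that round-trips losslessly without binary dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Grid",
    "GridError",
    "resample_equal_area",
    "aggregate_fraction",
    "natural_habitat_at",
    "read_ascii_grid",
    "write_ascii_grid",
]


class GridError(ValueError):
    """Raised for missing georeferencing, out-of-extent lookups and bad factors."""


@dataclass(frozen=True)
class Grid:
    """A single-band raster on an equal-area km grid.

    Parameters
    ----------
    values
        2-D array, ``values[iy, ix]``; NaN marks missing cells.
    x0, y0
        Coordinates (km) of the outer lower-left corner.
    grain_km
        Cell edge length in km; must be positive for a georeferenced grid.
    """

    values: np.ndarray
    x0: float
    y0: float
    grain_km: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise GridError("grid values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def georeferenced(self) -> bool:
        return bool(np.isfinite(self.x0) and np.isfinite(self.y0) and self.grain_km > 0)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinate vectors along each axis."""
        ny, nx = self.values.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.grain_km
        ys = self.y0 + (np.arange(ny) + 0.5) * self.grain_km
        return xs, ys

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Indices of the half-open cell containing each point; errors outside."""
        if not self.georeferenced:
            raise GridError("grid has no georeferencing")
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor((x - self.x0) / self.grain_km).astype(int)
        iy = np.floor((y - self.y0) / self.grain_km).astype(int)
        ny, nx = self.values.shape
        bad = (ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)
        if np.any(bad):
            xb = np.atleast_1d(x)[np.atleast_1d(bad)][:1]
            yb = np.atleast_1d(y)[np.atleast_1d(bad)][:1]
            raise GridError(
                f"point(s) outside grid extent, e.g. ({float(xb[0]):.3f}, {float(yb[0]):.3f})"
            )
        return ix, iy

    def value_at(self, x, y) -> np.ndarray:
        ix, iy = self.cell_index(x, y)
        return self.values[iy, ix]


def resample_equal_area(
    source: Grid,
    target_grain_km: float = 1.0,
    *,
    clamp: tuple[float, float] | None = (0.0, 1.0),
) -> Grid:
    """Bilinearly resample a fractional-cover raster onto a finer/coarser km grid.

    The target grid covers the same extent, registered to the same origin.
    Each target cell centre is interpolated from the four surrounding source
    cell centres; outside the outermost centres the edge value is held
    (interpolation weights clipped), as terra/GDAL do.  Fractional covers are
    clamped back into ``[0, 1]`` after interpolation.
    """
    if not source.georeferenced:
        raise GridError("source raster has no georeferencing")
    if target_grain_km <= 0:
        raise GridError("target grain must be positive")
    ny, nx = source.shape
    width = nx * source.grain_km
    height = ny * source.grain_km
    tx = int(round(width / target_grain_km))
    ty = int(round(height / target_grain_km))
    if tx < 1 or ty < 1:
        raise GridError("target grain larger than source extent")

    # fractional index of each target centre in source-centre coordinates
    xt = source.x0 + (np.arange(tx) + 0.5) * target_grain_km
    yt = source.y0 + (np.arange(ty) + 0.5) * target_grain_km
    gx = (xt - (source.x0 + 0.5 * source.grain_km)) / source.grain_km
    gy = (yt - (source.y0 + 0.5 * source.grain_km)) / source.grain_km
    gx = np.clip(gx, 0.0, nx - 1.0)
    gy = np.clip(gy, 0.0, ny - 1.0)
    ix0 = np.minimum(np.floor(gx).astype(int), max(nx - 2, 0))
    iy0 = np.minimum(np.floor(gy).astype(int), max(ny - 2, 0))
    wx = gx - ix0
    wy = gy - iy0
    ix1 = np.minimum(ix0 + 1, nx - 1)
    iy1 = np.minimum(iy0 + 1, ny - 1)

    v = source.values
    wy2 = wy[:, None]
    wx2 = wx[None, :]
    out = (
        v[np.ix_(iy0, ix0)] * (1 - wy2) * (1 - wx2)
        + v[np.ix_(iy0, ix1)] * (1 - wy2) * wx2
        + v[np.ix_(iy1, ix0)] * wy2 * (1 - wx2)
        + v[np.ix_(iy1, ix1)] * wy2 * wx2
    )
    if clamp is not None:
        out = np.clip(out, clamp[0], clamp[1])
    return Grid(out, source.x0, source.y0, target_grain_km)


def aggregate_fraction(grid: Grid, factor: int) -> Grid:
    """Aggregate by an integer factor, each coarse cell the mean of its block.

    Dimensions not divisible by ``factor`` are padded with missing cells;
    missing cells are excluded from block means (a fully missing block stays
    missing).
    """
    if factor < 1 or int(factor) != factor:
        raise GridError(f"aggregation factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return replace(grid, values=grid.values.copy())
    ny, nx = grid.shape
    py = (-ny) % factor
    px = (-nx) % factor
    v = np.pad(grid.values, ((0, py), (0, px)), constant_values=np.nan)
    blocks = v.reshape(v.shape[0] // factor, factor, v.shape[1] // factor, factor)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(blocks.transpose(0, 2, 1, 3).reshape(
            blocks.shape[0], blocks.shape[2], factor * factor), axis=2)
    return Grid(out, grid.x0, grid.y0, grid.grain_km * factor)


def natural_habitat_at(grid: Grid, x, y) -> np.ndarray:
    """Fractional natural habitat of the cell containing each site (no interpolation)."""
    return grid.value_at(x, y)


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (NODATA = -9999)."""
    ny, nx = grid.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {grid.x0}\nyllcorner {grid.y0}\n"
        f"cellsize {grid.grain_km}\nNODATA_value -9999\n"
    )
    vals = np.where(np.isfinite(grid.values), grid.values, -9999.0)
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI convention: first data row is the top (highest y) row
        np.savetxt(fh, vals[::-1], fmt="%.8g")


def read_ascii_grid(path: str | Path) -> Grid:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1].copy()
    vals[vals == hdr.get("nodata_value", -9999.0)] = np.nan
    return Grid(vals, hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"])
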