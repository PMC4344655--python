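"""Geolocated raster grids and monthly stacks, with netCDF round-trip I/O.

Conventions
-----------
* Plate carrée lat/lon only; uniform cell size per axis; coordinates refer
  to cell centers.
* The latitude axis is stored north-to-south: row 0 is the northernmost
  row, matching the common convention of level-3 mapped ocean products.
* Validity is carried as a boolean mask (``True`` = sea / valid). On disk a
  single nodata sentinel encodes it (NaN for floating grids, 0 for integer
  class maps); in memory the mask is authoritative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import xarray as xr

__all__ = [
    "GridGeo",
    "RasterGrid",
    "MonthlyStack",
    "read_grid",
    "write_grid",
    "read_stack",
    "write_stack",
    "crop_grid",
    "combine_masks",
]

_INT_NODATA = 0


@dataclass(frozen=True)
class GridGeo:
    """Extent and shape of a regular lat/lon grid (cell-edge bounds)."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("degenerate extent: require lon_min < lon_max and lat_min < lat_max")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def cell_width(self) -> float:
        return (self.lon_max - self.lon_min) / self.n_cols

    @property
    def cell_height(self) -> float:
        return (self.lat_max - self.lat_min) / self.n_rows

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_width

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (row 0 northernmost)."""
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.cell_height


@dataclass
class RasterGrid:
    """One 2-D geolocated field with a validity mask.

    ``values`` must be finite wherever ``mask`` is True; invalid cells may
    hold anything (typically NaN).
    """

    geo: GridGeo
    values: np.ndarray
    mask: np.ndarray
    units: str = ""
    name: str = "field"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.geo.shape or self.mask.shape != self.geo.shape:
            raise ValueError(
                f"shape mismatch: values {self.values.shape}, mask {self.mask.shape}, "
                f"geo {self.geo.shape}"
            )
        if self.values.dtype.kind == "f" and not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside the valid mask")

    def masked_values(self) -> np.ndarray:
        """Float copy with invalid cells set to NaN."""
        out = self.values.astype(float, copy=True)
        out[~self.mask] = np.nan
        return out


@dataclass
class MonthlyStack:
    """Time-ordered sequence of co-registered RasterGrids."""

    grids: list[RasterGrid]
    times: list[tuple[int, int]] = field(default_factory=list)  # (year, month)

    def __post_init__(self) -> None:
        if not self.grids:
            raise ValueError("empty stack")
        if len(self.times) != len(self.grids):
            raise ValueError("one (year, month) entry required per grid")
        geo = self.grids[0].geo
        for g in self.grids:
            if g.geo != geo:
                raise ValueError("stack grids are not co-registered")
        keys = [y * 12 + (m - 1) for y, m in self.times]
        if any(not 1 <= m <= 12 for _, m in self.times):
            raise ValueError("months must lie in 1..12")
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("time index must be strictly increasing")

    @property
    def geo(self) -> GridGeo:
        return self.grids[0].geo

    def __len__(self) -> int:
        return len(self.grids)

    def to_array(self) -> np.ndarray:
        """(T, rows, cols) float array with NaN at invalid cells."""
        return np.stack([g.masked_values() for g in self.grids])


# ---------------------------------------------------------------------------
# netCDF I/O (CF-style lat/lon coordinate variables; scipy backend)
# ---------------------------------------------------------------------------

def _geo_from_coords(lat: np.ndarray, lon: np.ndarray) -> GridGeo:
    if lat.size > 1:
        dlat = float(lat[0] - lat[1])
        if dlat <= 0:
            raise ValueError("latitude coordinate must decrease (north-to-south rows)")
        if not np.allclose(np.diff(lat), -dlat, rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform latitude spacing")
    else:
        dlat = 1.0
    if lon.size > 1:
        dlon = float(lon[1] - lon[0])
        if dlon <= 0:
            raise ValueError("longitude coordinate must increase")
        if not np.allclose(np.diff(lon), dlon, rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform longitude spacing")
    else:
        dlon = 1.0
    return GridGeo(
        lon_min=float(lon[0]) - dlon / 2,
        lon_max=float(lon[-1]) + dlon / 2,
        lat_min=float(lat[-1]) - dlat / 2,
        lat_max=float(lat[0]) + dlat / 2,
        n_rows=lat.size,
        n_cols=lon.size,
    )


def _grid_to_dataarray(grid: RasterGrid) -> xr.DataArray:
    if grid.values.dtype.kind in "iu":
        data = grid.values.astype("int32", copy=True)
        data[~grid.mask] = _INT_NODATA
        attrs = {"units": grid.units, "nodata": _INT_NODATA}
    else:
        data = grid.masked_values()
        attrs = {"units": grid.units}
    return xr.DataArray(
        data,
        dims=("lat", "lon"),
        coords={"lat": grid.geo.lat_centers(), "lon": grid.geo.lon_centers()},
        name=grid.name,
        attrs=attrs,
    )


def write_grid(grid: RasterGrid, path) -> None:
    """Write one grid to netCDF; the mask becomes the nodata sentinel."""
    _grid_to_dataarray(grid).to_dataset().to_netcdf(path, engine="scipy")


def read_grid(path, variable: str) -> RasterGrid:
    """Read ``variable`` from a netCDF file written by :func:`write_grid`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds:
            raise KeyError(f"variable {variable!r} not found in {path}")
        da = ds[variable].load()
    geo = _geo_from_coords(da["lat"].values, da["lon"].values)
    vals = da.values
    if vals.dtype.kind in "iu" or "nodata" in da.attrs:
        nodata = int(da.attrs.get("nodata", _INT_NODATA))
        vals = vals.astype("int32")
        mask = vals != nodata
    else:
        vals = vals.astype(float)
        mask = np.isfinite(vals)
    return RasterGrid(geo=geo, values=vals, mask=mask,
                      units=str(da.attrs.get("units", "")), name=variable)


def write_stack(stack: MonthlyStack, path, name: str | None = None) -> None:
    """Write a MonthlyStack as a (time, lat, lon) netCDF variable.

    The time coordinate is encoded as the integer year*100 + month, which
    netCDF3 stores losslessly.
    """
    name = name or stack.grids[0].name
    geo = stack.geo
    data = stack.to_array()
    tcoord = np.array([y * 100 + m for y, m in stack.times], dtype="int32")
    da = xr.DataArray(
        data,
        dims=("time", "lat", "lon"),
        coords={"time": tcoord, "lat": geo.lat_centers(), "lon": geo.lon_centers()},
        name=name,
        attrs={"units": stack.grids[0].units, "time_encoding": "yyyymm"},
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_stack(path, variable: str) -> MonthlyStack:
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds:
            raise KeyError(f"variable {variable!r} not found in {path}")
        da = ds[variable].load()
    geo = _geo_from_coords(da["lat"].values, da["lon"].values)
    units = str(da.attrs.get("units", ""))
    grids, times = [], []
    for ti, tval in enumerate(np.asarray(da["time"].values, dtype=int)):
        vals = da.values[ti].astype(float)
        grids.append(RasterGrid(geo=geo, values=vals, mask=np.isfinite(vals),
                                units=units, name=variable))
        times.append((tval // 100, tval % 100))
    return MonthlyStack(grids=grids, times=times)


# ---------------------------------------------------------------------------
# Cropping and mask algebra
# ---------------------------------------------------------------------------

def crop_grid(grid: RasterGrid, bbox: tuple[float, float, float, float]) -> RasterGrid:
    """Crop to the cells whose centers fall inside ``bbox``.

    ``bbox`` is (lon_min, lon_max, lat_min, lat_max); inclusion is half-open
    [min, max) on each axis so adjacent crops never double-count a cell.
    """
    lon_min, lon_max, lat_min, lat_max = bbox
    lons = grid.geo.lon_centers()
    lats = grid.geo.lat_centers()
    col_keep = (lons >= lon_min) & (lons < lon_max)
    row_keep = (lats >= lat_min) & (lats < lat_max)
    if not col_keep.any() or not row_keep.any():
        raise ValueError("crop bbox does not intersect the grid")
    rows = np.where(row_keep)[0]
    cols = np.where(col_keep)[0]
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    cw, ch = grid.geo.cell_width, grid.geo.cell_height
    new_geo = GridGeo(
        lon_min=grid.geo.lon_min + c0 * cw,
        lon_max=grid.geo.lon_min + c1 * cw,
        lat_min=grid.geo.lat_max - r1 * ch,
        lat_max=grid.geo.lat_max - r0 * ch,
        n_rows=r1 - r0,
        n_cols=c1 - c0,
    )
    return RasterGrid(
        geo=new_geo,
        values=grid.values[r0:r1, c0:c1].copy(),
        mask=grid.mask[r0:r1, c0:c1].copy(),
        units=grid.units,
        name=grid.name,
    )


def combine_masks(grids: list[RasterGrid]) -> np.ndarray:
    """Intersection of validity masks: a cell is valid iff valid everywhere."""
    if not grids:
        raise ValueError("no grids given")
    geo = grids[0].geo
    out = np.ones(geo.shape, dtype=bool)
    for g in grids:
        if g.geo != geo:
            raise ValueError("grids are not co-registered")
        out &= g.mask
    return out
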