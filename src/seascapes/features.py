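"""Feature assembly: regridding, collinearity screening, range scaling.

Brings the six climatological variables onto one grid, screens pairwise
collinearity (report-and-warn, never auto-drop), standardizes each variable
by its observed range so all six contribute equally to the clustering, and
assembles the sea-pixel x variable feature table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .grids import GridGeo, RasterGrid
from .synthetic import UNITS, VARIABLES

__all__ = [
    "FeatureTable",
    "StandardizationParams",
    "RangeScaler",
    "resample_bicubic",
    "assess_collinearity",
    "range_standardize",
    "build_feature_table",
    "scatter_to_grid",
]

COLLINEARITY_THRESHOLD = 0.85


# ---------------------------------------------------------------------------
# Bicubic (cubic-convolution) resampling
# ---------------------------------------------------------------------------

def _cubic_kernel(t: np.ndarray, a: float) -> np.ndarray:
    """Keys' cubic convolution kernel (a = -0.5 is Catmull-Rom)."""
    t = np.abs(t)
    out = np.zeros_like(t)
    near = t <= 1
    far = (t > 1) & (t < 2)
    out[near] = (a + 2) * t[near] ** 3 - (a + 3) * t[near] ** 2 + 1
    out[far] = a * t[far] ** 3 - 5 * a * t[far] ** 2 + 8 * a * t[far] - 4 * a
    return out


def _axis_weights(src_coords: np.ndarray, dst_coords: np.ndarray,
                  a: float) -> np.ndarray:
    """(n_dst, n_src) interpolation matrix for one axis, edge-clamped.

    ``src_coords`` must be uniformly spaced; positions are converted to
    fractional source index, the 4 surrounding taps are weighted by the
    cubic kernel, and out-of-range taps are clamped to the boundary sample
    (replication padding).
    """
    step = src_coords[1] - src_coords[0] if len(src_coords) > 1 else 1.0
    u = (dst_coords - src_coords[0]) / step
    n_src = len(src_coords)
    W = np.zeros((len(dst_coords), n_src))
    base = np.floor(u).astype(int)
    for tap in (-1, 0, 1, 2):
        idx = base + tap
        w = _cubic_kernel(u - idx, a)
        np.add.at(W, (np.arange(len(u)), np.clip(idx, 0, n_src - 1)), w)
    return W


def _fill_invalid_nearest(grid: RasterGrid) -> np.ndarray:
    """Replace invalid cells with the nearest valid value (for interpolation)."""
    if grid.mask.all():
        return grid.values.astype(float)
    if not grid.mask.any():
        raise ValueError("grid has no valid cells to interpolate from")
    ind = ndimage.distance_transform_edt(~grid.mask, return_distances=False,
                                         return_indices=True)
    return grid.values.astype(float)[tuple(ind)]


def resample_bicubic(grid: RasterGrid, target: GridGeo,
                     target_mask: np.ndarray | None = None,
                     a: float = -0.5) -> RasterGrid:
    """Resample onto ``target`` by separable cubic convolution.

    Invalid source cells (land) are pre-filled from their nearest valid
    neighbor so the 4x4 support never mixes in nodata, then the output is
    re-masked: by ``target_mask`` when given, else by nearest-neighbor
    sampling of the source mask at the target cell centers.
    """
    src, dst = grid.geo, target
    if (dst.lon_min < src.lon_min - src.cell_width or
            dst.lon_max > src.lon_max + src.cell_width or
            dst.lat_min < src.lat_min - src.cell_height or
            dst.lat_max > src.lat_max + src.cell_height):
        raise ValueError("target extent is not covered by the source grid")
    filled = _fill_invalid_nearest(grid)
    W_lat = _axis_weights(src.lat_centers(), dst.lat_centers(), a)
    W_lon = _axis_weights(src.lon_centers(), dst.lon_centers(), a)
    out = W_lat @ filled @ W_lon.T
    if target_mask is None:
        rows = np.clip(np.round((src.lat_max - dst.lat_centers())
                                / src.cell_height - 0.5).astype(int), 0, src.n_rows - 1)
        cols = np.clip(np.round((dst.lon_centers() - src.lon_min)
                                / src.cell_width - 0.5).astype(int), 0, src.n_cols - 1)
        target_mask = grid.mask[np.ix_(rows, cols)]
    out = out.copy()
    out[~target_mask] = np.nan
    return RasterGrid(geo=dst, values=out, mask=np.asarray(target_mask, bool).copy(),
                      units=grid.units, name=grid.name)


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Sea-pixel x variable matrix with the pixel <-> row mapping.

    Rows are fully valid sea pixels scanned row-major over the grid; column
    order is fixed package-wide (``VARIABLES``).
    """

    values: np.ndarray                 # (n, 6) float, no missing entries
    pixel_index: np.ndarray            # (n, 2) int (row, col) grid cells
    geo: GridGeo
    columns: tuple[str, ...] = VARIABLES
    units: tuple[str, ...] = UNITS
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.pixel_index = np.asarray(self.pixel_index, int)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("feature matrix must be n x %d" % len(self.columns))
        if len(self.pixel_index) != len(self.values):
            raise ValueError("pixel_index must have one entry per row")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains missing entries")
        flat = self.pixel_index[:, 0] * self.geo.n_cols + self.pixel_index[:, 1]
        if len(np.unique(flat)) != len(flat):
            raise ValueError("duplicate pixels in pixel_index")

    def __len__(self) -> int:
        return len(self.values)

    def lonlat(self) -> tuple[np.ndarray, np.ndarray]:
        lons = self.geo.lon_centers()[self.pixel_index[:, 1]]
        lats = self.geo.lat_centers()[self.pixel_index[:, 0]]
        return lons, lats

    def to_dataframe(self) -> pd.DataFrame:
        lons, lats = self.lonlat()
        df = pd.DataFrame({"row": self.pixel_index[:, 0], "col": self.pixel_index[:, 1],
                           "lon": lons, "lat": lats})
        for j, c in enumerate(self.columns):
            df[c] = self.values[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, geo: GridGeo, standardized: bool = False) -> "FeatureTable":
        df = pd.read_csv(path)
        return cls(values=df[list(VARIABLES)].to_numpy(float),
                   pixel_index=df[["row", "col"]].to_numpy(int),
                   geo=geo, standardized=standardized)


def build_feature_table(grids: dict[str, RasterGrid] | list[RasterGrid],
                        sea_mask: np.ndarray) -> FeatureTable:
    """Rows = cells valid in ``sea_mask`` and in all six variable grids."""
    if isinstance(grids, dict):
        ordered = [grids[v] for v in VARIABLES]
    else:
        ordered = list(grids)
    geo = ordered[0].geo
    if sea_mask.shape != geo.shape:
        raise ValueError("sea mask not co-registered with the grids")
    usable = np.asarray(sea_mask, bool).copy()
    for g in ordered:
        if g.geo != geo:
            raise ValueError("variable grids are not co-registered")
        usable &= g.mask
    idx = np.argwhere(usable)  # row-major order
    if len(idx) == 0:
        raise ValueError("no usable sea pixels")
    vals = np.column_stack([g.values[idx[:, 0], idx[:, 1]] for g in ordered])
    return FeatureTable(values=vals, pixel_index=idx, geo=geo)


def scatter_to_grid(table: FeatureTable, row_values: np.ndarray,
                    fill=np.nan, dtype=float) -> np.ndarray:
    """Scatter one value per table row back onto the full grid."""
    out = np.full(table.geo.shape, fill, dtype=dtype)
    out[table.pixel_index[:, 0], table.pixel_index[:, 1]] = row_values
    return out


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------

def assess_collinearity(table: FeatureTable,
                        threshold: float = COLLINEARITY_THRESHOLD
                        ) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pearson correlations of all variable pairs; |r| >= threshold flagged.

    Flagged pairs are reported with a warning but never removed — variable
    selection is the analyst's call.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows to assess collinearity")
    sd = table.values.std(axis=0)
    zero = [c for c, s in zip(table.columns, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    r = np.corrcoef(table.values, rowvar=False)
    corr = pd.DataFrame(r, index=table.columns, columns=table.columns)
    flags = []
    for i in range(len(table.columns)):
        for j in range(i + 1, len(table.columns)):
            if abs(r[i, j]) >= threshold:
                flags.append((table.columns[i], table.columns[j], float(r[i, j])))
    if flags:
        warnings.warn("collinear variable pairs (kept): "
                      + ", ".join(f"{a}~{b} (r={v:.3f})" for a, b, v in flags),
                      stacklevel=2)
    return corr, flags


# ---------------------------------------------------------------------------
# Range standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationParams:
    """Per-column min/max in physical units, for the inverse mapping."""

    mins: np.ndarray
    maxs: np.ndarray
    columns: tuple[str, ...] = VARIABLES

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, float)
        self.maxs = np.asarray(self.maxs, float)
        if np.any(self.maxs <= self.mins):
            raise ValueError("max must exceed min for every column")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"columns": list(self.columns),
                       "min": self.mins.tolist(), "max": self.maxs.tolist()}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StandardizationParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(mins=np.array(d["min"]), maxs=np.array(d["max"]),
                   columns=tuple(d["columns"]))


class RangeScaler(TransformerMixin, BaseEstimator):
    """Scale each column to [0, 1] by its observed range.

    Equivalent to min-max scaling; kept as an explicit estimator so the
    fitted physical-unit ranges travel with the pipeline and the inverse
    mapping is exact. Constant columns abort: a variable with no spread in
    the study region signals degenerate input rather than a unit interval.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        if np.any(self.data_max_ <= self.data_min_):
            bad = np.where(self.data_max_ <= self.data_min_)[0].tolist()
            raise ValueError(f"constant column(s) {bad}: range standardization undefined")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X)
        return (X - self.data_min_) / (self.data_max_ - self.data_min_)

    def inverse_transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X)
        return X * (self.data_max_ - self.data_min_) + self.data_min_


def range_standardize(table: FeatureTable) -> tuple[FeatureTable, StandardizationParams]:
    """Map each column through x -> (x - min)/(max - min) over sea pixels."""
    scaler = RangeScaler().fit(table.values)
    std = FeatureTable(values=scaler.transform(table.values),
                       pixel_index=table.pixel_index, geo=table.geo,
                       columns=table.columns, units=("1",) * len(table.columns),
                       standardized=True)
    params = StandardizationParams(mins=scaler.data_min_, maxs=scaler.data_max_,
                                   columns=table.columns)
    return std, params
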