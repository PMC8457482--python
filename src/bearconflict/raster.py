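"""Planar grid rasters and the point/raster engineering used by the conflict model.

All grids live on an abstract planar CRS in metres. A :class:`GridRaster` is a
rectangular array of cell values anchored at its upper-left corner ``origin``;
row indices grow downward (decreasing y), column indices grow rightward
(increasing x). Cell membership is half-open, ``[x0 + j*s, x0 + (j+1)*s)`` in x
and ``(y0 - (i+1)*s, y0 - i*s]`` read through ``i = floor((y0 - y)/s)``, so a
point on a shared cell edge resolves deterministically to the lower index.
Distances and extraction are cell-centre based throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
BOOLEAN = "boolean"

#: required leading columns of a point table
POINT_COLUMNS = ("id", "x", "y", "label")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid: shape, resolution and upper-left anchor."""

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float]  # (x0, y0) of the upper-left corner

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid's outer edges."""
        x0, y0 = self.origin
        return (x0, x0 + self.n_cols * self.cell_size,
                y0 - self.n_rows * self.cell_size, y0)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-centre coordinates, shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def xy_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) indices; may fall outside the grid."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x, dtype=float) - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - np.asarray(y, dtype=float)) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.xy_to_rowcol(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass
class GridRaster:
    """A single-band raster on a planar grid.

    Parameters
    ----------
    values
        2-D array of cell values. Continuous rasters are float; categorical
        rasters hold integer codes; boolean rasters hold masks.
    cell_size
        Cell edge length in metres.
    origin
        (x0, y0) of the grid's upper-left corner.
    nodata
        Sentinel for missing cells (NaN for continuous by default, -1 for
        categorical). Boolean rasters have no nodata.
    kind
        One of ``"continuous"``, ``"categorical"``, ``"boolean"``.
    category_labels
        Optional map code -> name for categorical rasters.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float | int | None = None
    kind: str = CONTINUOUS
    category_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.kind not in (CONTINUOUS, CATEGORICAL, BOOLEAN):
            raise ValueError(f"unknown raster kind {self.kind!r}")
        if self.kind == BOOLEAN:
            self.values = self.values.astype(bool)
            self.nodata = None
        elif self.nodata is None:
            if self.kind == CONTINUOUS:
                self.values = self.values.astype(float)
                self.nodata = np.nan
            else:
                self.nodata = -1

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.values.shape[0], self.values.shape[1],
                        self.cell_size, self.origin)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def nodata_mask(self) -> np.ndarray:
        """Boolean array, True where the cell is missing."""
        if self.kind == BOOLEAN:
            return np.zeros(self.values.shape, dtype=bool)
        if isinstance(self.nodata, float) and np.isnan(self.nodata):
            return np.isnan(self.values)
        return self.values == self.nodata

    def with_values(self, values: np.ndarray, **kwargs) -> "GridRaster":
        """Copy of this raster with new cell values (same grid)."""
        out = replace(self, **kwargs)
        out.values = np.asarray(values)
        return out


@dataclass
class RasterStack:
    """Named co-registered rasters sharing one grid exactly."""

    layers: dict[str, GridRaster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = {name: lyr.grid for name, lyr in self.layers.items()}
        if grids:
            ref = next(iter(grids.values()))
            for name, g in grids.items():
                if g != ref:
                    raise ValueError(f"layer {name!r} is not aligned with the stack grid")

    @property
    def grid(self) -> GridSpec:
        if not self.layers:
            raise ValueError("empty stack has no grid")
        return next(iter(self.layers.values())).grid

    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> GridRaster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def add(self, name: str, raster: GridRaster) -> None:
        if self.layers and raster.grid != self.grid:
            raise ValueError(f"layer {name!r} is not aligned with the stack grid")
        self.layers[name] = raster


def make_points(x, y, label, ids=None) -> pd.DataFrame:
    """Build a point table with the canonical column layout (id, x, y, label)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    label = np.asarray(label, dtype=int)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("point coordinates must be finite")
    if not np.isin(label, (0, 1)).all():
        raise ValueError("labels must be 0 (available) or 1 (used)")
    if ids is None:
        ids = np.arange(len(x))
    return pd.DataFrame({"id": ids, "x": x, "y": y, "label": label})


def distance_to_feature(feature: GridRaster) -> GridRaster:
    """Euclidean distance (metres) from every cell centre to the nearest feature cell centre.

    Mirrors a GIS Euclidean-distance layer: feature cells hold 0, all other
    cells hold the straight-line centre-to-centre distance to the closest
    feature cell.
    """
    mask = feature.values.astype(bool)
    if not mask.any():
        raise ValueError("distance undefined: the feature raster has no feature cells")
    dist = ndimage.distance_transform_edt(~mask, sampling=feature.cell_size)
    return GridRaster(dist, feature.cell_size, feature.origin, kind=CONTINUOUS)


def reclassify(raster: GridRaster, mapping: Mapping[int, int],
               category_labels: dict[int, str] | None = None) -> GridRaster:
    """Relabel a categorical raster cell-wise; nodata is preserved.

    Raises if any observed code is missing from ``mapping`` (the input is left
    untouched).
    """
    if raster.kind != CATEGORICAL:
        raise ValueError("reclassify expects a categorical raster")
    nodata_mask = raster.nodata_mask()
    observed = np.unique(raster.values[~nodata_mask])
    missing = [int(c) for c in observed if int(c) not in mapping]
    if missing:
        raise ValueError(f"reclassification mapping is missing codes: {missing}")
    out = raster.values.copy()
    flat = out[~nodata_mask]
    lut = {int(c): int(mapping[int(c)]) for c in observed}
    out[~nodata_mask] = np.vectorize(lut.__getitem__, otypes=[out.dtype])(flat)
    return GridRaster(out, raster.cell_size, raster.origin, nodata=raster.nodata,
                      kind=CATEGORICAL, category_labels=category_labels)


def log_transform(raster: GridRaster, offset: float = 1.0) -> GridRaster:
    """Natural log of (value + offset), cell-wise; nodata preserved.

    Used to tame right-skewed layers (distance to forest, population density)
    whose supports include 0 — hence the default offset of 1.
    """
    if raster.kind != CONTINUOUS:
        raise ValueError("log_transform expects a continuous raster")
    nodata_mask = raster.nodata_mask()
    valid = raster.values[~nodata_mask]
    if valid.size and (valid.min() + offset) <= 0:
        raise ValueError(
            f"log undefined: min(value)+offset = {valid.min() + offset:g} <= 0")
    out = raster.values.astype(float).copy()
    out[~nodata_mask] = np.log(out[~nodata_mask] + offset)
    out[nodata_mask] = raster.nodata
    return raster.with_values(out)


def resample_nearest(raster: GridRaster, target: GridSpec) -> GridRaster:
    """Resample onto ``target`` by nearest source cell centre.

    Categorical codes are carried over verbatim (never interpolated). Target
    cells whose centres fall outside the source extent become nodata; if no
    target centre overlaps the source at all the grids are disjoint and an
    error is raised.
    """
    src = raster.grid
    tx, ty = target.cell_centers()
    # nearest source cell centre: round to the closest centre index
    jj = np.rint((tx - src.origin[0]) / src.cell_size - 0.5).astype(int)
    ii = np.rint((src.origin[1] - ty) / src.cell_size - 0.5).astype(int)
    inside = (ii >= 0) & (ii < src.n_rows) & (jj >= 0) & (jj < src.n_cols)
    if not inside.any():
        raise ValueError("target grid is disjoint from the source raster")
    if raster.kind == BOOLEAN:
        out = np.zeros(target.n_rows * target.n_cols, dtype=bool).reshape(tx.shape)
        out[inside] = raster.values[ii[inside], jj[inside]]
        return GridRaster(out, target.cell_size, target.origin, kind=BOOLEAN)
    nodata = raster.nodata
    out = np.full(tx.shape, nodata, dtype=raster.values.dtype if raster.kind == CATEGORICAL else float)
    out[inside] = raster.values[ii[inside], jj[inside]]
    return GridRaster(out, target.cell_size, target.origin, nodata=nodata,
                      kind=raster.kind, category_labels=raster.category_labels)


def crop_align(layers: Mapping[str, GridRaster] | RasterStack,
               extent: tuple[float, float, float, float],
               cell_size: float | None = None) -> RasterStack:
    """Crop and co-register layers onto one grid covering ``extent``.

    ``extent`` is (xmin, xmax, ymin, ymax). The output grid is anchored at
    (xmin, ymax) with ``cell_size`` (default: the first layer's); every layer
    is nearest-neighbour resampled onto it, so layers that already coincide
    with the target grid keep their values bit-for-bit.
    """
    if isinstance(layers, RasterStack):
        layers = layers.layers
    if not layers:
        raise ValueError("no layers to align")
    xmin, xmax, ymin, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate extent")
    if cell_size is None:
        cell_size = next(iter(layers.values())).cell_size
    n_cols = int(np.ceil((xmax - xmin) / cell_size - 1e-9))
    n_rows = int(np.ceil((ymax - ymin) / cell_size - 1e-9))
    target = GridSpec(n_rows, n_cols, cell_size, (xmin, ymax))
    out = {}
    for name, lyr in layers.items():
        sx0, sx1, sy0, sy1 = lyr.grid.extent
        if sx1 <= xmin or sx0 >= xmax or sy1 <= ymin or sy0 >= ymax:
            raise ValueError(f"layer {name!r} does not intersect the target extent")
        out[name] = resample_nearest(lyr, target)
    return RasterStack(out)


def extract_values(stack: RasterStack, points: pd.DataFrame,
                   drop_incomplete: bool = True) -> pd.DataFrame:
    """Attach the containing-cell value of every stack layer to each point.

    Points outside the stack extent, or landing on nodata in any layer, are
    flagged and (by default) excluded; the exclusion count is logged.
    """
    grid = stack.grid
    pts = points.reset_index(drop=True)
    row, col = grid.xy_to_rowcol(pts["x"].to_numpy(), pts["y"].to_numpy())
    inside = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    out = pts.copy()
    complete = inside.copy()
    r = np.clip(row, 0, grid.n_rows - 1)
    c = np.clip(col, 0, grid.n_cols - 1)
    for name, lyr in stack.layers.items():
        vals = lyr.values[r, c]
        bad = lyr.nodata_mask()[r, c]
        if lyr.kind == CONTINUOUS:
            vals = vals.astype(float)
            vals[~inside | bad] = np.nan
        out[name] = vals
        complete &= ~bad
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("extract_values: excluded %d point(s) outside the extent or on nodata",
                    n_dropped)
    if drop_incomplete:
        return out.loc[complete].reset_index(drop=True)
    out["_complete"] = complete
    return out
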