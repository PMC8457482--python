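"""Project a fitted RSPF across a covariate raster stack into a risk map.

Every cell gets w(x) evaluated on its covariate row, exactly as used points
were scored during fitting: continuous layers enter on their stored scales,
the categorical land-cover layer is expanded into the same dummy contrasts
(same reference class) the fit was built with. Cells where any required layer
is nodata come out nodata. Projection is streamed in row blocks so statewide
grids (tens of millions of cells at 50 m) stay inside bounded memory; the
block size changes nothing but peak memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import CATEGORICAL, CONTINUOUS, GridRaster, RasterStack
from .rspf import RSPFFit, eval_w

__all__ = ["RiskRaster", "project_model", "crop_to_focus", "classify_hotspots"]


@dataclass
class RiskRaster:
    """Cell-wise conflict probability plus the provenance of the fit behind it."""

    raster: GridRaster
    fit_metadata: dict

    @property
    def values(self) -> np.ndarray:
        return self.raster.values


def _design_block(fit: RSPFFit, stack: RasterStack, rows: slice) -> tuple[np.ndarray, np.ndarray]:
    """Build the (n_cells, k) design block for a band of raster rows."""
    shape = stack[stack.names()[0]].values[rows].shape
    n = shape[0] * shape[1]
    X = np.empty((n, len(fit.column_names)))
    X[:, 0] = 1.0
    bad = np.zeros(n, dtype=bool)
    for j, name in enumerate(fit.column_names[1:], start=1):
        if "=" in name:
            layer_name, code = name.split("=", 1)
            lyr = stack[layer_name]
            block = lyr.values[rows].ravel()
            X[:, j] = (block == int(code)).astype(float)
            bad |= lyr.nodata_mask()[rows].ravel()
        else:
            lyr = stack[name]
            block = lyr.values[rows].ravel().astype(float)
            nodata = lyr.nodata_mask()[rows].ravel()
            block[nodata] = 0.0  # placeholder; masked out below
            X[:, j] = block
            bad |= nodata
    # categorical sanity: codes unseen at fit time have no dummy and no reference
    cover_layers = {name.split("=", 1)[0] for name in fit.column_names if "=" in name}
    for layer_name in cover_layers:
        lyr = stack[layer_name]
        known = {int(name.split("=", 1)[1]) for name in fit.column_names
                 if name.startswith(f"{layer_name}=")}
        if fit.reference_class is not None:
            known.add(int(fit.reference_class))
        codes = np.unique(lyr.values[rows][~lyr.nodata_mask()[rows]])
        unseen = [int(c) for c in codes if int(c) not in known]
        if unseen:
            raise ValueError(f"layer {layer_name!r} contains codes unseen at "
                             f"fit time: {unseen}")
    return X, bad


def project_model(fit: RSPFFit, stack: RasterStack,
                  block_rows: int = 256) -> RiskRaster:
    """Evaluate the fitted w(x) on every cell of the stack.

    Raises if a model term has no layer in the stack or a categorical layer
    carries codes the fit never saw. Deterministic; the output is identical
    for any ``block_rows``.
    """
    needed = {name.split("=", 1)[0] for name in fit.column_names[1:]}
    missing = sorted(needed - set(stack.names()))
    if missing:
        raise ValueError(f"stack is missing model layers: {missing}")
    grid = stack.grid
    out = np.full((grid.n_rows, grid.n_cols), np.nan)
    for r0 in range(0, grid.n_rows, max(1, block_rows)):
        rows = slice(r0, min(r0 + block_rows, grid.n_rows))
        X, bad = _design_block(fit, stack, rows)
        w = eval_w(fit.beta, X)
        w[bad] = np.nan
        out[rows] = w.reshape(rows.stop - rows.start, grid.n_cols)
    raster = GridRaster(out, grid.cell_size, grid.origin, kind=CONTINUOUS)
    return RiskRaster(raster, fit.metadata() | {"beta": fit.beta.tolist(),
                                                "columns": fit.column_names})


def crop_to_focus(risk: RiskRaster, focal_mask: GridRaster) -> RiskRaster:
    """Keep risk values inside the focal region; everything outside is nodata."""
    if focal_mask.grid != risk.raster.grid:
        raise ValueError("focal mask is not aligned with the risk raster")
    mask = focal_mask.values.astype(bool)
    if not mask.any():
        raise ValueError("focal mask is empty")
    vals = risk.raster.values.copy()
    vals[~mask] = np.nan
    return RiskRaster(risk.raster.with_values(vals), dict(risk.fit_metadata))


def classify_hotspots(risk: RiskRaster, breaks) -> GridRaster:
    """Discretise probabilities into ordered risk classes.

    ``breaks`` are strictly increasing cut points inside (0, 1); bins are
    half-open, so a value exactly at a break goes to the class above. No
    breaks means a single class. Nodata cells stay nodata.
    """
    breaks = list(breaks)
    if breaks != sorted(set(breaks)):
        raise ValueError("breaks must be strictly increasing")
    if any(not 0 < b < 1 for b in breaks):
        raise ValueError("breaks must lie strictly inside (0, 1)")
    vals = risk.raster.values
    nodata_mask = np.isnan(vals)
    codes = np.searchsorted(np.asarray(breaks, dtype=float), vals, side="right")
    codes = codes.astype(int)
    codes[nodata_mask] = -1
    labels = {i: f"class_{i}" for i in range(len(breaks) + 1)}
    return GridRaster(codes, risk.raster.cell_size, risk.raster.origin,
                      nodata=-1, kind=CATEGORICAL, category_labels=labels)
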