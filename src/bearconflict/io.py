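"""File I/O: text rasters (ESRI ASCII grid), point tables, configs and fits.

Rasters are exchanged in the ESRI ASCII grid format (``.asc``) — a plain-text
header (ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value) followed by the
cell values — which every mainstream GIS reads and writes. Point tables are
CSV with the canonical columns ``id, x, y, label`` followed by covariates, or
GeoJSON point features (stdlib json). Use-availability covariate tables (a binary conflict
column plus covariates, the layout of published supplementary datasets) are
read into the same point-table convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .raster import BOOLEAN, CATEGORICAL, CONTINUOUS, GridRaster, RasterStack

__all__ = [
    "read_ascii_grid", "write_ascii_grid", "read_stack", "write_stack",
    "read_points_csv", "write_points_csv", "read_points_geojson",
    "write_points_geojson", "read_use_availability_csv",
    "load_config", "save_config", "save_fit", "load_fit_metadata",
]


def write_ascii_grid(raster: GridRaster, path: str | Path) -> Path:
    """Write one raster as an ESRI ASCII grid."""
    path = Path(path)
    g = raster.grid
    if raster.kind == BOOLEAN:
        vals, nodata, fmt = raster.values.astype(int), -1, "%d"
    elif raster.kind == CATEGORICAL:
        vals, nodata, fmt = raster.values, raster.nodata, "%d"
    else:
        nodata = -9999.0
        vals = np.where(raster.nodata_mask(), nodata, raster.values)
        fmt = "%.10g"
    header = (f"ncols {g.n_cols}\nnrows {g.n_rows}\n"
              f"xllcorner {g.origin[0]:.10g}\n"
              f"yllcorner {g.origin[1] - g.n_rows * g.cell_size:.10g}\n"
              f"cellsize {g.cell_size:.10g}\nNODATA_value {nodata}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)
    return path


def read_ascii_grid(path: str | Path, kind: str = CONTINUOUS) -> GridRaster:
    """Read an ESRI ASCII grid back into a :class:`GridRaster`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            key = key.lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"):
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (n_rows, n_cols):
        raise ValueError(f"grid body {vals.shape} does not match header "
                         f"({n_rows}, {n_cols})")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
    nodata = header.get("nodata_value", -9999.0)
    if kind == BOOLEAN:
        return GridRaster(vals != 0, cell, origin, kind=BOOLEAN)
    if kind == CATEGORICAL:
        return GridRaster(vals.astype(int), cell, origin, nodata=int(nodata),
                          kind=CATEGORICAL)
    out = vals.astype(float)
    out[out == nodata] = np.nan
    return GridRaster(out, cell, origin, kind=CONTINUOUS)


def write_stack(stack: RasterStack, directory: str | Path) -> dict[str, Path]:
    """Write each layer as ``<name>.asc`` plus a ``stack.json`` manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    meta = {}
    for name, lyr in stack.layers.items():
        p = write_ascii_grid(lyr, directory / f"{name}.asc")
        paths[name] = p
        meta[name] = {"kind": lyr.kind, "file": p.name}
    (directory / "stack.json").write_text(json.dumps(meta, indent=2))
    return paths


def read_stack(directory: str | Path) -> RasterStack:
    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    layers = {name: read_ascii_grid(directory / info["file"], kind=info["kind"])
              for name, info in meta.items()}
    return RasterStack(layers)


def write_points_csv(points: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    points.to_csv(path, index=False)
    return path


def read_points_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"point CSV is missing columns: {missing}")
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(len(df)))
    if "label" not in df.columns:
        df["label"] = 1
    return df


def write_points_geojson(points: pd.DataFrame, path: str | Path) -> Path:
    """Write points as a GeoJSON FeatureCollection (planar coordinates)."""
    feats = []
    attr_cols = [c for c in points.columns if c not in ("x", "y")]
    for _, row in points.iterrows():
        props = {c: (row[c].item() if hasattr(row[c], "item") else row[c])
                 for c in attr_cols}
        feats.append({"type": "Feature",
                      "geometry": {"type": "Point",
                                   "coordinates": [float(row["x"]), float(row["y"])]},
                      "properties": props})
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
    return path


def read_points_geojson(path: str | Path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data["features"]:
        x, y = feat["geometry"]["coordinates"][:2]
        rows.append({"x": x, "y": y, **feat.get("properties", {})})
    df = pd.DataFrame(rows)
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(len(df)))
    if "label" not in df.columns:
        df["label"] = 1
    return df


def read_use_availability_csv(path: str | Path,
                              label_col: str = "Conflict") -> pd.DataFrame:
    """Read a covariate table with a binary conflict column into the point layout.

    This is the layout of supplementary use-availability datasets: one row per
    location, a 0/1 conflict indicator, and covariate columns; coordinates may
    be withheld, in which case x and y are filled with NaN placeholders.
    """
    df = pd.read_csv(path)
    if label_col not in df.columns:
        raise ValueError(f"no {label_col!r} column in {path}")
    out = df.rename(columns={label_col: "label"})
    out["label"] = out["label"].astype(int)
    if not out["label"].isin((0, 1)).all():
        raise ValueError(f"{label_col!r} must be binary 0/1")
    for coord in ("x", "y"):
        if coord not in out.columns:
            out[coord] = np.nan
    if "id" not in out.columns:
        out.insert(0, "id", np.arange(len(out)))
    lead = ["id", "x", "y", "label"]
    return out[lead + [c for c in out.columns if c not in lead]]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path


def save_fit(fit, directory: str | Path, stem: str = "fit") -> dict[str, Path]:
    """Write a fitted model as a coefficient-table CSV plus metadata JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coef_path = directory / f"{stem}_coefficients.csv"
    fit.coefficient_table().to_csv(coef_path, index=False)
    meta = fit.metadata() | {"beta": fit.beta.tolist(),
                             "columns": fit.column_names}
    if fit.se is not None:
        meta["se"] = fit.se.tolist()
    meta_path = directory / f"{stem}_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"coefficients": coef_path, "metadata": meta_path}


def load_fit_metadata(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
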