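"""Text-based raster and table I/O.

Rasters are written as ESRI ASCII grids (``.asc``) — a plain-text format
readable by GDAL/QGIS and trivially diff-able — and, as a fallback for
tests, as long-form CSV (x, y, value). Point tables (occurrences,
haulouts, background) are CSV via pandas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import CONTINUOUS, GridSpec, RasterLayer

_NODATA = -9999.0


def write_ascii_grid(layer: RasterLayer, path) -> None:
    """Write a layer as an ESRI ASCII grid (rows north to south)."""
    g = layer.grid
    vals = np.where(layer.mask, layer.values, _NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.x_min!r}\n")
        fh.write(f"yllcorner {g.y_min!r}\n")
        fh.write(f"cellsize {g.cell_side!r}\n")
        fh.write(f"NODATA_value {_NODATA}\n")
        # internal row 0 is the southernmost; .asc stores north first
        np.savetxt(fh, vals[::-1], fmt="%.10g")


def read_ascii_grid(path, name: str = "", kind: str = CONTINUOUS) -> RasterLayer:
    """Read an ESRI ASCII grid back into a :class:`RasterLayer`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1]
    nodata = header.get("nodata_value", _NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    grid = GridSpec(
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        cell_side=header["cellsize"],
        n_cols=int(header["ncols"]),
        n_rows=int(header["nrows"]),
    )
    return RasterLayer(grid=grid, name=name or str(path), values=vals, kind=kind)


def write_layer_csv(layer: RasterLayer, path) -> None:
    """Long-form CSV (x, y, value) of the non-missing cells."""
    centers = layer.grid.cell_centers()
    flat = layer.values.ravel()
    ok = np.isfinite(flat)
    pd.DataFrame(
        {"x": centers[ok, 0], "y": centers[ok, 1], "value": flat[ok]}
    ).to_csv(path, index=False)


def write_points_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_points_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
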