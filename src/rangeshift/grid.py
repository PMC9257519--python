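"""Planar equal-area raster grid model, regridding, and stack alignment.

All spatial data in the pipeline live on a shared planar grid of square
cells, with coordinates in km in an equal-area projection. Cell area is
therefore ``cell_side**2`` everywhere, which is what enters every km²
summary downstream. The default cell side is ``sqrt(9.2)`` km so that one
cell covers 9.2 km², the native resolution of the oceanographic layers the
pipeline is designed around.

Grid indexing is 0-based row-major from the lower-left corner: row 0 is the
southernmost row, and within a row x varies fastest. Cell intervals are
half-open ``[min, min + n*side)``. Missing cells are NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

#: Side length (km) of a square cell covering 9.2 km².
DEFAULT_CELL_SIDE_KM = math.sqrt(9.2)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a planar raster grid: origin, cell side (km), and shape."""

    x_min: float
    y_min: float
    cell_side: float = DEFAULT_CELL_SIDE_KM
    n_cols: int = 1
    n_rows: int = 1

    def __post_init__(self) -> None:
        if self.cell_side <= 0:
            raise ValueError("cell_side must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_side

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_side

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_side**2

    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_side

    def y_centers(self) -> np.ndarray:
        return self.y_min + (np.arange(self.n_rows) + 0.5) * self.cell_side

    def cell_centers(self) -> np.ndarray:
        """All cell centers as an (n_cells, 2) array of (x, y), row-major
        from the lower-left corner (row 0 first, x varying fastest)."""
        xx, yy = np.meshgrid(self.x_centers(), self.y_centers())
        return np.column_stack([xx.ravel(), yy.ravel()])

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min) & (x < self.x_max) & (y >= self.y_min) & (y < self.y_max)
        )

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of the cells containing planar points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_min) / self.cell_side).astype(int)
        row = np.floor((y - self.y_min) / self.cell_side).astype(int)
        return row, col


def cell_centers(grid: GridSpec) -> np.ndarray:
    """Row-major cell-center coordinates; center = min + (index+0.5)*side."""
    return grid.cell_centers()


@dataclass
class RasterLayer:
    """One gridded variable: values on a :class:`GridSpec`, NaN = missing.

    ``kind`` is ``"continuous"`` or ``"categorical"``; categorical layers
    hold integer level codes stored as floats (NaN still marks missing)
    and carry the declared ``levels``.
    """

    grid: GridSpec
    name: str
    values: np.ndarray
    kind: str = CONTINUOUS
    units: str = ""
    levels: tuple | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} != "
                f"grid shape {self.grid.shape}"
            )
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == CATEGORICAL and self.levels is not None:
            observed = set(np.unique(self.values[np.isfinite(self.values)]))
            declared = {float(v) for v in self.levels}
            if not observed <= declared:
                raise ValueError(
                    f"categorical layer {self.name!r} contains undeclared codes "
                    f"{sorted(observed - declared)}"
                )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell has a value."""
        return np.isfinite(self.values)

    def copy_with(self, **kw) -> "RasterLayer":
        out = RasterLayer(
            grid=kw.get("grid", self.grid),
            name=kw.get("name", self.name),
            values=kw.get("values", self.values.copy()),
            kind=kw.get("kind", self.kind),
            units=kw.get("units", self.units),
            levels=kw.get("levels", self.levels),
        )
        return out


@dataclass
class RasterStack:
    """Ordered collection of co-registered layers with a joint validity mask."""

    grid: GridSpec
    layers: list = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [lyr.name for lyr in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for lyr in self.layers:
            if lyr.grid != self.grid:
                raise ValueError(f"layer {lyr.name!r} is not on the stack grid")

    def __iter__(self):
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def __contains__(self, name: str) -> bool:
        return any(lyr.name == name for lyr in self.layers)

    def __getitem__(self, name: str) -> RasterLayer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    @property
    def valid_mask(self) -> np.ndarray:
        """A cell is valid iff it is non-missing in every layer."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for lyr in self.layers:
            mask &= lyr.mask
        return mask

    def with_layer(self, layer: RasterLayer) -> "RasterStack":
        """New stack with ``layer`` appended (or replaced if the name exists)."""
        kept = [lyr for lyr in self.layers if lyr.name != layer.name]
        return RasterStack(self.grid, kept + [layer])

    def values_at(self, x, y, names=None) -> dict[str, np.ndarray]:
        """Per-layer values at planar points; NaN outside the grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.grid.contains(x, y)
        row, col = self.grid.cell_of(np.clip(x, self.grid.x_min, None), y)
        row = np.clip(row, 0, self.grid.n_rows - 1)
        col = np.clip(col, 0, self.grid.n_cols - 1)
        out = {}
        for name in names if names is not None else self.names:
            vals = self[name].values[row, col]
            vals = np.where(inside, vals, np.nan)
            out[name] = vals
        return out


def resample_to_grid(layer: RasterLayer, target: GridSpec) -> RasterLayer:
    """Resample a layer onto a target grid.

    Continuous layers use bilinear interpolation of the four surrounding
    source cell centers; categorical layers use nearest-neighbour (bilinear
    is undefined on class codes). Target cells outside the source extent
    come back missing.
    """
    src = layer.grid
    if src.n_cols < 2 or src.n_rows < 2:
        raise ValueError("source layer must have at least 2x2 cells")
    if (
        target.x_min >= src.x_max
        or target.x_max <= src.x_min
        or target.y_min >= src.y_max
        or target.y_max <= src.y_min
    ):
        raise ValueError("target grid does not overlap the source extent")

    tx, ty = np.meshgrid(target.x_centers(), target.y_centers())
    if layer.kind == CONTINUOUS:
        interp = RegularGridInterpolator(
            (src.y_centers(), src.x_centers()),
            layer.values,
            method="linear",
            bounds_error=False,
            fill_value=np.nan,
        )
        out = interp(np.column_stack([ty.ravel(), tx.ravel()])).reshape(target.shape)
    else:
        # nearest-neighbour on cell indices, masked outside the source extent
        col = np.clip(
            np.floor((tx - src.x_min) / src.cell_side).astype(int), 0, src.n_cols - 1
        )
        row = np.clip(
            np.floor((ty - src.y_min) / src.cell_side).astype(int), 0, src.n_rows - 1
        )
        out = layer.values[row, col]
        outside = ~src.contains(tx, ty)
        out = np.where(outside, np.nan, out)
    return layer.copy_with(grid=target, values=out)


def align_stack(layers, target: GridSpec) -> RasterStack:
    """Resample every layer to ``target`` and assemble a stack.

    Layers already on the target grid are passed through untouched so that
    alignment is the identity for co-registered inputs.
    """
    layers = list(layers)
    if not layers:
        raise ValueError("need at least one layer")
    names = [lyr.name for lyr in layers]
    if len(set(names)) != len(names):
        raise ValueError("duplicate layer names")
    aligned = [
        lyr if lyr.grid == target else resample_to_grid(lyr, target) for lyr in layers
    ]
    return RasterStack(target, aligned)
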