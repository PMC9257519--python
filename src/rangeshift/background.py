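"""Sampling-bias surfaces and bias-aware background sampling.

Presence-background models need background points that reflect the same
spatial sampling effort as the presences; otherwise the model learns the
observers' behaviour instead of the species'. The standard correction
estimates a kernel density surface of all sampling locations and draws the
background from it, so bias cancels in the presence/background contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, RasterLayer
from .synth import OccurrenceSet

DEFAULT_N_BACKGROUND = 10_000


@dataclass
class BiasSurface:
    """Normalized sampling-effort density on the grid (sums to 1 over valid
    cells) with the kernel bandwidth used, in km."""

    layer: RasterLayer
    bandwidth_km: float

    def __post_init__(self) -> None:
        vals = self.layer.values
        ok = np.isfinite(vals)
        if np.any(vals[ok] < 0):
            raise ValueError("bias surface has negative values")
        total = vals[ok].sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"bias surface sums to {total}, expected 1")


def scott_bandwidth(points: np.ndarray) -> float:
    """Scott's rule for a 2-D isotropic kernel: n^(-1/6) times the pooled
    per-dimension standard deviation (floored to stay positive for
    degenerate point sets)."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    sd = np.sqrt(points.var(axis=0, ddof=1).mean()) if n > 1 else 1.0
    return max(float(n ** (-1.0 / 6.0) * sd), 1e-6)


def bias_surface(
    occurrences: OccurrenceSet,
    grid: GridSpec,
    bandwidth: float | str = "auto",
    valid_mask: np.ndarray | None = None,
) -> BiasSurface:
    """Isotropic Gaussian kernel density of the sampling locations,
    evaluated at cell centers, masked to valid cells, renormalized to 1."""
    pts = occurrences.points
    if len(pts) == 0:
        raise ValueError("need at least one occurrence")
    h = scott_bandwidth(pts) if bandwidth == "auto" else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    centers = grid.cell_centers()
    # sum of Gaussian kernels; chunked over points to bound memory
    dens = np.zeros(len(centers))
    inv = 1.0 / (2.0 * h * h)
    for start in range(0, len(pts), 512):
        chunk = pts[start : start + 512]
        d2 = ((centers[:, None, :] - chunk[None, :, :]) ** 2).sum(axis=2)
        dens += np.exp(-d2 * inv).sum(axis=1)
    dens = dens.reshape(grid.shape)
    if valid_mask is not None:
        dens = np.where(valid_mask, dens, np.nan)
    ok = np.isfinite(dens)
    if not ok.any():
        raise ValueError("no valid cells for the bias surface")
    total = dens[ok].sum()
    if total <= 0:
        # all kernels negligibly far from valid cells: fall back to uniform
        dens = np.where(ok, 1.0 / ok.sum(), np.nan)
    else:
        dens = dens / total
    return BiasSurface(
        layer=RasterLayer(grid=grid, name="sampling_bias", values=dens),
        bandwidth_km=h,
    )


def sample_background(
    bias: BiasSurface, n: int = DEFAULT_N_BACKGROUND, seed: int = 0
) -> np.ndarray:
    """Draw ``n`` background points: cells with replacement proportional to
    the bias surface, uniform placement within each drawn cell."""
    if n <= 0:
        raise ValueError("n must be positive")
    grid = bias.layer.grid
    w = np.where(np.isfinite(bias.layer.values), bias.layer.values, 0.0).ravel()
    rng = np.random.default_rng(seed)
    cells = rng.choice(grid.n_cells, size=n, replace=True, p=w / w.sum())
    rows, cols = np.divmod(cells, grid.n_cols)
    x = grid.x_min + (cols + rng.random(n)) * grid.cell_side
    y = grid.y_min + (rows + rng.random(n)) * grid.cell_side
    return np.column_stack([x, y])
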