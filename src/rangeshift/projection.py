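"""Multivariate environmental similarity (MESS) and masked projection.

Projecting a fitted model onto future conditions is only trustworthy where
those conditions resemble the training data. MESS scores each cell by its
similarity to a reference sample (here: the presence locations' current
conditions), per variable, and takes the per-cell minimum; a negative
score means at least one variable falls outside the reference range. Cells
with negative MESS are masked out of the projection ("novel" conditions),
as are cells whose categorical class was unseen in the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import CATEGORICAL, RasterLayer, RasterStack
from .maxent import MaxEntModel, predict_cloglog_values


@dataclass
class MESSResult:
    """Per-cell minimum similarity (percent scale, negative = novel) and
    the name of the most dissimilar variable per cell."""

    similarity: RasterLayer
    most_dissimilar: np.ndarray  # object array of variable names

    @property
    def novel_mask(self) -> np.ndarray:
        """True where conditions are novel (S < 0)."""
        s = self.similarity.values
        return np.isfinite(s) & (s < 0)


def _mess_one(ref: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Similarity of values ``p`` to a reference sample, on the standard
    piecewise percent scale."""
    ref = np.sort(ref[np.isfinite(ref)])
    n = len(ref)
    lo, hi = ref[0], ref[-1]
    s = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if hi == lo:
        s[ok] = np.where(p[ok] == lo, 0.0, -np.inf)
        return s
    f = 100.0 * np.searchsorted(ref, p[ok], side="left") / n  # % of ref < p
    pv = p[ok]
    out = np.where(
        f == 0.0,
        100.0 * (pv - lo) / (hi - lo),
        np.where(
            f <= 50.0,
            2.0 * f,
            np.where(f < 100.0, 2.0 * (100.0 - f), 100.0 * (hi - pv) / (hi - lo)),
        ),
    )
    s[ok] = out
    return s


def mess(reference_values: dict, stack: RasterStack) -> MESSResult:
    """MESS of a raster stack against reference samples per variable.

    ``reference_values`` maps continuous variable names to 1-D reference
    samples (>= 2 values each); categorical variables are excluded.
    The cell score is the minimum over variables; the arg-min variable is
    recorded per cell.
    """
    if not reference_values:
        raise ValueError("need at least one reference variable")
    names = list(reference_values)
    for name in names:
        ref = np.asarray(reference_values[name], dtype=float)
        if np.isfinite(ref).sum() < 2:
            raise ValueError(f"variable {name!r}: need >= 2 reference values")
        if stack[name].kind == CATEGORICAL:
            raise ValueError(f"variable {name!r} is categorical; excluded from MESS")

    sims = np.stack(
        [
            _mess_one(
                np.asarray(reference_values[name], dtype=float),
                stack[name].values,
            )
            for name in names
        ]
    )
    masked = np.where(np.isnan(sims), np.inf, sims)
    idx = np.argmin(masked, axis=0)
    any_valid = ~np.all(np.isnan(sims), axis=0)
    s_min = np.where(any_valid, masked.min(axis=0), np.nan)
    most = np.array(names, dtype=object)[idx]
    most[~any_valid] = None
    layer = RasterLayer(grid=stack.grid, name="mess", values=s_min, units="%")
    return MESSResult(similarity=layer, most_dissimilar=most)


def presence_reference(
    stack: RasterStack, points: np.ndarray, variables=None
) -> dict:
    """Reference sample for MESS: current-condition values at the presence
    locations, continuous variables only."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if variables is None:
        variables = [lyr.name for lyr in stack if lyr.kind != CATEGORICAL]
    vals = stack.values_at(points[:, 0], points[:, 1], names=variables)
    return {k: v[np.isfinite(v)] for k, v in vals.items()}


def project(
    model: MaxEntModel,
    stack: RasterStack,
    mess_result: MESSResult | None = None,
    reference_categorical: dict | None = None,
) -> RasterLayer:
    """Cloglog suitability on the stack's valid cells, with novel cells
    (negative MESS, or an unseen categorical class when
    ``reference_categorical`` maps variable -> seen level set) masked out."""
    needed = [name for name, _, _ in model.expansion.continuous] + [
        name for name, _ in model.expansion.categorical
    ]
    missing = [name for name in needed if name not in stack]
    if missing:
        raise ValueError(f"stack is missing model variables {missing}")

    values = {name: stack[name].values.ravel() for name in needed}
    suit = predict_cloglog_values(model, values).reshape(stack.grid.shape)
    mask = stack.valid_mask
    if mess_result is not None:
        sim = mess_result.similarity.values
        mask = mask & np.isfinite(sim) & (sim >= 0)
    if reference_categorical:
        for name, seen in reference_categorical.items():
            codes = stack[name].values
            mask = mask & (np.isin(codes, list(seen)) | ~np.isfinite(codes))
    out = np.where(mask, suit, np.nan)
    return RasterLayer(grid=stack.grid, name="suitability", values=out)
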