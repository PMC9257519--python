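"""Binarization thresholds, range area, clustering, and overlap metrics.

Continuous suitability maps are binarized at three complementary
thresholds: Kappa (the cutoff maximizing Cohen's kappa against the
background sample — typically the most restrictive), MSSS (maximizing
sensitivity + specificity), and P10 (the suitability of the lowest-scoring
10% of presences — typically the most inclusive). Binary range maps are
summarized by total area (cell count × cell area), by the Clark–Evans
nearest-neighbour index (NNI: observed mean nearest-neighbour distance
over its expectation under complete spatial randomness; < 1 clustered,
> 1 dispersed; no edge correction), and by cellwise inter-specific overlap.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import RasterLayer
from .selection import p10_threshold

THRESHOLD_NAMES = ("kappa", "msss", "p10")


@dataclass
class ThresholdSet:
    """The three binarization cutoffs derived from one score vector pair."""

    kappa: float
    msss: float
    p10: float

    def as_dict(self) -> dict[str, float]:
        return {"kappa": self.kappa, "msss": self.msss, "p10": self.p10}


@dataclass
class BinaryMap:
    """A thresholded range map: cells in {0, 1, missing}."""

    layer: RasterLayer
    threshold_name: str
    threshold_value: float
    species: str = ""
    period: str = ""

    @property
    def suitable(self) -> np.ndarray:
        return self.layer.values == 1.0


def _confusion_counts(pos, neg, candidates):
    """Vectorized TP/FP counts for 'score >= t' over sorted candidates."""
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    tp = len(pos) - np.searchsorted(pos_sorted, candidates, side="left")
    fp = len(neg) - np.searchsorted(neg_sorted, candidates, side="left")
    return tp, fp


def _scan(pos_scores, neg_scores, stat) -> float:
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be nonempty")
    candidates = np.unique(np.concatenate([pos, neg]))
    if len(candidates) == 1:
        warnings.warn("all scores identical; threshold degenerate", stacklevel=3)
        return float(candidates[0])
    tp, fp = _confusion_counts(pos, neg, candidates)
    values = stat(tp, fp, len(pos), len(neg))
    best = np.flatnonzero(values == values.max())[0]  # ties -> smallest t
    return float(candidates[best])


def threshold_kappa(pos_scores, neg_scores) -> float:
    """Cutoff maximizing Cohen's kappa (presences positive, background
    negative); ties go to the smallest cutoff."""

    def kappa_stat(tp, fp, n_pos, n_neg):
        fn = n_pos - tp
        tn = n_neg - fp
        n = n_pos + n_neg
        po = (tp + tn) / n
        pe = ((tp + fp) * n_pos + (fn + tn) * n_neg) / (n * n)
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(pe >= 1.0, 0.0, (po - pe) / (1.0 - pe))
        return k

    return _scan(pos_scores, neg_scores, kappa_stat)


def threshold_msss(pos_scores, neg_scores) -> float:
    """Cutoff maximizing sensitivity + specificity (Youden); ties go to
    the smallest cutoff."""

    def youden(tp, fp, n_pos, n_neg):
        return tp / n_pos + (n_neg - fp) / n_neg

    return _scan(pos_scores, neg_scores, youden)


def threshold_p10(pos_scores) -> float:
    """Cutoff omitting the lowest-scoring 10% of presences (same
    order-statistic rule as the OR10 metric)."""
    return p10_threshold(pos_scores)


def threshold_set(pos_scores, neg_scores) -> ThresholdSet:
    return ThresholdSet(
        kappa=threshold_kappa(pos_scores, neg_scores),
        msss=threshold_msss(pos_scores, neg_scores),
        p10=threshold_p10(pos_scores),
    )


def binarize(
    suitability: RasterLayer,
    threshold: float,
    name: str = "",
    species: str = "",
    period: str = "",
) -> BinaryMap:
    """1 iff suitability >= threshold; missing propagates."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    vals = suitability.values
    out = np.where(np.isfinite(vals), (vals >= threshold).astype(float), np.nan)
    return BinaryMap(
        layer=RasterLayer(grid=suitability.grid, name=f"binary_{name}", values=out),
        threshold_name=name,
        threshold_value=threshold,
        species=species,
        period=period,
    )


def area_km2(binary: BinaryMap) -> float:
    """Total suitable area: count of 1-cells times the cell area."""
    return float(binary.suitable.sum()) * binary.layer.grid.cell_area_km2


def nni_points(points: np.ndarray, study_area_km2: float) -> float:
    """Clark–Evans nearest-neighbour index for a planar point set."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    if n < 2:
        return float("nan")
    if study_area_km2 <= 0:
        raise ValueError("study area must be positive")
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=2)
    d_obs = dist[:, 1].mean()
    density = n / study_area_km2
    d_exp = 1.0 / (2.0 * np.sqrt(density))
    return float(d_obs / d_exp)


def nni(binary: BinaryMap, study_area_km2: float | None = None) -> float:
    """NNI of the suitable-cell centers. The reference density uses the
    map's valid (non-missing) area unless a study area is given; fewer
    than two suitable cells yields NaN."""
    grid = binary.layer.grid
    if study_area_km2 is None:
        valid = np.isfinite(binary.layer.values)
        study_area_km2 = float(valid.sum()) * grid.cell_area_km2
    pts = grid.cell_centers()[binary.suitable.ravel()]
    return nni_points(pts, study_area_km2)


@dataclass
class OverlapSummary:
    """Shared-range areas per species combination."""

    rows: pd.DataFrame  # columns: combination, period, threshold, area_km2
    maps: dict  # combination key -> BinaryMap


def overlap_area(binaries: dict, period: str = "", threshold_name: str = "") -> OverlapSummary:
    """Cellwise-AND overlap for every pairwise and the all-species
    combination of binary maps on a shared grid."""
    names = list(binaries)
    if len(names) < 2:
        raise ValueError("need >= 2 maps for overlap")
    grid = binaries[names[0]].layer.grid
    for nm in names:
        if binaries[nm].layer.grid != grid:
            raise ValueError("maps are on different grids")

    combos = [c for r in range(2, len(names) + 1) for c in itertools.combinations(names, r)]
    rows, maps = [], {}
    for combo in combos:
        vals = np.ones(grid.shape)
        missing = np.zeros(grid.shape, dtype=bool)
        for nm in combo:
            v = binaries[nm].layer.values
            missing |= ~np.isfinite(v)
            vals = vals * np.where(np.isfinite(v), v, 0.0)
        vals = np.where(missing, np.nan, vals)
        bmap = BinaryMap(
            layer=RasterLayer(grid=grid, name="overlap", values=vals),
            threshold_name=threshold_name,
            threshold_value=float("nan"),
            species="+".join(combo),
            period=period,
        )
        key = "+".join(combo)
        maps[key] = bmap
        rows.append(
            {
                "combination": key,
                "period": period,
                "threshold": threshold_name,
                "area_km2": area_km2(bmap),
            }
        )
    return OverlapSummary(rows=pd.DataFrame(rows), maps=maps)


@dataclass
class ChangeSummary:
    """Current-vs-future area and clustering for one species × scenario ×
    threshold combination."""

    species: str
    scenario: str
    threshold_name: str
    threshold_value: float
    area_current_km2: float
    area_future_km2: float
    delta_km2: float
    nni_current: float
    nni_future: float

    def as_row(self) -> dict:
        return {
            "species": self.species,
            "scenario": self.scenario,
            "threshold": self.threshold_name,
            "threshold_value": self.threshold_value,
            "area_current_km2": self.area_current_km2,
            "area_future_km2": self.area_future_km2,
            "delta_km2": self.delta_km2,
            "nni_current": self.nni_current,
            "nni_future": self.nni_future,
        }


def change_summary(
    current: BinaryMap,
    future: BinaryMap,
    species: str = "",
    scenario: str = "",
) -> ChangeSummary:
    """Area and NNI change between periods at a fixed threshold."""
    if current.layer.grid != future.layer.grid:
        raise ValueError("binary maps are on different grids")
    a_cur = area_km2(current)
    a_fut = area_km2(future)
    return ChangeSummary(
        species=species or current.species,
        scenario=scenario or future.period,
        threshold_name=current.threshold_name,
        threshold_value=current.threshold_value,
        area_current_km2=a_cur,
        area_future_km2=a_fut,
        delta_km2=a_fut - a_cur,
        nni_current=nni(current),
        nni_future=nni(future),
    )
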