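"""Scenario-dependent covariates and collinearity diagnostics.

Sea-level rise removes low-lying haulout sites from future use: the
effective local water-level rise is the scenario's global mean rise plus a
regional isostatic adjustment, and a haulout whose elevation does not
exceed that rise is treated as flooded. The distance-to-nearest-haulout
predictor is then recomputed per scenario from the surviving sites.

Collinearity among predictors is reported (variance inflation factors and
pairwise Spearman rank correlations at the sampling locations) but nothing
is dropped automatically — the screen is diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .grid import CATEGORICAL, GridSpec, RasterLayer, RasterStack

#: Region codes for isostatic adjustment (south-west Baltic; southern
#: Kattegat and Bornholm; central/northern Kattegat).
REGIONS = ("SW_Baltic", "S_Kattegat_Bornholm", "CN_Kattegat")

#: Default regional isostatic water-level adjustments (m) added to the
#: global mean sea-level rise under future scenarios.
DEFAULT_ISOSTATIC = {
    "SW_Baltic": 0.10,
    "S_Kattegat_Bornholm": -0.05,
    "CN_Kattegat": -0.15,
}

#: Global mean sea-level rise (m) by scenario label.
DEFAULT_MEAN_SLR = {"current": 0.0, "RCP6.0": 0.39, "RCP8.5": 0.65}


@dataclass(frozen=True)
class HaulOut:
    """A shore site where seals rest; availability depends on elevation."""

    id: str
    x: float
    y: float
    elevation_m: float
    region: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    """A water-level scenario: global mean rise + per-region isostatic terms."""

    label: str
    mean_slr_m: float = 0.0
    isostatic_by_region: dict = field(default_factory=lambda: dict(DEFAULT_ISOSTATIC))

    def __post_init__(self) -> None:
        if self.label == "current" and self.mean_slr_m != 0.0:
            raise ValueError("current scenario must have zero mean sea-level rise")

    @property
    def is_current(self) -> bool:
        return self.label == "current"


def default_scenarios() -> list[ScenarioSpec]:
    return [ScenarioSpec(label=k, mean_slr_m=v) for k, v in DEFAULT_MEAN_SLR.items()]


def effective_water_level_rise(scenario: ScenarioSpec, region: str) -> float:
    """Effective local rise (m): mean rise + regional isostatic adjustment.

    The current period is the zero baseline by definition — isostatic
    terms enter only under future scenarios.
    """
    if region not in scenario.isostatic_by_region:
        raise ValueError(f"region {region!r} not declared in scenario")
    if scenario.is_current:
        return 0.0
    return scenario.mean_slr_m + scenario.isostatic_by_region[region]


def filter_flooded_haulouts(haulouts, scenario: ScenarioSpec) -> list[HaulOut]:
    """Retain haulouts whose elevation strictly exceeds the effective rise.

    A site exactly at the cutoff floods (ties go to removal). Under the
    current scenario every site is retained.
    """
    haulouts = list(haulouts)
    if not haulouts:
        raise ValueError("haulout list is empty")
    if scenario.is_current:
        return haulouts
    return [
        h
        for h in haulouts
        if h.elevation_m > effective_water_level_rise(scenario, h.region)
    ]


def distance_to_nearest_haulout(grid: GridSpec, haulouts) -> RasterLayer:
    """Per-cell Euclidean distance (km) from the cell center to the closest
    haulout site. Distance is planar, over water and land alike."""
    haulouts = list(haulouts)
    if not haulouts:
        raise ValueError("no haulouts under scenario")
    sites = np.array([[h.x, h.y] for h in haulouts])
    tree = cKDTree(sites)
    dist, _ = tree.query(grid.cell_centers())
    return RasterLayer(
        grid=grid,
        name="dist_haulout",
        values=dist.reshape(grid.shape),
        units="km",
    )


@dataclass
class CollinearityReport:
    """VIF per variable (NaN for categorical, inf for perfect collinearity)
    and the pairwise Spearman rho matrix over continuous variables."""

    vif: pd.Series
    spearman: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = self.spearman.copy()
        out.insert(0, "vif", self.vif.reindex(out.index))
        return out


def _vif_ols(X: np.ndarray, j: int) -> float:
    """VIF of column j from a centered least-squares fit on the others."""
    y = X[:, j] - X[:, j].mean()
    others = np.delete(X, j, axis=1)
    others = others - others.mean(axis=0)
    sst = float(y @ y)
    if sst == 0.0:
        return np.inf
    coef, *_ = np.linalg.lstsq(others, y, rcond=None)
    resid = y - others @ coef
    r2 = 1.0 - float(resid @ resid) / sst
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def collinearity_screen(stack: RasterStack, points: np.ndarray) -> CollinearityReport:
    """Collinearity diagnostics at sampling locations.

    VIF_j = 1/(1 - R²_j) from regressing continuous variable j on the
    other continuous variables; categorical variables are excluded from
    VIF (reported NaN) and from the Spearman matrix. Perfectly collinear
    variables get an infinite VIF rather than an error. The report is
    diagnostic only; no variables are dropped.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    cont = [lyr.name for lyr in stack if lyr.kind != CATEGORICAL]
    vals = stack.values_at(points[:, 0], points[:, 1], names=cont)
    X = np.column_stack([vals[name] for name in cont])
    X = X[np.all(np.isfinite(X), axis=1)]
    if X.shape[0] < len(cont) + 2:
        raise ValueError("too few valid points for a collinearity screen")

    vif = pd.Series(
        [_vif_ols(X, j) for j in range(len(cont))], index=cont, dtype=float
    )
    for lyr in stack:
        if lyr.kind == CATEGORICAL:
            vif[lyr.name] = np.nan

    rho, _ = stats.spearmanr(X)
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-variable case
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    spearman = pd.DataFrame(rho, index=cont, columns=cont)
    return CollinearityReport(vif=vif, spearman=spearman)
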