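"""Synthetic study systems: environment rasters, scenario futures, haulouts,
telemetry-like tracks, and presence points from known response surfaces.

The generator emulates a brackish shelf sea sampled on a planar equal-area
grid: smooth spatially autocorrelated bathymetry (with derived seabed
slope), a 5-class sediment factor, sea-surface current/temperature fields,
and a salinity field that declines monotonically from a saline northern
edge (25 PSU default) to a brackish southern edge (7 PSU default) —
the dominant gradient of the system the pipeline targets. Species truth is
a logistic response surface over min-max-scaled covariates, restricted to
linear + quadratic terms and categorical offsets, mirroring the feature
family the fitted models use. Presence points are drawn proportional to
truth × an optional spatial sampling-bias surface, so the bias-correction
stages downstream have a known signal to recover.

Everything is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .covariates import REGIONS, HaulOut
from .grid import CATEGORICAL, CONTINUOUS, GridSpec, RasterLayer, RasterStack

SEDIMENT_LEVELS = (1.0, 2.0, 3.0, 4.0, 5.0)

#: Telemetry subsampling target hours (6-hourly: 03:00, 09:00, 15:00, 21:00).
TARGET_HOURS = (3, 9, 15, 21)


@dataclass
class ResponseSpec:
    """Ground-truth habitat response: eta = intercept + sum(a1*s + a2*s^2)
    over min-max-scaled continuous variables, plus categorical level
    offsets; suitability = logistic(eta)."""

    intercept: float = 0.0
    linear: dict = field(default_factory=dict)
    quadratic: dict = field(default_factory=dict)
    categorical: dict = field(default_factory=dict)  # var -> {level: offset}

    @property
    def variables(self) -> set[str]:
        return set(self.linear) | set(self.quadratic) | set(self.categorical)


@dataclass
class SyntheticScenario:
    """Additive climate deltas defining a synthetic future."""

    label: str
    sst_delta: float = 0.0
    sss_delta: float = 0.0
    current_delta: float = 0.0


@dataclass
class Track:
    """A telemetry track: fix coordinates with timestamps."""

    species: str
    x: np.ndarray
    y: np.ndarray
    timestamps: pd.DatetimeIndex
    tag_type: str = "gps"  # "gps" or "argos"
    deploy_time: pd.Timestamp | None = None
    track_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if len(self.timestamps) != len(self.x) or len(self.x) != len(self.y):
            raise ValueError("x, y, timestamps must have equal length")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if self.tag_type not in ("gps", "argos"):
            raise ValueError(f"unknown tag type {self.tag_type!r}")
        if self.deploy_time is None and len(self.timestamps):
            self.deploy_time = self.timestamps[0]


@dataclass
class OccurrenceSet:
    """Presence points for one species."""

    species: str
    points: np.ndarray  # (n, 2) planar km
    track_ids: list | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": self.species, "x": self.points[:, 0], "y": self.points[:, 1]}
        )


@dataclass
class EnvParams:
    """Tunables of the synthetic environment (units in layer names)."""

    smooth_sigma: float = 4.0  # cells; spatial autocorrelation scale
    salinity_north: float = 25.0  # PSU at the northern (top) edge
    salinity_south: float = 7.0  # PSU at the southern (bottom) edge
    salinity_noise: float = 1.0  # PSU, smoothed-noise amplitude
    depth_min: float = 5.0  # m, shallowest water
    depth_max: float = 80.0  # m, deepest water
    temp_mean: float = 8.0  # deg C
    temp_amp: float = 3.5  # deg C, smoothed-noise amplitude
    current_mean: float = 0.15  # m/s
    current_amp: float = 0.10  # m/s
    land_fraction: float = 0.05  # fraction of cells masked as land


def _smooth_unit(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo)


def generate_environment(
    grid: GridSpec, seed: int, params: EnvParams | None = None
) -> RasterStack:
    """Generate the six environment layers on ``grid``.

    Layers: bathymetry (m, negative down), slope (degrees, gradient
    magnitude of bathymetry), sediment (5-class factor), current (m/s),
    salinity (PSU, north-to-south decline), temperature (deg C). The
    distance-to-haulout predictor is scenario-dependent and added by the
    covariate stage, not here. A common land mask (missing in all layers)
    covers ``land_fraction`` of cells.
    """
    if grid.n_cols < 20 or grid.n_rows < 20:
        raise ValueError("grid must be at least 20x20 for spatial structure")
    p = params or EnvParams()
    rng = np.random.default_rng(seed)
    shape = grid.shape

    depth_u = _smooth_unit(rng, shape, p.smooth_sigma)
    bathy = -(p.depth_min + (p.depth_max - p.depth_min) * depth_u)

    dz_dy, dz_dx = np.gradient(bathy, grid.cell_side)
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy) / 1000.0))  # m per m

    sed_field = _smooth_unit(rng, shape, p.smooth_sigma)
    edges = np.quantile(sed_field, [0.2, 0.4, 0.6, 0.8])
    sediment = (np.digitize(sed_field, edges) + 1).astype(float)

    current = p.current_mean + p.current_amp * (
        2.0 * _smooth_unit(rng, shape, p.smooth_sigma) - 1.0
    )
    current = np.clip(current, 0.0, None)

    t_north = (np.arange(grid.n_rows) + 0.5) / grid.n_rows  # 0 south -> 1 north
    salinity = (
        p.salinity_south
        + (p.salinity_north - p.salinity_south) * t_north[:, None]
        + p.salinity_noise * (2.0 * _smooth_unit(rng, shape, p.smooth_sigma) - 1.0)
    )

    temperature = p.temp_mean + p.temp_amp * (
        2.0 * _smooth_unit(rng, shape, p.smooth_sigma) - 1.0
    )

    land = np.zeros(shape, dtype=bool)
    if p.land_fraction > 0:
        land_field = _smooth_unit(rng, shape, p.smooth_sigma / 2.0)
        land = land_field > np.quantile(land_field, 1.0 - p.land_fraction)

    def lyr(name, vals, kind=CONTINUOUS, units="", levels=None):
        vals = np.where(land, np.nan, vals)
        return RasterLayer(
            grid=grid, name=name, values=vals, kind=kind, units=units, levels=levels
        )

    return RasterStack(
        grid,
        [
            lyr("bathymetry", bathy, units="m"),
            lyr("slope", slope, units="deg"),
            lyr("sediment", sediment, kind=CATEGORICAL, units="class",
                levels=SEDIMENT_LEVELS),
            lyr("current", current, units="m/s"),
            lyr("salinity", salinity, units="PSU"),
            lyr("temperature", temperature, units="degC"),
        ],
    )


#: Layers a scenario is allowed to shift; everything else is static.
DYNAMIC_LAYERS = {"temperature": "sst_delta", "salinity": "sss_delta",
                  "current": "current_delta"}


def apply_scenario(stack: RasterStack, scenario: SyntheticScenario) -> RasterStack:
    """Add the scenario's deltas to the dynamic layers; static layers pass
    through unchanged."""
    for name in DYNAMIC_LAYERS:
        if name not in stack:
            raise ValueError(f"stack is missing dynamic layer {name!r}")
    out = []
    for layer in stack:
        delta = getattr(scenario, DYNAMIC_LAYERS.get(layer.name, ""), 0.0) \
            if layer.name in DYNAMIC_LAYERS else 0.0
        if delta:
            out.append(layer.copy_with(values=layer.values + delta))
        else:
            out.append(layer.copy_with())
    return RasterStack(stack.grid, out)


def _minmax_scaled(layer: RasterLayer) -> np.ndarray:
    vals = layer.values
    ok = np.isfinite(vals)
    lo, hi = vals[ok].min(), vals[ok].max()
    if hi == lo:
        return np.where(ok, 0.0, np.nan)
    return (vals - lo) / (hi - lo)


def true_suitability(stack: RasterStack, resp: ResponseSpec) -> RasterLayer:
    """Ground-truth suitability surface: logistic(eta) per cell, with eta
    the linear+quadratic response on min-max-scaled variables."""
    missing = resp.variables - set(stack.names)
    if missing:
        raise ValueError(f"response references missing layers {sorted(missing)}")
    eta = np.full(stack.grid.shape, resp.intercept, dtype=float)
    for var, a1 in resp.linear.items():
        eta = eta + a1 * _minmax_scaled(stack[var])
    for var, a2 in resp.quadratic.items():
        eta = eta + a2 * _minmax_scaled(stack[var]) ** 2
    for var, offsets in resp.categorical.items():
        codes = stack[var].values
        shift = np.zeros_like(eta)
        for level, off in offsets.items():
            shift[codes == float(level)] = off
        eta = eta + shift
    suit = 1.0 / (1.0 + np.exp(-eta))
    suit = np.where(stack.valid_mask, suit, np.nan)
    return RasterLayer(grid=stack.grid, name="true_suitability", values=suit)


def sample_presences(
    suit: RasterLayer,
    n: int,
    bias: RasterLayer | None = None,
    seed: int = 0,
    species: str = "synthetic",
) -> OccurrenceSet:
    """Draw ``n`` presence points: cells with probability proportional to
    suitability × bias, then uniform placement within the drawn cell."""
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = suit.grid
    w = np.where(np.isfinite(suit.values), suit.values, 0.0).ravel()
    if bias is not None:
        b = np.where(np.isfinite(bias.values), bias.values, 0.0).ravel()
        w = w * b
    total = w.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    rng = np.random.default_rng(seed)
    cells = rng.choice(grid.n_cells, size=n, replace=True, p=w / total)
    rows, cols = np.divmod(cells, grid.n_cols)
    x = grid.x_min + (cols + rng.random(n)) * grid.cell_side
    y = grid.y_min + (rows + rng.random(n)) * grid.cell_side
    return OccurrenceSet(species=species, points=np.column_stack([x, y]))


def generate_haulouts(
    n: int,
    grid: GridSpec,
    valid_mask: np.ndarray | None = None,
    region_assignment=None,
    elevation_range: tuple[float, float] = (0.0, 1.2),
    seed: int = 0,
) -> list[HaulOut]:
    """Place ``n`` haulout sites on valid cells with uniform elevations.

    The default elevation range (0–1.2 m) straddles every scenario's
    effective water-level cutoff, so some sites flood under each future.
    ``region_assignment`` maps (x, y) to a region label; the default
    assigns by north-south terciles (south = SW_Baltic, middle =
    S_Kattegat_Bornholm, north = CN_Kattegat).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = elevation_range
    if hi <= lo:
        raise ValueError("elevation range must be nondegenerate")
    rng = np.random.default_rng(seed)
    if valid_mask is None:
        valid_mask = np.ones(grid.shape, dtype=bool)
    flat_valid = np.flatnonzero(valid_mask.ravel())
    if flat_valid.size == 0:
        raise ValueError("no valid cells for haulouts")
    cells = rng.choice(flat_valid, size=n, replace=flat_valid.size < n)
    rows, cols = np.divmod(cells, grid.n_cols)
    x = grid.x_min + (cols + 0.5) * grid.cell_side
    y = grid.y_min + (rows + 0.5) * grid.cell_side
    elev = rng.uniform(lo, hi, size=n)

    if region_assignment is None:
        y_span = grid.y_max - grid.y_min

        def region_assignment(px, py):
            t = (py - grid.y_min) / y_span
            return REGIONS[min(int(t * 3), 2)]

    return [
        HaulOut(
            id=f"h{i:03d}",
            x=float(x[i]),
            y=float(y[i]),
            elevation_m=float(elev[i]),
            region=region_assignment(float(x[i]), float(y[i])),
        )
        for i in range(n)
    ]


def preprocess_track(track: Track) -> OccurrenceSet:
    """Standard telemetry preprocessing into presence points.

    Fixes within 24 h of deployment are dropped (capture/tagging
    behavioural bias). GPS tracks are subsampled to six-hourly: per date
    and target hour (03/09/15/21) the single fix nearest the target is
    retained, ties going to the earlier fix. Argos tracks (already
    duty-cycled) pass through after the 24-h cut.
    """
    ts = track.timestamps
    keep = ts >= track.deploy_time + pd.Timedelta(hours=24)
    df = pd.DataFrame(
        {"x": track.x[keep], "y": track.y[keep], "ts": ts[keep]}
    )
    if track.tag_type == "gps" and len(df):
        hours = df["ts"].dt.hour + df["ts"].dt.minute / 60 + df["ts"].dt.second / 3600
        slots = np.asarray(TARGET_HOURS, dtype=float)
        dist = np.abs(hours.to_numpy()[:, None] - slots[None, :])
        df["slot"] = slots[np.argmin(dist, axis=1)]
        df["dist"] = dist.min(axis=1)
        df["date"] = df["ts"].dt.date
        df = (
            df.sort_values(["date", "slot", "dist", "ts"])
            .groupby(["date", "slot"], as_index=False)
            .first()
        )
    return OccurrenceSet(
        species=track.species,
        points=df[["x", "y"]].to_numpy(),
        track_ids=[track.track_id] * len(df),
    )


def demo_species_responses() -> dict[str, ResponseSpec]:
    """The two bundled demo species.

    ``seal_like`` declines linearly with salinity and decays with distance
    to the nearest haulout; ``porpoise_like`` has a concave quadratic
    salinity response peaking toward the saline end with a slight decline
    at the top — the qualitative contrast between resident seals and
    porpoises in the target system.
    """
    return {
        "seal_like": ResponseSpec(
            intercept=1.5,
            linear={"salinity": -3.0, "dist_haulout": -5.0, "slope": -1.0},
            quadratic={},
        ),
        "porpoise_like": ResponseSpec(
            intercept=-2.0,
            linear={"salinity": 9.75, "slope": 1.0},
            quadratic={"salinity": -7.5},
        ),
    }
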