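"""Configuration-driven orchestration of the full range-shift analysis.

One run covers, per species: synthetic (or supplied) presences →
scenario-dependent covariates → collinearity report → sampling-bias
surface → background sample → cross-validated tuning and model selection →
MESS masking and projection per scenario → binarization at three
thresholds → area/clustering change summaries → inter-specific overlap.
All randomness flows from one seed expanded into per-stage substreams, so
identical configs give byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .background import DEFAULT_N_BACKGROUND, bias_surface, sample_background
from .covariates import (
    ScenarioSpec,
    collinearity_screen,
    distance_to_nearest_haulout,
    filter_flooded_haulouts,
)
from .grid import GridSpec, RasterLayer, RasterStack
from .io import write_ascii_grid
from .maxent import predict_cloglog_values
from .metrics import (
    binarize,
    change_summary,
    overlap_area,
    threshold_set,
)
from .projection import mess, presence_reference, project
from .selection import (
    DEFAULT_FEATURE_CLASSES,
    DEFAULT_RM_GRID,
    default_grid,
    tune_and_select,
)
from .synth import (
    EnvParams,
    ResponseSpec,
    SyntheticScenario,
    apply_scenario,
    demo_species_responses,
    generate_environment,
    generate_haulouts,
    sample_presences,
    true_suitability,
)

logger = logging.getLogger(__name__)


class GridConfig(BaseModel):
    x_min: float = 0.0
    y_min: float = 0.0
    cell_side: float = Field(default=float(np.sqrt(9.2)), gt=0)
    n_cols: int = Field(default=60, ge=20)
    n_rows: int = Field(default=60, ge=20)

    def to_spec(self) -> GridSpec:
        return GridSpec(**self.model_dump())


class ResponseConfig(BaseModel):
    intercept: float = 0.0
    linear: dict[str, float] = Field(default_factory=dict)
    quadratic: dict[str, float] = Field(default_factory=dict)

    def to_spec(self) -> ResponseSpec:
        return ResponseSpec(
            intercept=self.intercept,
            linear=dict(self.linear),
            quadratic=dict(self.quadratic),
        )


class SpeciesConfig(BaseModel):
    name: str
    response: str | ResponseConfig = "seal_like"
    n_presences: int = Field(default=300, ge=10)
    uses_haulouts: bool = False

    def response_spec(self) -> ResponseSpec:
        if isinstance(self.response, str):
            demos = demo_species_responses()
            if self.response not in demos:
                raise ValueError(f"unknown demo response {self.response!r}")
            return demos[self.response]
        return self.response.to_spec()


class ScenarioConfig(BaseModel):
    label: str
    mean_slr_m: float = 0.0
    sst_delta: float = 0.0
    sss_delta: float = 0.0
    current_delta: float = 0.0


class PipelineConfig(BaseModel):
    """Validated configuration of one end-to-end run."""

    seed: int
    grid: GridConfig = Field(default_factory=GridConfig)
    species: list[SpeciesConfig]
    scenarios: list[ScenarioConfig]
    n_background: int = Field(default=DEFAULT_N_BACKGROUND, ge=100)
    n_haulouts: int = Field(default=25, ge=1)
    #: Bias-kernel bandwidth (km). The bias file should reflect sampling
    #: EFFORT, which varies on the scale of tagging hubs; a data-driven
    #: density bandwidth would under-smooth because occurrences also track
    #: habitat, folding the biological signal into the correction.
    bias_bandwidth_km: float = Field(default=40.0, gt=0)
    rm_grid: list[float] = Field(default_factory=lambda: list(DEFAULT_RM_GRID))
    feature_classes: list[str] = Field(
        default_factory=lambda: list(DEFAULT_FEATURE_CLASSES)
    )
    k_folds: int = Field(default=5, ge=2)
    fit_tol: float = Field(default=1e-6, gt=0)
    fit_max_iter: int = Field(default=5000, ge=100)
    overlap_threshold: str = "kappa"

    @field_validator("scenarios")
    @classmethod
    def _has_current(cls, v):
        labels = [s.label for s in v]
        if len(set(labels)) != len(labels):
            raise ValueError("scenario labels must be unique")
        if "current" not in labels:
            raise ValueError("a 'current' scenario is required")
        return v

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=float).encode()
        ).hexdigest()[:16]


def demo_config(seed: int = 0, **overrides) -> PipelineConfig:
    """The bundled two-species demo: a seal-like species (negative linear
    salinity response, haulout-distance decay) and a porpoise-like species
    (concave quadratic salinity response), under current conditions plus
    a moderate and a severe warming/salinification scenario."""
    cfg = dict(
        seed=seed,
        species=[
            {"name": "seal_like", "response": "seal_like",
             "n_presences": 300, "uses_haulouts": True},
            {"name": "porpoise_like", "response": "porpoise_like",
             "n_presences": 300, "uses_haulouts": False},
        ],
        scenarios=[
            {"label": "current"},
            {"label": "RCP6.0", "mean_slr_m": 0.39, "sst_delta": 1.35,
             "sss_delta": 1.0},
            {"label": "RCP8.5", "mean_slr_m": 0.65, "sst_delta": 2.7,
             "sss_delta": 2.0},
        ],
    )
    cfg.update(overrides)
    return PipelineConfig.model_validate(cfg)


def _sub_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31))


def _sampling_bias_layer(grid: GridSpec, valid_mask: np.ndarray) -> RasterLayer:
    """The synthetic observation bias: tagging effort concentrated around a
    hub in the west-center of the domain (what the KDE stage must recover)."""
    centers = grid.cell_centers()
    hub = np.array(
        [grid.x_min + 0.3 * (grid.x_max - grid.x_min),
         grid.y_min + 0.5 * (grid.y_max - grid.y_min)]
    )
    scale = 0.25 * (grid.x_max - grid.x_min)
    d2 = ((centers - hub) ** 2).sum(axis=1)
    vals = np.exp(-d2 / (2 * scale**2)).reshape(grid.shape)
    vals = np.where(valid_mask, vals, np.nan)
    return RasterLayer(grid=grid, name="tagging_bias", values=vals)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full analysis; returns the result bundle and writes all
    artifacts (tables, rasters, models, manifest) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = config.grid.to_spec()
    root_seq = np.random.SeedSequence(config.seed)
    env_seq, haul_seq, *species_seqs = root_seq.spawn(2 + len(config.species))

    logger.info("generating environment on %dx%d grid", grid.n_rows, grid.n_cols)
    env = generate_environment(grid, seed=_sub_seed(env_seq))
    haulouts = generate_haulouts(
        config.n_haulouts, grid, valid_mask=env.valid_mask, seed=_sub_seed(haul_seq)
    )

    scenarios = {}
    for sc in config.scenarios:
        spec = ScenarioSpec(label=sc.label, mean_slr_m=sc.mean_slr_m)
        synth_sc = SyntheticScenario(
            label=sc.label, sst_delta=sc.sst_delta, sss_delta=sc.sss_delta,
            current_delta=sc.current_delta,
        )
        stack = apply_scenario(env, synth_sc) if sc.label != "current" else env
        kept = filter_flooded_haulouts(haulouts, spec)
        logger.info(
            "scenario %s: %d/%d haulouts retained",
            sc.label, len(kept), len(haulouts),
        )
        scenarios[sc.label] = {"spec": spec, "stack": stack, "haulouts": kept}

    sed_levels = tuple(float(v) for v in np.unique(
        env["sediment"].values[np.isfinite(env["sediment"].values)]
    ))
    bias_truth = _sampling_bias_layer(grid, env.valid_mask)

    results: dict = {"species": {}, "config": config, "grid": grid}
    change_rows, overlap_frames, tuning_tables = [], [], {}
    # maps[(period, threshold)][species] -> BinaryMap, for overlap stacking
    maps_by_period: dict[tuple, dict[str, object]] = {}

    for sp_cfg, sp_seq in zip(config.species, species_seqs):
        name = sp_cfg.name
        pres_seq, bg_seq, fold_seq = sp_seq.spawn(3)
        logger.info("species %s: building covariates and presences", name)

        def stack_for(label: str) -> RasterStack:
            entry = scenarios[label]
            stack = entry["stack"]
            if sp_cfg.uses_haulouts:
                if not entry["haulouts"]:
                    raise RuntimeError(
                        f"no haulouts left under scenario {label!r}"
                    )
                dist = distance_to_nearest_haulout(grid, entry["haulouts"])
                dist = dist.copy_with(
                    values=np.where(stack.valid_mask, dist.values, np.nan)
                )
                stack = stack.with_layer(dist)
            return stack

        current_stack = stack_for("current")
        truth = true_suitability(current_stack, sp_cfg.response_spec())
        occurrences = sample_presences(
            truth, sp_cfg.n_presences, bias=bias_truth,
            seed=_sub_seed(pres_seq), species=name,
        )
        bias = bias_surface(
            occurrences, grid, bandwidth=config.bias_bandwidth_km,
            valid_mask=current_stack.valid_mask,
        )
        background = sample_background(
            bias, n=config.n_background, seed=_sub_seed(bg_seq)
        )

        all_points = np.vstack([occurrences.points, background])
        collin = collinearity_screen(current_stack, all_points)

        def values_at(stack: RasterStack, pts: np.ndarray) -> dict:
            vals = stack.values_at(pts[:, 0], pts[:, 1])
            ok = np.all(
                np.column_stack([np.isfinite(v) for v in vals.values()]), axis=1
            )
            return {k: v[ok] for k, v in vals.items()}

        pres_values = values_at(current_stack, occurrences.points)
        bg_values = values_at(current_stack, background)
        categorical = {"sediment": sed_levels}

        logger.info("species %s: tuning %d candidates", name,
                    len(config.rm_grid) * len(config.feature_classes))
        tuning = tune_and_select(
            pres_values,
            bg_values,
            grid=default_grid(config.rm_grid, config.feature_classes),
            categorical=categorical,
            k=config.k_folds,
            seed=_sub_seed(fold_seq),
            tol=config.fit_tol,
            max_iter=config.fit_max_iter,
        )
        model = tuning.model
        tuning_tables[name] = tuning.to_frame()

        pres_cloglog = predict_cloglog_values(model, pres_values)
        bg_cloglog = predict_cloglog_values(model, bg_values)
        thresholds = threshold_set(pres_cloglog, bg_cloglog)

        mess_ref = presence_reference(current_stack, occurrences.points)
        seen_levels = {"sediment": set(np.unique(pres_values["sediment"]))}

        per_scenario = {}
        for label, entry in scenarios.items():
            stack = stack_for(label)
            mess_res = mess(mess_ref, stack)
            suit = project(model, stack, mess_res, reference_categorical=seen_levels)
            novel_frac = float(mess_res.novel_mask[stack.valid_mask].mean())
            logger.info("species %s scenario %s: %.1f%% novel", name, label,
                        100 * novel_frac)
            binaries = {
                tname: binarize(suit, tval, name=tname, species=name, period=label)
                for tname, tval in thresholds.as_dict().items()
            }
            per_scenario[label] = {
                "stack": stack, "mess": mess_res, "suitability": suit,
                "binaries": binaries, "novel_fraction": novel_frac,
            }
            write_ascii_grid(suit, outdir / f"suitability_{name}_{label}.asc")
            for tname, bmap in binaries.items():
                maps_by_period.setdefault((label, tname), {})[name] = bmap

        for label, entry in per_scenario.items():
            if label == "current":
                continue
            for tname in thresholds.as_dict():
                change_rows.append(
                    change_summary(
                        per_scenario["current"]["binaries"][tname],
                        entry["binaries"][tname],
                        species=name,
                        scenario=label,
                    ).as_row()
                )

        (outdir / f"model_{name}.json").write_text(model.to_json())
        tuning_tables[name].to_csv(outdir / f"tuning_{name}.csv", index=False)

        results["species"][name] = {
            "occurrences": occurrences,
            "background": background,
            "collinearity": collin,
            "tuning": tuning,
            "model": model,
            "thresholds": thresholds,
            "scenarios": per_scenario,
        }

    if len(config.species) >= 2:
        for (label, tname), maps in maps_by_period.items():
            overlap_frames.append(
                overlap_area(maps, period=label, threshold_name=tname).rows
            )

    change_df = pd.DataFrame(change_rows)
    change_df.to_csv(outdir / "change_summary.csv", index=False)
    overlap_df = (
        pd.concat(overlap_frames, ignore_index=True)
        if overlap_frames
        else pd.DataFrame(columns=["combination", "period", "threshold", "area_km2"])
    )
    overlap_df.to_csv(outdir / "overlap.csv", index=False)

    manifest = {
        "package": "rangeshift",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "species": [s.name for s in config.species],
        "scenarios": [s.label for s in config.scenarios],
        "complete": True,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    results["change_summary"] = change_df
    results["overlap"] = overlap_df
    return results
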